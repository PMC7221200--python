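import math

import numpy as np
import pytest

from frondquant import fluorescence as fl
from frondquant import synthetic
from frondquant.stats import fit_linear
from frondquant.synthetic import (
    FluorScenario,
    GrowthScenario,
    PigmentScenario,
    SceneSpec,
    generate_dish_series,
    generate_fluorescence_table,
    generate_pigment_table,
)


class TestSceneSpec:
    def test_dish_must_fit_in_image(self):
        with pytest.raises(ValueError, match="inside the image"):
            SceneSpec(image_width_px=100, image_height_px=100,
                      dish_center_px=(50.0, 50.0), dish_radius_px=60.0)

    def test_color_range_checked(self):
        with pytest.raises(ValueError):
            SceneSpec(water_color=(300, 0, 0))

    def test_darkening_range(self):
        with pytest.raises(ValueError):
            SceneSpec(mother_frond_darkening=0.0)


class TestDishSeries:
    def test_zero_growth_identity(self, small_scene):
        growth = GrowthScenario(initial_area_m2=2e-4, rgr_per_day=0.0,
                                duration_days=4.0)
        series = generate_dish_series(small_scene, growth)
        assert len(series) == 5
        areas = [d.true_area_m2 for d in series]
        assert max(areas) - min(areas) <= 2 * small_scene.metres_per_px**2

    def test_closed_form_doubling(self, small_scene):
        growth = GrowthScenario(initial_area_m2=1e-3, rgr_per_day=math.log(2) / 4,
                                duration_days=4.0)
        series = generate_dish_series(small_scene, growth)
        assert series[-1].true_area_m2 == pytest.approx(2e-3, rel=0.01)

    def test_ground_truth_within_one_percent_of_analytic(self, small_scene):
        growth = GrowthScenario(initial_area_m2=1.6e-4, rgr_per_day=0.25)
        for d in generate_dish_series(small_scene, growth):
            analytic = growth.area_at(d.image.day)
            assert abs(d.true_area_m2 - analytic) / analytic <= 0.01

    def test_mask_pixel_count_is_ground_truth(self, small_scene):
        growth = GrowthScenario(initial_area_m2=2e-4, rgr_per_day=0.2)
        for d in generate_dish_series(small_scene, growth):
            assert d.true_area_m2 == (
                d.frond_mask.sum() * small_scene.metres_per_px**2
            )

    def test_determinism_byte_identical(self, small_scene):
        growth = GrowthScenario(initial_area_m2=2e-4, rgr_per_day=0.2)
        a = generate_dish_series(small_scene, growth)
        b = generate_dish_series(small_scene, growth)
        for da, db in zip(a, b):
            assert np.array_equal(da.image.pixels, db.image.pixels)
            assert np.array_equal(da.frond_mask, db.frond_mask)

    def test_different_seed_different_image(self, small_scene):
        from dataclasses import replace

        growth = GrowthScenario(initial_area_m2=2e-4, rgr_per_day=0.2)
        a = generate_dish_series(small_scene, growth)
        b = generate_dish_series(replace(small_scene, seed=small_scene.seed + 1),
                                 growth)
        assert not np.array_equal(a[0].image.pixels, b[0].image.pixels)

    def test_overflow_rejected(self, small_scene):
        growth = GrowthScenario(initial_area_m2=small_scene.water_area_m2,
                                rgr_per_day=0.2)
        with pytest.raises(ValueError, match="overflows"):
            generate_dish_series(small_scene, growth)

    def test_fronds_inside_water_circle(self, small_scene):
        growth = GrowthScenario(initial_area_m2=3e-4, rgr_per_day=0.3)
        d = generate_dish_series(small_scene, growth)[-1]
        rr, cc = np.nonzero(d.frond_mask)
        cr, ccen = small_scene.dish_center_px
        dist = np.sqrt((rr - cr) ** 2 + (cc - ccen) ** 2)
        assert dist.max() <= small_scene.dish_radius_px


class TestFluorTable:
    def test_zero_noise_roundtrip_exact(self, fluor_scenario):
        table = generate_fluorescence_table(fluor_scenario, dishes_per_ppfd=2)
        psii = fl.process_table(table)
        for _, row in psii.iterrows():
            p = row["growth_ppfd"]
            assert row["FvpFmp"] == pytest.approx(
                fluor_scenario.true_FvpFmp[p], abs=1e-14)
            assert row["oneMinusQP"] == pytest.approx(
                fluor_scenario.true_oneMinusQP[p], abs=1e-14)
            assert row["FvFm_pre"] == pytest.approx(
                fluor_scenario.dark_FvFm_pre[p], abs=1e-14)
            assert row["FvFm_post"] == pytest.approx(
                fluor_scenario.dark_FvFm_post[p], abs=1e-14)

    def test_derived_example_row(self):
        scn = FluorScenario(
            true_FvpFmp={100.0: 0.75}, true_oneMinusQP={100.0: 1 / 3},
            dark_FvFm_pre={100.0: 0.8}, dark_FvFm_post={100.0: 0.8},
        )
        table = generate_fluorescence_table(scn, dishes_per_ppfd=1)
        light = table[table["state"] == "light"].iloc[0]
        d = fl.derive_psii(
            fl.FluorRecord("d", 100.0, "light", F=light["F"],
                           Fmp=light["Fmp"], Fop=light["Fop"])
        )
        assert d.FvpFmp == pytest.approx(0.75, abs=1e-15)
        assert d.oneMinusQP == pytest.approx(1 / 3, abs=1e-15)

    def test_zero_efficiency_degenerate_row(self):
        scn = FluorScenario(
            true_FvpFmp={100.0: 0.0}, true_oneMinusQP={100.0: 0.5},
            dark_FvFm_pre={100.0: 0.8}, dark_FvFm_post={100.0: 0.8},
        )
        table = generate_fluorescence_table(scn, dishes_per_ppfd=1)
        psii = fl.process_table(table)
        assert bool(psii.iloc[0]["degenerate"])
        assert not bool(psii.iloc[0]["partition_valid"])

    def test_true_efficiency_above_max_rejected(self):
        with pytest.raises(ValueError):
            FluorScenario(
                true_FvpFmp={100.0: 0.85}, true_oneMinusQP={100.0: 0.1},
                dark_FvFm_pre={100.0: 0.8}, dark_FvFm_post={100.0: 0.8},
            )

    def test_zero_noise_tables_identical_across_runs(self, fluor_scenario):
        a = generate_fluorescence_table(fluor_scenario, 3)
        b = generate_fluorescence_table(fluor_scenario, 3)
        assert a.equals(b)

    def test_noisy_tables_deterministic_under_seed(self, fluor_scenario):
        from dataclasses import replace

        scn = replace(fluor_scenario, noise_sd=0.02)
        a = generate_fluorescence_table(scn, 3)
        b = generate_fluorescence_table(scn, 3)
        assert a.equals(b)


class TestPigmentTable:
    def test_zero_noise_means_exact(self, pigment_scenario):
        pig, _ = generate_pigment_table(pigment_scenario, 2, dishes_per_ppfd=3)
        pre = pig[(pig["growth_ppfd"] == 700.0) & (pig["recovery"] == "pre")]
        for name, mean in pigment_scenario.means[700.0].items():
            assert np.allclose(pre[name], mean)

    def test_fvfm_on_configured_line(self, pigment_scenario):
        _, dark = generate_pigment_table(pigment_scenario, 2)
        expect = (pigment_scenario.fvfm_intercept
                  + pigment_scenario.fvfm_slope * dark["z_frac_vaz"])
        assert np.allclose(dark["dark_fvfm"], expect)

    def test_line_evaluation_example(self):
        scn = PigmentScenario(
            means={100.0: {"chl_a": 300.0, "chl_b": 100.0, "viola": 12.0,
                           "anthera": 2.0, "zea": 6.0, "lutein": 10.0,
                           "beta_car": 30.0, "neo": 12.0}},
            fvfm_slope=-0.3, fvfm_intercept=0.84,
        )
        # z_frac = 6/20 = 0.3 -> FvFm = 0.84 - 0.3*0.3 = 0.75
        _, dark = generate_pigment_table(scn, 2, dishes_per_ppfd=1)
        pre = dark[dark["recovery"] == "pre"].iloc[0]
        assert pre["z_frac_vaz"] == pytest.approx(0.3)
        assert pre["dark_fvfm"] == pytest.approx(0.75)

    def test_post_zea_below_pre_when_drop_positive(self, pigment_scenario):
        pig, _ = generate_pigment_table(pigment_scenario, 2)
        for dish, grp in pig[pig["growth_ppfd"] == 700.0].groupby("dish_id"):
            z = grp.set_index("recovery")["zea"]
            assert z["post"] < z["pre"]

    def test_vaz_pool_recovery_stable(self, pigment_scenario):
        pig, _ = generate_pigment_table(pigment_scenario, 2)
        vaz = pig["viola"] + pig["anthera"] + pig["zea"]
        by = pig.assign(vaz=vaz).groupby(["dish_id", "recovery"])["vaz"].sum()
        for dish in pig["dish_id"].unique():
            assert by[dish]["pre"] == pytest.approx(by[dish]["post"])

    def test_flat_scenario_flat_trends(self):
        means = {p: {"chl_a": 300.0, "chl_b": 100.0, "viola": 12.0,
                     "anthera": 2.0, "zea": 6.0, "lutein": 10.0,
                     "beta_car": 30.0, "neo": 12.0} for p in (100.0, 700.0)}
        pig, _ = generate_pigment_table(PigmentScenario(means=means), 2)
        from frondquant.pigments import summarize_table

        summ = summarize_table(pig)
        assert summ.groupby("growth_ppfd")["vaz"].mean().nunique() == 1

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            PigmentScenario(means={100.0: {"chl_a": -1.0}})

    def test_odd_samples_per_dish_rejected(self, pigment_scenario):
        with pytest.raises(ValueError):
            generate_pigment_table(pigment_scenario, 3)

    def test_regression_recovers_configured_line(self, pigment_scenario):
        _, dark = generate_pigment_table(pigment_scenario, 2)
        res = fit_linear(dark["z_frac_vaz"], dark["dark_fvfm"])
        assert res.slope == pytest.approx(pigment_scenario.fvfm_slope, abs=1e-12)
        assert res.intercept == pytest.approx(pigment_scenario.fvfm_intercept,
                                              abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)


def test_write_dish_series_manifest(tmp_path, small_scene):
    growth = GrowthScenario(initial_area_m2=2e-4, rgr_per_day=0.2,
                            duration_days=2.0)
    series = {"d1": generate_dish_series(small_scene, growth, "d1")}
    manifest = synthetic.write_dish_series(series, tmp_path, seed=7)
    assert len(manifest) == 3
    for _, row in manifest.iterrows():
        assert (tmp_path / row["image"]).exists()
        assert (tmp_path / row["mask"]).exists()
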