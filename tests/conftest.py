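import pytest

from frondquant import synthetic


@pytest.fixture
def small_scene():
    """Compact scene used where rendering speed matters more than realism."""
    return synthetic.SceneSpec(
        image_width_px=240,
        image_height_px=240,
        dish_center_px=(120.0, 120.0),
        dish_radius_px=105.0,
        metres_per_px=0.0725 / 105.0,
        seed=7,
    )


@pytest.fixture
def fluor_scenario():
    return synthetic.FluorScenario(
        true_FvpFmp={100.0: 0.68, 700.0: 0.40},
        true_oneMinusQP={100.0: 0.12, 700.0: 0.34},
        dark_FvFm_pre={100.0: 0.79, 700.0: 0.72},
        dark_FvFm_post={100.0: 0.815, 700.0: 0.78},
        seed=11,
    )


@pytest.fixture
def pigment_scenario():
    return synthetic.PigmentScenario(
        means={
            100.0: {"chl_a": 320.0, "chl_b": 110.0, "viola": 24.0, "anthera": 1.5,
                    "zea": 0.5, "lutein": 55.0, "beta_car": 30.0, "neo": 12.0},
            700.0: {"chl_a": 240.0, "chl_b": 70.0, "viola": 20.0, "anthera": 5.0,
                    "zea": 12.5, "lutein": 65.0, "beta_car": 32.0, "neo": 11.0},
        },
        zea_recovery_drop={100.0: 0.3, 700.0: 7.0},
        fvfm_slope=-0.3,
        fvfm_intercept=0.82,
        seed=13,
    )
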