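"""End-to-end orchestration: simulate -> segment -> growth -> fluorescence
-> pigments -> stats, with a JSON run manifest."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import replace
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__, fluorescence, growth, imaging, pigments, stats, synthetic
from .config import RunConfig

__all__ = [
    "simulate_stage",
    "segment_stage",
    "growth_stage",
    "fluorescence_stage",
    "pigments_stage",
    "stats_stage",
    "run_all",
]

log = logging.getLogger("frondquant")


def _dish_scene(cfg: RunConfig, index: int) -> synthetic.SceneSpec:
    # one deterministic sub-seed per dish so series are independent
    return replace(cfg.scene, seed=cfg.seed * 100_003 + index)


def simulate_stage(cfg: RunConfig, out_dir: Path) -> Dict[str, str]:
    """Generate images + raw tables for the configured experiment."""
    out_dir.mkdir(parents=True, exist_ok=True)
    series_by_dish = {}
    for idx, (dish_id, ppfd) in enumerate(sorted(cfg.dish_ids().items())):
        scenario = synthetic.GrowthScenario(
            initial_area_m2=cfg.initial_area_m2,
            rgr_per_day=cfg.rgr_by_ppfd[ppfd],
            ppfd_umol_m2_s=ppfd,
            duration_days=cfg.t4_days,
            imaging_interval_days=cfg.imaging_interval_days,
        )
        series_by_dish[dish_id] = synthetic.generate_dish_series(
            _dish_scene(cfg, idx), scenario, dish_id=dish_id
        )
    synthetic.write_dish_series(series_by_dish, out_dir, seed=cfg.seed)

    fluor_scn = synthetic.FluorScenario(
        true_FvpFmp={p: cfg.true_FvpFmp[p] for p in cfg.ppfds},
        true_oneMinusQP={p: cfg.true_oneMinusQP[p] for p in cfg.ppfds},
        dark_FvFm_pre={p: cfg.dark_FvFm_pre[p] for p in cfg.ppfds},
        dark_FvFm_post={p: cfg.dark_FvFm_post[p] for p in cfg.ppfds},
        noise_sd=cfg.fluor_noise_sd,
        max_efficiency=cfg.max_efficiency,
        seed=cfg.seed + 1,
    )
    fluor = synthetic.generate_fluorescence_table(fluor_scn, cfg.dishes_per_ppfd)
    fluor.to_csv(out_dir / "fluor.csv", index=False)

    pig_scn = synthetic.PigmentScenario(
        means={p: cfg.pigment_means[p] for p in cfg.ppfds},
        zea_recovery_drop={p: cfg.zea_recovery_drop.get(p, 0.0) for p in cfg.ppfds},
        fvfm_slope=cfg.fvfm_slope,
        fvfm_intercept=cfg.fvfm_intercept,
        noise_sd=cfg.pigment_noise_sd,
        seed=cfg.seed + 2,
    )
    pig, dark = synthetic.generate_pigment_table(pig_scn, 2, cfg.dishes_per_ppfd)
    pig.to_csv(out_dir / "pigments_raw.csv", index=False)
    dark.to_csv(out_dir / "dark_fvfm.csv", index=False)
    return {
        "manifest": "manifest.csv",
        "fluor": "fluor.csv",
        "pigments_raw": "pigments_raw.csv",
        "dark_fvfm": "dark_fvfm.csv",
    }


def segment_stage(cfg: RunConfig, out_dir: Path,
                  qc_dir: Optional[Path] = None) -> pd.DataFrame:
    """Measure frond areas for every image listed in the manifest."""
    manifest = pd.read_csv(out_dir / "manifest.csv")
    records = []
    for _, row in manifest.iterrows():
        img = imaging.load_dish_image(
            out_dir / row["image"], str(row["dish_id"]), float(row["day"]),
            geometry=cfg.geometry,
        )
        water = imaging.detect_water_mask(img)
        rec = imaging.measure_frond_area(img, water, cfg.thresholds)
        records.append(rec)
        if qc_dir is not None:
            qc_dir.mkdir(parents=True, exist_ok=True)
            frond = imaging.threshold_fronds(img, water, cfg.thresholds)
            imaging.write_qc_overlay(
                img, water, frond, qc_dir / f"{rec.dish_id}_day{rec.day:g}.png"
            )
    return imaging.write_area_csv(records, out_dir / "areas.csv")


def growth_stage(cfg: RunConfig, out_dir: Path) -> pd.DataFrame:
    areas = pd.read_csv(out_dir / "areas.csv")
    df = growth.growth_table(
        areas.to_dict("records"),
        {d: p for d, p in cfg.dish_ids().items()},
    )
    df.to_csv(out_dir / "growth.csv", index=False)
    return df


def fluorescence_stage(cfg: RunConfig, out_dir: Path) -> pd.DataFrame:
    fluor = pd.read_csv(out_dir / "fluor.csv")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        df = fluorescence.process_table(
            fluor,
            max_efficiency=cfg.max_efficiency,
            recovered_fvfm_floor=cfg.recovered_fvfm_floor,
        )
    for w in caught:
        log.warning("fluorescence: %s", w.message)
    df.attrs["warnings"] = [str(w.message) for w in caught]
    df.to_csv(out_dir / "psii.csv", index=False)
    return df


def pigments_stage(cfg: RunConfig, out_dir: Path) -> pd.DataFrame:
    raw = pd.read_csv(out_dir / "pigments_raw.csv")
    df = pigments.summarize_table(raw, per_chl=cfg.pigment_units == "molar")
    df.to_csv(out_dir / "pigments.csv", index=False)
    return df


def stats_stage(cfg: RunConfig, out_dir: Path) -> pd.DataFrame:
    """Letter the per-PPFD growth metrics and fit the dark Fv/Fm vs
    Z/(V+A+Z) regression."""
    growth_df = pd.read_csv(out_dir / "growth.csv")
    parts = []
    for col in ("RGR", "lue_m2_per_mol"):
        t = stats.compare_groups_table(growth_df, col, "ppfd", alpha=cfg.alpha)
        t.insert(0, "variable", col)
        parts.append(t.rename(columns={"ppfd": "group"}))
    out = pd.concat(parts, ignore_index=True)
    out.to_csv(out_dir / "stats.csv", index=False)

    dark = pd.read_csv(out_dir / "dark_fvfm.csv")
    reg = stats.fit_linear(dark["z_frac_vaz"], dark["dark_fvfm"])
    pd.DataFrame(
        [{"slope": reg.slope, "intercept": reg.intercept,
          "r_squared": reg.r_squared, "p_slope": reg.p_slope, "n": reg.n}]
    ).to_csv(out_dir / "regression.csv", index=False)
    return out


_STAGES = ("simulate", "segment", "growth", "fluorescence", "pigments", "stats")


def run_all(cfg: RunConfig, out_dir, qc: bool = False) -> dict:
    """Run every stage in dependency order and write a JSON manifest.

    Any stage failure aborts with the failing stage named; outputs of the
    completed stages are retained for debugging.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "package_version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "warnings": [],
    }
    for stage in _STAGES:
        log.info("stage %s", stage)
        try:
            if stage == "simulate":
                simulate_stage(cfg, out_dir)
                files = ["manifest.csv", "fluor.csv", "pigments_raw.csv", "dark_fvfm.csv"]
            elif stage == "segment":
                segment_stage(cfg, out_dir, qc_dir=out_dir / "qc" if qc else None)
                files = ["areas.csv"]
            elif stage == "growth":
                growth_stage(cfg, out_dir)
                files = ["growth.csv"]
            elif stage == "fluorescence":
                df = fluorescence_stage(cfg, out_dir)
                manifest["warnings"].extend(df.attrs.get("warnings", []))
                files = ["psii.csv"]
            elif stage == "pigments":
                pigments_stage(cfg, out_dir)
                files = ["pigments.csv"]
            else:
                stats_stage(cfg, out_dir)
                files = ["stats.csv", "regression.csv"]
        except Exception as exc:
            manifest["failed_stage"] = stage
            (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "files": files,
            "rows": {f: _row_count(out_dir / f) for f in files},
        }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _row_count(path: Path) -> int:
    with open(path) as fh:
        return max(sum(1 for _ in fh) - 1, 0)
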