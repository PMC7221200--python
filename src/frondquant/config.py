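"""Run configuration: one YAML file shared by every CLI stage.

Defaults describe the standard layout — 3 dishes at each of four growth
PPFDs (100, 200, 500, 700 umol m^-2 s^-1), 4 days of growth imaged
daily — with per-PPFD synthetic scenario parameters chosen to follow the
qualitative trends of the real experiment (similar RGRs with a modest
rise, declining light-adapted efficiency, rising zeaxanthin).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional

import yaml

from .imaging import ColorThresholds, DishGeometry
from .synthetic import SceneSpec

__all__ = ["RunConfig", "load_config", "default_config"]

_DEFAULT_PPFDS = [100.0, 200.0, 500.0, 700.0]


def _default_rgr() -> Dict[float, float]:
    return {100.0: 0.20, 200.0: 0.22, 500.0: 0.24, 700.0: 0.25}


def _default_fvpfmp() -> Dict[float, float]:
    return {100.0: 0.68, 200.0: 0.60, 500.0: 0.46, 700.0: 0.40}


def _default_one_minus_qp() -> Dict[float, float]:
    return {100.0: 0.12, 200.0: 0.22, 500.0: 0.34, 700.0: 0.34}


def _default_fvfm_pre() -> Dict[float, float]:
    return {100.0: 0.79, 200.0: 0.77, 500.0: 0.74, 700.0: 0.72}


def _default_fvfm_post() -> Dict[float, float]:
    return {100.0: 0.815, 200.0: 0.805, 500.0: 0.79, 700.0: 0.78}


def _default_pigment_means() -> Dict[float, Dict[str, float]]:
    # arbitrary but trend-consistent concentrations (unit carried via
    # `pigment_units`): chlorophyll falls and xanthophylls rise with PPFD
    return {
        100.0: {"chl_a": 320.0, "chl_b": 110.0, "viola": 24.0, "anthera": 1.5,
                "zea": 0.5, "lutein": 55.0, "beta_car": 30.0, "neo": 12.0},
        200.0: {"chl_a": 300.0, "chl_b": 98.0, "viola": 24.0, "anthera": 2.5,
                "zea": 2.5, "lutein": 57.0, "beta_car": 30.0, "neo": 12.0},
        500.0: {"chl_a": 260.0, "chl_b": 80.0, "viola": 22.0, "anthera": 4.0,
                "zea": 9.0, "lutein": 62.0, "beta_car": 31.0, "neo": 11.0},
        700.0: {"chl_a": 240.0, "chl_b": 70.0, "viola": 20.0, "anthera": 5.0,
                "zea": 12.5, "lutein": 65.0, "beta_car": 32.0, "neo": 11.0},
    }


def _default_zea_drop() -> Dict[float, float]:
    return {100.0: 0.3, 200.0: 1.5, 500.0: 5.0, 700.0: 7.0}


@dataclass(frozen=True)
class RunConfig:
    ppfds: List[float] = field(default_factory=lambda: list(_DEFAULT_PPFDS))
    dishes_per_ppfd: int = 3
    t4_days: float = 4.0
    imaging_interval_days: float = 1.0
    seed: int = 0

    initial_area_m2: float = 1.6e-4
    rgr_by_ppfd: Dict[float, float] = field(default_factory=_default_rgr)

    true_FvpFmp: Dict[float, float] = field(default_factory=_default_fvpfmp)
    true_oneMinusQP: Dict[float, float] = field(default_factory=_default_one_minus_qp)
    dark_FvFm_pre: Dict[float, float] = field(default_factory=_default_fvfm_pre)
    dark_FvFm_post: Dict[float, float] = field(default_factory=_default_fvfm_post)
    fluor_noise_sd: float = 0.0

    pigment_means: Dict[float, Dict[str, float]] = field(default_factory=_default_pigment_means)
    zea_recovery_drop: Dict[float, float] = field(default_factory=_default_zea_drop)
    fvfm_slope: float = -0.3
    fvfm_intercept: float = 0.82
    pigment_noise_sd: float = 0.0
    pigment_units: str = "arbitrary"

    scene: SceneSpec = field(default_factory=SceneSpec)
    thresholds: ColorThresholds = field(default_factory=ColorThresholds)
    max_efficiency: float = 0.8
    recovered_fvfm_floor: float = 0.75
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.ppfds):
            raise ValueError("all PPFDs must be positive")
        if self.t4_days <= 0:
            raise ValueError("t4_days must be positive")
        if self.imaging_interval_days <= 0:
            raise ValueError("imaging_interval_days must be positive")
        if self.dishes_per_ppfd < 1:
            raise ValueError("dishes_per_ppfd must be >= 1")
        missing = [p for p in self.ppfds if p not in self.rgr_by_ppfd]
        if missing:
            raise ValueError(f"rgr_by_ppfd missing PPFDs: {missing}")

    @property
    def geometry(self) -> DishGeometry:
        return self.scene.geometry

    def dish_ids(self) -> Dict[str, float]:
        """dish_id -> growth PPFD, for the configured layout."""
        return {
            f"d{int(p)}-{i}": p
            for p in self.ppfds
            for i in range(1, self.dishes_per_ppfd + 1)
        }

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_to_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def default_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed)


def load_config(path: Optional[str] = None, seed: Optional[int] = None) -> RunConfig:
    """Load a YAML config; missing keys fall back to the defaults."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    kwargs = {}
    simple = {
        "ppfds", "dishes_per_ppfd", "t4_days", "imaging_interval_days", "seed",
        "initial_area_m2", "fluor_noise_sd", "fvfm_slope", "fvfm_intercept",
        "pigment_noise_sd", "pigment_units", "max_efficiency",
        "recovered_fvfm_floor", "alpha",
    }
    for key in simple & set(data):
        kwargs[key] = data[key]
    for key in ("rgr_by_ppfd", "true_FvpFmp", "true_oneMinusQP",
                "dark_FvFm_pre", "dark_FvFm_post", "zea_recovery_drop"):
        if key in data:
            kwargs[key] = {float(k): float(v) for k, v in data[key].items()}
    if "pigment_means" in data:
        kwargs["pigment_means"] = {
            float(k): {str(p): float(v) for p, v in m.items()}
            for k, m in data["pigment_means"].items()
        }
    if "scene" in data:
        sc = dict(data["scene"])
        for tup in ("dish_center_px", "background_color", "water_color",
                    "frond_color_mean", "frond_color_sd", "frond_axis_mm_range"):
            if tup in sc:
                sc[tup] = tuple(sc[tup])
        kwargs["scene"] = SceneSpec(**sc)
    if "thresholds" in data:
        kwargs["thresholds"] = ColorThresholds(**data["thresholds"])
    cfg = RunConfig(**kwargs)
    if seed is not None:
        cfg = cfg.with_seed(seed)
    return cfg
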