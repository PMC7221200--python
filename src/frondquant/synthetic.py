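"""Seeded synthetic data with known ground truth.

Three generators mirror the three raw inputs of a growth experiment:

* top-down dish photographs in which green elliptical "fronds" cover an
  exactly known, exponentially growing area of the water surface;
* fluorescence-yield tables constructed by inverting the PSII parameter
  definitions, so zero-noise tables round-trip exactly;
* pigment-concentration tables with configurable per-PPFD means, a
  pre/post-recovery zeaxanthin drop (re-epoxidised into violaxanthin so
  the V+A+Z pool stays recovery-stable), and dark Fv/Fm values
  co-generated on a configured line against Z/(V+A+Z).

Everything is bit-reproducible given the scenario seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from skimage import draw

from .imaging import DishGeometry, DishImage
from .pigments import PIGMENT_COLUMNS

__all__ = [
    "SceneSpec",
    "GrowthScenario",
    "FluorScenario",
    "PigmentScenario",
    "SyntheticDish",
    "generate_dish_series",
    "generate_fluorescence_table",
    "generate_pigment_table",
    "write_dish_series",
    "default_scene",
]


@dataclass(frozen=True)
class SceneSpec:
    """Rendering geometry and colors for one synthetic dish scene."""

    image_width_px: int = 560
    image_height_px: int = 560
    dish_center_px: Tuple[float, float] = (280.0, 280.0)
    dish_radius_px: float = 260.0
    metres_per_px: float = 0.0725 / 260.0  # 145-mm inner diameter dish
    background_color: Tuple[int, int, int] = (40, 38, 36)
    water_color: Tuple[int, int, int] = (168, 178, 186)
    frond_color_mean: Tuple[int, int, int] = (70, 150, 60)
    frond_color_sd: Tuple[float, float, float] = (8.0, 10.0, 8.0)
    frond_axis_mm_range: Tuple[float, float] = (1.4, 3.2)  # ellipse semi-axes
    mother_frond_darkening: float = 0.8
    mother_frond_fraction: float = 0.3
    max_packing_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dish_radius_px <= 0 or self.metres_per_px <= 0:
            raise ValueError("dish_radius_px and metres_per_px must be positive")
        r, c = self.dish_center_px
        if (
            r - self.dish_radius_px < 0
            or c - self.dish_radius_px < 0
            or r + self.dish_radius_px > self.image_height_px
            or c + self.dish_radius_px > self.image_width_px
        ):
            raise ValueError("dish must lie fully inside the image")
        for col in (self.background_color, self.water_color, self.frond_color_mean):
            if any(not (0 <= v <= 255) for v in col):
                raise ValueError("colors must be in [0, 255]")
        if not (0 < self.mother_frond_darkening <= 1):
            raise ValueError("mother_frond_darkening must be in (0, 1]")
        lo, hi = self.frond_axis_mm_range
        if not (0 < lo <= hi):
            raise ValueError("frond_axis_mm_range must be 0 < min <= max")

    @property
    def geometry(self) -> DishGeometry:
        return DishGeometry(
            center_px=self.dish_center_px,
            radius_px=self.dish_radius_px,
            metres_per_px=self.metres_per_px,
        )

    @property
    def water_area_m2(self) -> float:
        return self.geometry.water_area_m2


@dataclass(frozen=True)
class GrowthScenario:
    """Exponential area trajectory to render: FA(t) = FA0 * exp(RGR * t)."""

    initial_area_m2: float = 1.6e-4
    rgr_per_day: float = 0.22
    ppfd_umol_m2_s: float = 100.0
    duration_days: float = 4.0
    imaging_interval_days: float = 1.0

    def __post_init__(self) -> None:
        if self.initial_area_m2 <= 0:
            raise ValueError("initial_area_m2 must be positive")
        if self.duration_days <= 0 or self.imaging_interval_days <= 0:
            raise ValueError("durations must be positive")

    @property
    def imaging_days(self) -> List[float]:
        n = int(round(self.duration_days / self.imaging_interval_days))
        return [i * self.imaging_interval_days for i in range(n + 1)]

    def area_at(self, t: float) -> float:
        return self.initial_area_m2 * math.exp(self.rgr_per_day * t)


@dataclass(frozen=True)
class SyntheticDish:
    """One rendered photograph plus its ground truth."""

    image: DishImage
    frond_mask: np.ndarray  # H x W bool, the exact rendered frond pixels
    true_area_m2: float


def generate_dish_series(
    scene: SceneSpec, growth: GrowthScenario, dish_id: str = "dish"
) -> List[SyntheticDish]:
    """Render one image per imaging day with exactly known frond coverage.

    Fronds are ellipses with mild random eccentricity, placed by
    rejection sampling without overlap inside the water circle; ellipse
    sizes shrink when placement stalls so that target coverages near the
    packing limit remain reachable. After coarse placement, the mask is
    trimmed or grown pixel-by-pixel at frond boundaries so the rendered
    area matches the analytic target to within rounding (far inside the
    1% contract). ``true_area_m2`` is the pixel count times the pixel
    area.
    """
    max_area = growth.area_at(growth.duration_days)
    budget = scene.max_packing_fraction * scene.water_area_m2
    if max_area > budget:
        raise ValueError(
            f"scenario overflows the dish: final frond area {max_area:.3e} m^2 "
            f"exceeds {scene.max_packing_fraction:.0%} of the water surface "
            f"({budget:.3e} m^2); lower FA0, RGR or duration"
        )
    rng = np.random.default_rng(scene.seed)
    out = []
    for day in growth.imaging_days:
        target_m2 = growth.area_at(day)
        mask, fronds = _place_fronds(scene, target_m2, rng)
        image = _render(scene, mask, fronds, rng)
        out.append(
            SyntheticDish(
                image=DishImage(
                    pixels=image, dish_id=dish_id, day=day, geometry=scene.geometry
                ),
                frond_mask=mask,
                true_area_m2=float(mask.sum()) * scene.metres_per_px**2,
            )
        )
    return out


def _place_fronds(
    scene: SceneSpec, target_m2: float, rng: np.random.Generator
) -> Tuple[np.ndarray, List[dict]]:
    """Place non-overlapping ellipses totalling ``target_m2`` of coverage."""
    h, w = scene.image_height_px, scene.image_width_px
    mpp = scene.metres_per_px
    target_px = int(round(target_m2 / mpp**2))
    cr, cc = scene.dish_center_px
    R = scene.dish_radius_px

    mask = np.zeros((h, w), dtype=bool)
    fronds: List[dict] = []
    ax_lo = scene.frond_axis_mm_range[0] * 1e-3 / mpp
    ax_hi = scene.frond_axis_mm_range[1] * 1e-3 / mpp

    placed = 0
    while target_px - placed > max(4, 0.002 * target_px):
        remaining = target_px - placed
        a = rng.uniform(ax_lo, ax_hi)
        b = a * rng.uniform(0.6, 1.0)
        # never aim past the remaining area: shrink the ellipse to fit
        if math.pi * a * b > remaining:
            s = math.sqrt(remaining / (math.pi * a * b))
            a, b = max(a * s, 0.8), max(b * s, 0.8)
        theta = rng.uniform(0, math.pi)
        footprint = _try_place(mask, (cr, cc), R, a, b, theta, rng)
        while footprint is None and a > 1.0:
            a, b = a * 0.75, b * 0.75  # shrink to fill gaps near saturation
            footprint = _try_place(mask, (cr, cc), R, a, b, theta, rng)
        if footprint is None:
            raise RuntimeError(
                f"could not place a frond after bounded retries at "
                f"{placed / target_px:.0%} of the target coverage; "
                "the scene is too densely packed"
            )
        rr, cc_px = footprint
        mask[rr, cc_px] = True
        fronds.append({"rr": rr, "cc": cc_px, "center": (rr.mean(), cc_px.mean())})
        placed += rr.size

    _trim_to_target(mask, fronds, target_px, (cr, cc), R, rng)
    return mask, fronds


def _try_place(mask, center, R, a, b, theta, rng, tries: int = 200):
    h, w = mask.shape
    margin = max(a, b) + 1.5
    for _ in range(tries):
        rad = (R - margin) * math.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * math.pi)
        r0 = center[0] + rad * math.sin(ang)
        c0 = center[1] + rad * math.cos(ang)
        rr, cc = draw.ellipse(r0, c0, a, b, shape=(h, w), rotation=theta)
        if rr.size == 0:
            continue
        if not mask[rr, cc].any():
            return rr, cc
    return None


def _trim_to_target(mask, fronds, target_px, center, R, rng) -> None:
    """Adjust the mask at frond boundaries to hit ``target_px`` exactly."""
    surplus = int(mask.sum()) - target_px
    if surplus > 0:
        # peel outermost pixels of the most recent fronds
        for f in reversed(fronds):
            if surplus <= 0:
                break
            rr, cc = f["rr"], f["cc"]
            keep = mask[rr, cc]
            rr, cc = rr[keep], cc[keep]
            d2 = (rr - f["center"][0]) ** 2 + (cc - f["center"][1]) ** 2
            order = np.argsort(-d2)
            take = order[: min(surplus, rr.size)]
            mask[rr[take], cc[take]] = False
            surplus -= take.size
    elif surplus < 0:
        # grow frond boundaries one ring at a time inside the water circle
        deficit = -surplus
        h, w = mask.shape
        yy, xx = np.mgrid[0:h, 0:w]
        inside = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= (R - 1.0) ** 2
        while deficit > 0:
            from scipy.ndimage import binary_dilation

            ring = binary_dilation(mask) & ~mask & inside
            rr, cc = np.nonzero(ring)
            if rr.size == 0:
                raise RuntimeError("cannot grow fronds to the target area")
            take = rng.permutation(rr.size)[: min(deficit, rr.size)]
            mask[rr[take], cc[take]] = True
            deficit -= take.size


def _render(scene: SceneSpec, mask, fronds, rng) -> np.ndarray:
    h, w = scene.image_height_px, scene.image_width_px
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = np.asarray(scene.background_color, dtype=np.uint8)
    rr, cc = draw.disk(scene.dish_center_px, scene.dish_radius_px, shape=(h, w))
    img[rr, cc] = np.asarray(scene.water_color, dtype=np.uint8)
    n_mother = int(round(scene.mother_frond_fraction * len(fronds)))
    for i, f in enumerate(fronds):
        col = rng.normal(scene.frond_color_mean, scene.frond_color_sd)
        if i < n_mother:
            col = col * scene.mother_frond_darkening
        col = np.clip(col, 0, 255).astype(np.uint8)
        keep = mask[f["rr"], f["cc"]]
        img[f["rr"][keep], f["cc"][keep]] = col
    return img


def write_dish_series(
    series_by_dish: Mapping[str, List[SyntheticDish]], out_dir, seed: int
) -> pd.DataFrame:
    """Write images and ground-truth masks as PNG plus a CSV manifest."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for dish_id, series in series_by_dish.items():
        for d in series:
            stem = f"{dish_id}_day{d.image.day:g}"
            Image.fromarray(d.image.pixels).save(out / "images" / f"{stem}.png")
            Image.fromarray((d.frond_mask * np.uint8(255))).save(
                out / "masks" / f"{stem}.png"
            )
            rows.append(
                {
                    "dish_id": dish_id,
                    "day": d.image.day,
                    "true_area_m2": d.true_area_m2,
                    "image": f"images/{stem}.png",
                    "mask": f"masks/{stem}.png",
                    "seed": seed,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def default_scene(seed: int = 0) -> SceneSpec:
    return SceneSpec(seed=seed)


# ---------------------------------------------------------------------------
# fluorescence tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluorScenario:
    """Per-PPFD ground truth for synthetic fluorescence yields.

    Yields are built by inverting the parameter definitions: with base
    maximal yields ``fmp_light``/``fm_dark``,
    ``Fo' = Fm' * (1 - Fv'/Fm')`` and ``F = Fo' + (1-qP) * (Fm' - Fo')``,
    so zero-noise tables recover the true values exactly.
    """

    true_FvpFmp: Mapping[float, float]
    true_oneMinusQP: Mapping[float, float]
    dark_FvFm_pre: Mapping[float, float]
    dark_FvFm_post: Mapping[float, float]
    noise_sd: float = 0.0
    max_efficiency: float = 0.8
    fm_dark: float = 2.5
    fmp_light: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for ppfd, f in self.true_FvpFmp.items():
            if not (0.0 <= f <= self.max_efficiency):
                raise ValueError(
                    f"true Fv'/Fm'={f} at PPFD {ppfd} outside [0, "
                    f"{self.max_efficiency}]"
                )
        for vals in (self.true_oneMinusQP, self.dark_FvFm_pre, self.dark_FvFm_post):
            for ppfd, v in vals.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"value {v} at PPFD {ppfd} outside [0, 1]")


def generate_fluorescence_table(scn: FluorScenario, dishes_per_ppfd: int = 3) -> pd.DataFrame:
    """Emit raw-yield rows (light + dark pre/post recovery) per dish."""
    if dishes_per_ppfd < 1:
        raise ValueError("dishes_per_ppfd must be >= 1")
    rng = np.random.default_rng(scn.seed)
    rows = []
    for ppfd in sorted(scn.true_FvpFmp):
        f_true = scn.true_FvpFmp[ppfd]
        m_true = scn.true_oneMinusQP[ppfd]
        for d in range(1, dishes_per_ppfd + 1):
            dish_id = f"d{int(ppfd)}-{d}"
            fmp = scn.fmp_light
            fop = fmp * (1.0 - f_true)
            fss = fop + m_true * (fmp - fop)
            rows.append(
                _noisy_row(dish_id, ppfd, "light", rng, scn.noise_sd,
                           F=fss, Fmp=fmp, Fop=fop)
            )
            for state, fvfm in (
                ("dark_pre_recovery", scn.dark_FvFm_pre[ppfd]),
                ("dark_post_recovery", scn.dark_FvFm_post[ppfd]),
            ):
                fm = scn.fm_dark
                fo = fm * (1.0 - fvfm)
                rows.append(
                    _noisy_row(dish_id, ppfd, state, rng, scn.noise_sd, Fo=fo, Fm=fm)
                )
    return pd.DataFrame(
        rows, columns=["dish_id", "growth_ppfd", "state", "Fo", "Fm", "F", "Fmp", "Fop"]
    )


def _noisy_row(dish_id, ppfd, state, rng, sd, **yields) -> dict:
    row: Dict[str, object] = {"dish_id": dish_id, "growth_ppfd": ppfd, "state": state,
                              "Fo": np.nan, "Fm": np.nan, "F": np.nan,
                              "Fmp": np.nan, "Fop": np.nan}
    for _ in range(100):
        vals = {}
        for k, v in yields.items():
            factor = 1.0 + rng.normal(0.0, sd) if sd > 0 else 1.0
            vals[k] = max(v * factor, 1e-9) if v > 0 else v
        # keep physically ordered yields even under noise
        if "Fm" in vals and vals["Fm"] <= vals["Fo"]:
            continue
        if "Fmp" in vals and vals["Fmp"] < vals["Fop"]:
            continue
        row.update(vals)
        return row
    raise RuntimeError("noise level too high to generate physically ordered yields")


# ---------------------------------------------------------------------------
# pigment tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PigmentScenario:
    """Per-PPFD pigment means plus the recovery and Fv/Fm couplings.

    ``means`` maps PPFD -> {pigment -> pre-recovery concentration}.
    ``zea_recovery_drop`` is the zeaxanthin removed over the 30-min
    recovery; it is added back to violaxanthin so the V+A+Z pool is
    recovery-stable. Dark Fv/Fm is co-generated per sample as
    ``intercept + slope * Z/(V+A+Z)``.
    """

    means: Mapping[float, Mapping[str, float]]
    zea_recovery_drop: Mapping[float, float] = field(default_factory=dict)
    fvfm_slope: float = -0.3
    fvfm_intercept: float = 0.84
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not math.isfinite(self.fvfm_slope):
            raise ValueError("fvfm_slope must be finite")
        for ppfd, m in self.means.items():
            for pig in PIGMENT_COLUMNS:
                if m.get(pig, 0.0) < 0:
                    raise ValueError(f"negative mean for {pig} at PPFD {ppfd}")
            drop = self.zea_recovery_drop.get(ppfd, 0.0)
            if drop < 0 or drop > m.get("zea", 0.0):
                raise ValueError(
                    f"zea_recovery_drop at PPFD {ppfd} must be in [0, mean zea]"
                )


def generate_pigment_table(
    scn: PigmentScenario,
    samples_per_dish: int = 2,
    dishes_per_ppfd: int = 3,
    frond_area_m2: float = 1e-4,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Emit per-sample pigment rows and the co-generated dark Fv/Fm table.

    Each dish contributes ``samples_per_dish / 2`` pre/post sample pairs
    (the standard protocol uses exactly one pair). Returns
    ``(pigments, dark_fvfm)`` where the second table holds dish_id,
    growth_ppfd, recovery, z_frac_vaz and dark_fvfm on the configured
    line.
    """
    if samples_per_dish < 2 or samples_per_dish % 2:
        raise ValueError("samples_per_dish must be an even number >= 2")
    rng = np.random.default_rng(scn.seed)
    pig_rows, fvfm_rows = [], []
    for ppfd in sorted(scn.means):
        base = {pig: float(scn.means[ppfd].get(pig, 0.0)) for pig in PIGMENT_COLUMNS}
        drop = float(scn.zea_recovery_drop.get(ppfd, 0.0))
        for d in range(1, dishes_per_ppfd + 1):
            dish_id = f"d{int(ppfd)}-{d}"
            for pair in range(samples_per_dish // 2):
                noisy = {
                    pig: _positive_noise(v, scn.noise_sd, rng) for pig, v in base.items()
                }
                for recovery in ("pre", "post"):
                    conc = dict(noisy)
                    if recovery == "post":
                        conc["zea"] = max(conc["zea"] - drop, 0.0)
                        conc["viola"] = conc["viola"] + drop
                    row = {
                        "dish_id": dish_id,
                        "growth_ppfd": ppfd,
                        "recovery": recovery,
                        **conc,
                        "frond_area_m2": frond_area_m2,
                    }
                    if samples_per_dish > 2:
                        row["sample_pair"] = pair
                    pig_rows.append(row)
                    vaz = conc["viola"] + conc["anthera"] + conc["zea"]
                    zfrac = conc["zea"] / vaz if vaz > 0 else 0.0
                    fvfm_rows.append(
                        {
                            "dish_id": dish_id,
                            "growth_ppfd": ppfd,
                            "recovery": recovery,
                            "z_frac_vaz": zfrac,
                            "dark_fvfm": scn.fvfm_intercept + scn.fvfm_slope * zfrac,
                        }
                    )
    return pd.DataFrame(pig_rows), pd.DataFrame(fvfm_rows)


def _positive_noise(v: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0 or v == 0:
        return v
    return max(v * (1.0 + rng.normal(0.0, sd)), 1e-12)
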