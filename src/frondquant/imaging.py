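"""Frond-area measurement from top-down dish photographs.

A circular water-surface mask (from configured geometry, or detected via
a circular Hough transform) restricts the analysis to the dish interior;
green fronds are selected there by HSV color thresholding; frond area is
the coverage fraction of the water surface times the known water-surface
area.

Coordinates are (row, col) with origin at the top-left; areas are m^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color, draw, feature, morphology, transform

__all__ = [
    "DishGeometry",
    "DishImage",
    "WaterMask",
    "FrondAreaRecord",
    "ColorThresholds",
    "detect_water_mask",
    "threshold_fronds",
    "measure_frond_area",
    "load_dish_image",
    "write_area_csv",
    "write_qc_overlay",
]


@dataclass(frozen=True)
class DishGeometry:
    """Circle of the dish interior plus the pixel scale."""

    center_px: Tuple[float, float]  # (row, col)
    radius_px: float
    metres_per_px: float

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if self.metres_per_px <= 0:
            raise ValueError("metres_per_px must be positive")

    @property
    def water_area_m2(self) -> float:
        return math.pi * (self.radius_px * self.metres_per_px) ** 2


@dataclass
class DishImage:
    pixels: np.ndarray  # H x W x 3 uint8
    dish_id: str
    day: float
    geometry: Optional[DishGeometry] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] == 0 or px.shape[1] == 0:
            raise ValueError("pixels must be a non-empty H x W x 3 array")
        self.pixels = px


@dataclass(frozen=True)
class WaterMask:
    mask: np.ndarray  # H x W bool
    water_area_m2: float
    source: str  # "config" | "detected"
    geometry: DishGeometry

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("water mask is empty")
        if self.water_area_m2 <= 0:
            raise ValueError("water_area_m2 must be positive")


@dataclass(frozen=True)
class FrondAreaRecord:
    dish_id: str
    day: float
    coverage_fraction: float
    frond_area_m2: float


@dataclass(frozen=True)
class ColorThresholds:
    """HSV window for 'green frond' pixels (all channels scaled to [0, 1]).

    Defaults were calibrated against the synthetic dish generator: a green
    hue window around 1/3 plus minimum saturation and value cut-offs to
    reject the pale water surface and the dark background. ``min_blob_px``
    optionally removes connected components below that pixel count
    (off by default; the raw thresholding is the measurement).
    """

    hue_min: float = 0.17
    hue_max: float = 0.50
    sat_min: float = 0.22
    val_min: float = 0.12
    min_blob_px: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.hue_min < self.hue_max <= 1):
            raise ValueError("need 0 <= hue_min < hue_max <= 1")
        if not (0 <= self.sat_min <= 1 and 0 <= self.val_min <= 1):
            raise ValueError("sat_min and val_min must be in [0, 1]")
        if self.min_blob_px < 0:
            raise ValueError("min_blob_px must be >= 0")


def detect_water_mask(
    img: DishImage,
    geometry: Optional[DishGeometry] = None,
    auto_metres_per_px: Optional[float] = None,
) -> WaterMask:
    """Build the circular water-surface mask.

    With ``geometry`` given (preferred: fixed camera setup) the mask is
    the exact configured circle and ``water_area_m2 = pi * (r * mpp)^2``.
    Otherwise a circular Hough transform finds the dish; then
    ``auto_metres_per_px`` must supply the scale.
    """
    geom = geometry or img.geometry
    h, w = img.pixels.shape[:2]
    if geom is None:
        if auto_metres_per_px is None:
            raise ValueError("auto detection requires auto_metres_per_px for the scale")
        geom = _hough_dish_circle(img, auto_metres_per_px)
        source = "detected"
    else:
        source = "config"
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw.disk(geom.center_px, geom.radius_px, shape=(h, w))
    mask[rr, cc] = True
    return WaterMask(mask=mask, water_area_m2=geom.water_area_m2, source=source, geometry=geom)


def _hough_dish_circle(img: DishImage, metres_per_px: float) -> DishGeometry:
    gray = color.rgb2gray(img.pixels)
    edges = feature.canny(gray, sigma=2.0)
    h, w = gray.shape
    r_min = int(0.25 * min(h, w))
    r_max = int(0.49 * min(h, w))
    radii = np.arange(r_min, r_max, 2)
    if radii.size == 0:
        raise ValueError(f"image too small for dish detection ({img.dish_id})")
    hough = transform.hough_circle(edges, radii)
    accums, cx, cy, rad = transform.hough_circle_peaks(hough, radii, total_num_peaks=1)
    if accums.size == 0 or accums[0] < 0.2:
        raise ValueError(
            f"no plausible dish circle found in image for dish {img.dish_id!r} "
            f"(day {img.day})"
        )
    return DishGeometry(
        center_px=(float(cy[0]), float(cx[0])),
        radius_px=float(rad[0]),
        metres_per_px=metres_per_px,
    )


def threshold_fronds(
    img: DishImage, water: WaterMask, thresholds: ColorThresholds = ColorThresholds()
) -> np.ndarray:
    """Boolean mask of green-frond pixels inside the water mask."""
    hsv = color.rgb2hsv(img.pixels)
    mask = (
        (hsv[..., 0] >= thresholds.hue_min)
        & (hsv[..., 0] <= thresholds.hue_max)
        & (hsv[..., 1] >= thresholds.sat_min)
        & (hsv[..., 2] >= thresholds.val_min)
        & water.mask
    )
    if thresholds.min_blob_px > 0:
        # removes blobs strictly below min_blob_px pixels
        mask = morphology.remove_small_objects(mask, max_size=thresholds.min_blob_px - 1)
    return mask


def measure_frond_area(
    img: DishImage, water: WaterMask, thresholds: ColorThresholds = ColorThresholds()
) -> FrondAreaRecord:
    """Coverage fraction of the water surface times the water-surface area."""
    frond = threshold_fronds(img, water, thresholds)
    coverage = float(frond.sum()) / float(water.mask.sum())
    return FrondAreaRecord(
        dish_id=img.dish_id,
        day=img.day,
        coverage_fraction=coverage,
        frond_area_m2=coverage * water.water_area_m2,
    )


def load_dish_image(path, dish_id: str, day: float,
                    geometry: Optional[DishGeometry] = None) -> DishImage:
    """Read a PNG/JPEG/TIFF photograph as an 8-bit RGB dish image."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return DishImage(pixels=arr, dish_id=dish_id, day=day, geometry=geometry)


def write_area_csv(records: Iterable[FrondAreaRecord], path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "dish_id": r.dish_id,
                "day": r.day,
                "coverage_fraction": r.coverage_fraction,
                "frond_area_m2": r.frond_area_m2,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)
    return df


def write_qc_overlay(img: DishImage, water: WaterMask, frond_mask: np.ndarray, path) -> None:
    """Write the photo with frond-mask boundaries in red and the water
    circle in blue, for visual QC."""
    from skimage.segmentation import find_boundaries

    out = img.pixels.copy()
    out[find_boundaries(frond_mask, mode="outer")] = (255, 0, 0)
    out[find_boundaries(water.mask, mode="inner")] = (0, 80, 255)
    Image.fromarray(out).save(path)
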