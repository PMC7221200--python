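"""Exponential growth and light-budget model.

Implements the endpoint relative growth rate (RGR), the exponential
frond-area projection ``FA(t) = FA0 * exp(RGR * t)``, the photon flux
``PPFD * 0.0864 * FA(t)`` (mol day^-1), its closed-form time integral
("photons received"), and light-use efficiency (m^2 frond area produced
per mol photons received).

Units are fixed throughout: areas in m^2, time in days, PPFD in
umol photons m^-2 s^-1, photon doses in mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MOL_PER_UMOL_DAY",
    "GrowthFit",
    "PhotonBudget",
    "fit_rgr",
    "project_area",
    "photon_flux",
    "photons_received",
    "light_use_efficiency",
    "photon_dose_ratio",
    "photon_budget",
]

#: mol photons per day per (umol m^-2 s^-1 of PPFD per m^2 of area):
#: 1e-6 mol/umol * 86400 s/day.
MOL_PER_UMOL_DAY = 0.0864

#: below this |RGR| (day^-1) the dose integral switches to its series limit.
_RGR_EPS = 1e-12


@dataclass(frozen=True)
class GrowthFit:
    """Endpoint areas and the relative growth rate of one dish.

    ``RGR = (ln FA4 - ln FA0) / t4`` holds by construction.
    """

    dish_id: str
    FA0: float
    FA4: float
    t4: float
    RGR: float

    def __post_init__(self) -> None:
        if self.FA0 <= 0 or self.FA4 <= 0:
            raise ValueError("frond areas must be positive")
        if self.t4 <= 0:
            raise ValueError("t4 must be positive")

    @classmethod
    def from_endpoints(cls, dish_id: str, FA0: float, FA4: float, t4: float) -> "GrowthFit":
        if FA0 <= 0 or FA4 <= 0:
            raise ValueError("frond areas must be positive")
        if t4 <= 0:
            raise ValueError("t4 must be positive")
        rgr = (math.log(FA4) - math.log(FA0)) / t4
        return cls(dish_id=dish_id, FA0=FA0, FA4=FA4, t4=t4, RGR=rgr)


@dataclass(frozen=True)
class PhotonBudget:
    """Integrated photon dose and light-use efficiency for one dish."""

    dish_id: str
    PPFD: float
    photons_received_mol: float
    light_use_efficiency_m2_per_mol: float


def fit_rgr(areas: Sequence, method: str = "endpoint") -> GrowthFit:
    """Fit the relative growth rate for one dish's area time series.

    Parameters
    ----------
    areas
        Records with ``dish_id``, ``day`` and ``frond_area_m2`` attributes
        (or mappings with those keys), all for the same dish.
    method
        ``"endpoint"`` (default) uses the first and last timepoints, i.e.
        the log-ratio of endpoint areas over the elapsed time.
        ``"regression"`` fits ln(area) vs day by ordinary least squares
        and reports the slope as RGR; FA0/FA4 are then the fitted values
        at the first and last day so that the RGR identity still holds.
    """
    recs = [_as_record(a) for a in areas]
    if len(recs) < 2:
        raise ValueError("need at least two timepoints to fit a growth rate")
    dish_ids = {r[0] for r in recs}
    if len(dish_ids) != 1:
        raise ValueError(f"records span multiple dishes: {sorted(dish_ids)}")
    recs.sort(key=lambda r: r[1])
    days = np.array([r[1] for r in recs], dtype=float)
    vals = np.array([r[2] for r in recs], dtype=float)
    if np.any(vals <= 0):
        raise ValueError("all frond areas must be positive")
    t4 = float(days[-1] - days[0])
    if t4 <= 0:
        raise ValueError("timepoints must span a positive interval")
    dish_id = next(iter(dish_ids))

    if method == "endpoint":
        return GrowthFit.from_endpoints(dish_id, float(vals[0]), float(vals[-1]), t4)
    if method == "regression":
        slope, intercept = np.polyfit(days - days[0], np.log(vals), 1)
        fa0 = math.exp(intercept)
        fa4 = math.exp(intercept + slope * t4)
        return GrowthFit(dish_id=dish_id, FA0=fa0, FA4=fa4, t4=t4, RGR=float(slope))
    raise ValueError(f"unknown method {method!r}")


def _as_record(a) -> tuple:
    if hasattr(a, "dish_id"):
        return (a.dish_id, float(a.day), float(a.frond_area_m2))
    return (a["dish_id"], float(a["day"]), float(a["frond_area_m2"]))


def project_area(fit: GrowthFit, t: float) -> float:
    """Frond area at time ``t`` days: ``FA0 * exp(RGR * t)``."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return fit.FA0 * math.exp(fit.RGR * t)


def photon_flux(fit: GrowthFit, PPFD: float, t: float) -> float:
    """Instantaneous photon receipt rate at time ``t``, in mol day^-1."""
    return PPFD * MOL_PER_UMOL_DAY * project_area(fit, t)


def photons_received(fit: GrowthFit, PPFD: float) -> float:
    """Photon dose over [0, t4] in mol: the closed-form flux integral.

    ``PPFD * 0.0864 * FA0 * (exp(RGR*t4) - 1) / RGR``, with the
    ``RGR -> 0`` limit ``PPFD * 0.0864 * FA0 * t4`` taken via a
    first-order series when |RGR| is below 1e-12 day^-1.
    """
    if PPFD < 0:
        raise ValueError("PPFD must be non-negative")
    rgr, t4 = fit.RGR, fit.t4
    if abs(rgr) < _RGR_EPS:
        growth_term = t4 * (1.0 + 0.5 * rgr * t4)
    else:
        growth_term = math.expm1(rgr * t4) / rgr
    return PPFD * MOL_PER_UMOL_DAY * fit.FA0 * growth_term


def light_use_efficiency(fit: GrowthFit, PPFD: float) -> float:
    """Frond area produced per mol photons received, m^2 mol^-1.

    ``(FA4 - FA0) / photons_received``. For an endpoint fit this reduces
    algebraically to ``RGR / (0.0864 * PPFD)``.
    """
    if PPFD <= 0:
        raise ValueError("light-use efficiency is undefined at PPFD <= 0")
    return (fit.FA4 - fit.FA0) / photons_received(fit, PPFD)


def photon_dose_ratio(fit_a: GrowthFit, PPFD_a: float, fit_b: GrowthFit, PPFD_b: float) -> float:
    """Percent increase in photon dose of scenario b over scenario a.

    ``100 * (dose_b - dose_a) / dose_a``. With equal FA0, RGR and t4 this
    is the bare PPFD ratio: 100 vs 700 gives exactly 600%.
    """
    dose_a = photons_received(fit_a, PPFD_a)
    dose_b = photons_received(fit_b, PPFD_b)
    if dose_a == 0:
        raise ValueError("reference photon dose is zero; ratio undefined")
    return 100.0 * (dose_b - dose_a) / dose_a


def photon_budget(fit: GrowthFit, PPFD: float) -> PhotonBudget:
    """Bundle the dose integral and light-use efficiency for one dish."""
    dose = photons_received(fit, PPFD)
    return PhotonBudget(
        dish_id=fit.dish_id,
        PPFD=PPFD,
        photons_received_mol=dose,
        light_use_efficiency_m2_per_mol=light_use_efficiency(fit, PPFD),
    )


def growth_table(area_records: Iterable, ppfd_by_dish: dict, method: str = "endpoint"):
    """Group area records by dish, fit RGR, and attach photon budgets.

    Returns a pandas DataFrame with columns
    dish_id, FA0, FA4, t4, RGR, ppfd, photons_received_mol, lue_m2_per_mol.
    """
    import pandas as pd

    by_dish: dict = {}
    for rec in area_records:
        d = _as_record(rec)
        by_dish.setdefault(d[0], []).append(rec)
    rows = []
    for dish_id in sorted(by_dish):
        fit = fit_rgr(by_dish[dish_id], method=method)
        ppfd = float(ppfd_by_dish[dish_id])
        budget = photon_budget(fit, ppfd)
        rows.append(
            {
                "dish_id": dish_id,
                "FA0": fit.FA0,
                "FA4": fit.FA4,
                "t4": fit.t4,
                "RGR": fit.RGR,
                "ppfd": ppfd,
                "photons_received_mol": budget.photons_received_mol,
                "lue_m2_per_mol": budget.light_use_efficiency_m2_per_mol,
            }
        )
    return pd.DataFrame(rows)
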