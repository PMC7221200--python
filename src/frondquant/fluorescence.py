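"""PSII chlorophyll-fluorescence parameters and excitation-energy partitioning.

From raw yields (Fo, Fm dark; F, Fm', Fo' light) derive Fv/Fm, Fv'/Fm',
qP and 1-qP, then split absorbed photons into photochemistry
(P = Fv'/Fm' x qP), thermal dissipation (D = max_efficiency - Fv'/Fm')
and excess (E = Fv'/Fm' x (1-qP)), plus their products with the incident
PPFD. P + D + E equals the assumed maximum usable fraction (0.8 by
default) as an algebraic identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

__all__ = [
    "MAX_EFFICIENCY_DEFAULT",
    "RECOVERED_FVFM_FLOOR_DEFAULT",
    "FluorRecord",
    "DerivedPSII",
    "EnergyPartition",
    "derive_psii",
    "partition_energy",
    "recovery_delta",
    "process_table",
]

#: assumed maximum fraction of absorbed photons usable in photochemistry.
MAX_EFFICIENCY_DEFAULT = 0.8

#: post-recovery dark Fv/Fm below this flags possible photoinhibition, in
#: which case the D = max_efficiency - Fv'/Fm' partitioning is not valid.
RECOVERED_FVFM_FLOOR_DEFAULT = 0.75

_STATES = ("light", "dark_pre_recovery", "dark_post_recovery")


@dataclass(frozen=True)
class FluorRecord:
    """Raw fluorescence yields for one dish in one measurement state.

    Dark states carry (Fo, Fm); the light state carries (F, Fmp, Fop).
    """

    dish_id: str
    growth_ppfd: float
    state: str
    Fo: Optional[float] = None
    Fm: Optional[float] = None
    F: Optional[float] = None
    Fmp: Optional[float] = None
    Fop: Optional[float] = None

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"state must be one of {_STATES}, got {self.state!r}")
        for name in ("Fo", "Fm", "F", "Fmp", "Fop"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.state != "light":
            if self.Fo is None or self.Fm is None:
                raise ValueError("dark records need Fo and Fm")
            if self.Fm <= self.Fo:
                raise ValueError("dark records require Fm > Fo")
        else:
            if self.F is None or self.Fmp is None or self.Fop is None:
                raise ValueError("light records need F, Fmp and Fop")
            if self.Fmp < self.Fop:
                raise ValueError("light records require Fmp >= Fop")


@dataclass(frozen=True)
class DerivedPSII:
    """Derived PSII parameters for one record.

    ``degenerate`` marks Fmp == Fop (qP undefined); ``f_out_of_range``
    marks steady-state F outside [Fop, Fmp].
    """

    dish_id: str
    state: str
    FvFm: Optional[float] = None
    FvpFmp: Optional[float] = None
    qP: Optional[float] = None
    oneMinusQP: Optional[float] = None
    degenerate: bool = False
    f_out_of_range: bool = False


@dataclass(frozen=True)
class EnergyPartition:
    """P/D/E allocation fractions of absorbed photons and their PPFD rates."""

    P: float
    D: float
    E: float
    max_efficiency: float
    ppfd_i: float
    rate_P: float = field(init=False)
    rate_D: float = field(init=False)
    rate_E: float = field(init=False)
    valid: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "rate_P", self.P * self.ppfd_i)
        object.__setattr__(self, "rate_D", self.D * self.ppfd_i)
        object.__setattr__(self, "rate_E", self.E * self.ppfd_i)


def derive_psii(rec: FluorRecord, clamp_f: bool = False) -> DerivedPSII:
    """Compute Fv/Fm (dark) or Fv'/Fm', qP, 1-qP (light) from raw yields.

    ``1 - qP = (F - Fo') / (Fm' - Fo')``. If F falls outside
    [Fo', Fm'] a warning is issued and the record is flagged; qP is
    clamped into [0, 1] only when ``clamp_f=True``.
    """
    if rec.state != "light":
        return DerivedPSII(
            dish_id=rec.dish_id, state=rec.state, FvFm=(rec.Fm - rec.Fo) / rec.Fm
        )
    if rec.Fmp == rec.Fop:
        return DerivedPSII(
            dish_id=rec.dish_id,
            state=rec.state,
            FvpFmp=0.0,
            degenerate=True,
        )
    fvpfmp = (rec.Fmp - rec.Fop) / rec.Fmp
    one_minus_qp = (rec.F - rec.Fop) / (rec.Fmp - rec.Fop)
    out_of_range = not (0.0 <= one_minus_qp <= 1.0)
    if out_of_range:
        warnings.warn(
            f"dish {rec.dish_id}: steady-state F={rec.F} outside [Fo'={rec.Fop}, "
            f"Fm'={rec.Fmp}]; qP out of [0, 1]",
            stacklevel=2,
        )
        if clamp_f:
            one_minus_qp = min(max(one_minus_qp, 0.0), 1.0)
    return DerivedPSII(
        dish_id=rec.dish_id,
        state=rec.state,
        FvpFmp=fvpfmp,
        qP=1.0 - one_minus_qp,
        oneMinusQP=one_minus_qp,
        f_out_of_range=out_of_range,
    )


def partition_energy(
    d: DerivedPSII,
    ppfd_i: float,
    max_efficiency: float = MAX_EFFICIENCY_DEFAULT,
) -> EnergyPartition:
    """Partition absorbed photons into P, D and E fractions.

    P = Fv'/Fm' x qP; D = max_efficiency - Fv'/Fm'; E = Fv'/Fm' x (1-qP).
    D < 0 (Fv'/Fm' above the assumed maximum) is reported as-is with a
    warning and ``valid=False`` — never silently clamped.
    """
    if d.FvpFmp is None:
        raise ValueError("partition_energy requires a light-state record with Fv'/Fm'")
    if d.degenerate:
        # Fmp == Fop: no variable fluorescence; all absorbed light is
        # dissipated or lost, and qP is undefined.
        return EnergyPartition(
            P=0.0, D=max_efficiency, E=0.0,
            max_efficiency=max_efficiency, ppfd_i=ppfd_i, valid=False,
        )
    if d.qP is None:
        raise ValueError("qP undefined; cannot partition")
    p = d.FvpFmp * d.qP
    dd = max_efficiency - d.FvpFmp
    e = d.FvpFmp * (1.0 - d.qP)
    valid = True
    if dd < 0:
        warnings.warn(
            f"Fv'/Fm'={d.FvpFmp:.4f} exceeds max_efficiency={max_efficiency}; "
            "thermal dissipation fraction is negative",
            stacklevel=2,
        )
        valid = False
    return EnergyPartition(P=p, D=dd, E=e, max_efficiency=max_efficiency,
                           ppfd_i=ppfd_i, valid=valid)


def recovery_delta(pre: DerivedPSII, post: DerivedPSII) -> float:
    """Change in dark Fv/Fm over the low-light recovery period.

    Positive values indicate relaxation of sustained thermal dissipation.
    """
    if pre.dish_id != post.dish_id:
        raise ValueError(f"dish mismatch: {pre.dish_id!r} vs {post.dish_id!r}")
    if pre.FvFm is None or post.FvFm is None:
        raise ValueError("recovery_delta requires dark-state records")
    return post.FvFm - pre.FvFm


def process_table(
    table: pd.DataFrame,
    max_efficiency: float = MAX_EFFICIENCY_DEFAULT,
    recovered_fvfm_floor: float = RECOVERED_FVFM_FLOOR_DEFAULT,
    clamp_f: bool = False,
) -> pd.DataFrame:
    """Derive the per-dish PSII summary from a raw fluorescence table.

    Expects columns dish_id, growth_ppfd, state, Fo, Fm, F, Fmp, Fop with
    one light, one dark_pre_recovery and one dark_post_recovery row per
    dish. The ``partition_valid`` flag requires both a non-degenerate
    light record and a post-recovery dark Fv/Fm at or above
    ``recovered_fvfm_floor`` (absence of photoinhibition).
    """
    rows = []
    for dish_id, grp in table.groupby("dish_id", sort=True):
        by_state = {}
        for _, r in grp.iterrows():
            rec = FluorRecord(
                dish_id=str(dish_id),
                growth_ppfd=float(r["growth_ppfd"]),
                state=str(r["state"]),
                Fo=_maybe(r, "Fo"),
                Fm=_maybe(r, "Fm"),
                F=_maybe(r, "F"),
                Fmp=_maybe(r, "Fmp"),
                Fop=_maybe(r, "Fop"),
            )
            if rec.state in by_state:
                raise ValueError(f"duplicate {rec.state} row for dish {dish_id}")
            by_state[rec.state] = rec
        missing = set(_STATES) - set(by_state)
        if missing:
            raise ValueError(f"dish {dish_id} missing states: {sorted(missing)}")
        ppfd = by_state["light"].growth_ppfd
        d_light = derive_psii(by_state["light"], clamp_f=clamp_f)
        d_pre = derive_psii(by_state["dark_pre_recovery"])
        d_post = derive_psii(by_state["dark_post_recovery"])
        part = partition_energy(d_light, ppfd_i=ppfd, max_efficiency=max_efficiency)
        recovered = d_post.FvFm >= recovered_fvfm_floor
        rows.append(
            {
                "dish_id": str(dish_id),
                "growth_ppfd": ppfd,
                "FvFm_pre": d_pre.FvFm,
                "FvFm_post": d_post.FvFm,
                "recovery_delta": d_post.FvFm - d_pre.FvFm,
                "FvpFmp": d_light.FvpFmp,
                "qP": d_light.qP,
                "oneMinusQP": d_light.oneMinusQP,
                "P": part.P,
                "D": part.D,
                "E": part.E,
                "rate_P": part.rate_P,
                "rate_D": part.rate_D,
                "rate_E": part.rate_E,
                "degenerate": d_light.degenerate,
                "f_out_of_range": d_light.f_out_of_range,
                "partition_valid": bool(part.valid and recovered and not d_light.degenerate),
            }
        )
    return pd.DataFrame(rows)


def _maybe(row, key) -> Optional[float]:
    v = row.get(key)
    if v is None or pd.isna(v):
        return None
    return float(v)
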