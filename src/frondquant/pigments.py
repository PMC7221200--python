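"""Pigment-pool arithmetic and reporting conventions.

Per dish, two samples are harvested: one before and one after a 30-min
low-light recovery. Pigments whose concentration is stable over that
window (chlorophylls a and b, lutein, beta-carotene, the xanthophyll
cycle pool V+A+Z, and total carotenoids) are reported as the mean of the
two samples; zeaxanthin is kept separate per recovery state, with the
pre-recovery value as the default reported level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "PIGMENT_COLUMNS",
    "PigmentSample",
    "PigmentSummary",
    "summarize_dish",
    "summarize_table",
    "per_chlorophyll",
    "zeaxanthin_retention",
]

PIGMENT_COLUMNS = (
    "chl_a",
    "chl_b",
    "viola",
    "anthera",
    "zea",
    "lutein",
    "beta_car",
    "neo",
)


@dataclass(frozen=True)
class PigmentSample:
    """Per-area pigment concentrations of one sample (one recovery state)."""

    dish_id: str
    growth_ppfd: float
    recovery: str  # "pre" | "post"
    chl_a: float
    chl_b: float
    viola: float
    anthera: float
    zea: float
    lutein: float
    beta_car: float
    neo: float
    frond_area_m2: float = 1.0

    def __post_init__(self) -> None:
        if self.recovery not in ("pre", "post"):
            raise ValueError(f"recovery must be 'pre' or 'post', got {self.recovery!r}")
        for name in PIGMENT_COLUMNS:
            if getattr(self, name) < 0:
                raise ValueError(f"negative concentration for {name}")
        if self.frond_area_m2 <= 0:
            raise ValueError("frond_area_m2 must be positive")

    @property
    def vaz(self) -> float:
        return self.viola + self.anthera + self.zea

    @property
    def total_car(self) -> float:
        return self.lutein + self.beta_car + self.vaz + self.neo


@dataclass(frozen=True)
class PigmentSummary:
    """Reported pigment pools and ratios for one dish."""

    dish_id: str
    growth_ppfd: float
    chl_a: float
    chl_b: float
    chl_ab: float
    chl_a_over_b: float
    lutein: float
    beta_car: float
    vaz: float
    total_car: float
    zea_pre: float
    zea_post: float
    z_frac_vaz_pre: Optional[float]
    z_frac_vaz_post: Optional[float]

    @property
    def zea(self) -> float:
        """Default reported zeaxanthin: the pre-recovery level."""
        return self.zea_pre

    @property
    def z_frac_vaz(self) -> Optional[float]:
        """Default reported Z/(V+A+Z): the pre-recovery fraction."""
        return self.z_frac_vaz_pre


def summarize_dish(pre: PigmentSample, post: PigmentSample) -> PigmentSummary:
    """Apply the pre/post averaging convention to one dish's sample pair.

    Stable pigments are averaged across the two samples; the V+A+Z pool
    is averaged as a pool (mean of the pre pool and the post pool), and
    zeaxanthin is kept per recovery state.
    """
    if pre.recovery != "pre" or post.recovery != "post":
        raise ValueError("expected one 'pre' and one 'post' sample, in that order")
    if pre.dish_id != post.dish_id:
        raise ValueError(f"dish mismatch: {pre.dish_id!r} vs {post.dish_id!r}")
    chl_a = (pre.chl_a + post.chl_a) / 2.0
    chl_b = (pre.chl_b + post.chl_b) / 2.0
    chl_ab = chl_a + chl_b
    if chl_b == 0:
        raise ValueError("chl_b is zero; chlorophyll a/b ratio undefined")
    return PigmentSummary(
        dish_id=pre.dish_id,
        growth_ppfd=pre.growth_ppfd,
        chl_a=chl_a,
        chl_b=chl_b,
        chl_ab=chl_ab,
        chl_a_over_b=chl_a / chl_b,
        lutein=(pre.lutein + post.lutein) / 2.0,
        beta_car=(pre.beta_car + post.beta_car) / 2.0,
        vaz=(pre.vaz + post.vaz) / 2.0,
        total_car=(pre.total_car + post.total_car) / 2.0,
        zea_pre=pre.zea,
        zea_post=post.zea,
        z_frac_vaz_pre=(pre.zea / pre.vaz) if pre.vaz > 0 else None,
        z_frac_vaz_post=(post.zea / post.vaz) if post.vaz > 0 else None,
    )


def per_chlorophyll(summary: PigmentSummary) -> dict:
    """Carotenoid pools divided by total chlorophyll (a+b).

    Meaningful as mol/mol only when the input concentrations share a
    molar basis; the caller is responsible for declaring that.
    """
    if summary.chl_ab <= 0:
        raise ValueError("chl_ab must be positive")
    return {
        "lutein_per_chl": summary.lutein / summary.chl_ab,
        "beta_car_per_chl": summary.beta_car / summary.chl_ab,
        "vaz_per_chl": summary.vaz / summary.chl_ab,
        "total_car_per_chl": summary.total_car / summary.chl_ab,
        "zea_per_chl": summary.zea_pre / summary.chl_ab,
    }


def summarize_table(table: pd.DataFrame, per_chl: bool = False) -> pd.DataFrame:
    """Summarize a raw pigment table (one pre + one post row per dish).

    Expects the columns dish_id, growth_ppfd, recovery, chl_a, chl_b,
    viola, anthera, zea, lutein, beta_car, neo, frond_area_m2.
    """
    rows = []
    for dish_id, grp in table.groupby("dish_id", sort=True):
        samples = {}
        for _, r in grp.iterrows():
            s = PigmentSample(
                dish_id=str(dish_id),
                growth_ppfd=float(r["growth_ppfd"]),
                recovery=str(r["recovery"]),
                frond_area_m2=float(r.get("frond_area_m2", 1.0)),
                **{c: float(r[c]) for c in PIGMENT_COLUMNS},
            )
            if s.recovery in samples:
                raise ValueError(f"duplicate {s.recovery!r} sample for dish {dish_id}")
            samples[s.recovery] = s
        if set(samples) != {"pre", "post"}:
            raise ValueError(
                f"dish {dish_id} needs exactly one pre and one post sample, "
                f"got {sorted(samples)}"
            )
        summ = summarize_dish(samples["pre"], samples["post"])
        row = {
            "dish_id": summ.dish_id,
            "growth_ppfd": summ.growth_ppfd,
            "chl_a": summ.chl_a,
            "chl_b": summ.chl_b,
            "chl_ab": summ.chl_ab,
            "chl_a_over_b": summ.chl_a_over_b,
            "lutein": summ.lutein,
            "beta_car": summ.beta_car,
            "vaz": summ.vaz,
            "total_car": summ.total_car,
            "zea_pre": summ.zea_pre,
            "zea_post": summ.zea_post,
            "z_frac_vaz_pre": summ.z_frac_vaz_pre,
            "z_frac_vaz_post": summ.z_frac_vaz_post,
        }
        if per_chl:
            row.update(per_chlorophyll(summ))
        rows.append(row)
    return pd.DataFrame(rows)


def zeaxanthin_retention(summaries: Iterable[PigmentSummary]) -> pd.DataFrame:
    """Per-PPFD mean and sd of Z/(V+A+Z), pre and post recovery.

    Dishes with an empty xanthophyll-cycle pool are flagged and excluded
    from the statistics of their recovery state.
    """
    recs = []
    for s in summaries:
        for state, frac in (("pre", s.z_frac_vaz_pre), ("post", s.z_frac_vaz_post)):
            recs.append(
                {
                    "dish_id": s.dish_id,
                    "growth_ppfd": s.growth_ppfd,
                    "recovery": state,
                    "z_frac_vaz": frac,
                    "undefined_pool": frac is None,
                }
            )
    df = pd.DataFrame(recs)
    ok = df[~df["undefined_pool"]]
    out = (
        ok.groupby(["growth_ppfd", "recovery"])["z_frac_vaz"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    n_flagged = int(df["undefined_pool"].sum())
    out.attrs["n_flagged_undefined"] = n_flagged
    return out
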