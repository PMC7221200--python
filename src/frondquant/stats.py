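"""Group statistics: one-way ANOVA, Tukey-Kramer HSD with compact letter
display, and simple linear regression.

The studentized-range distribution comes from scipy; the compact-letter
assignment (insert-and-absorb) is implemented here because the letters
are the reported output surface.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "GroupComparison",
    "RegressionResult",
    "one_way_anova",
    "tukey_kramer",
    "compact_letters",
    "fit_linear",
    "compare_groups_table",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float


@dataclass(frozen=True)
class GroupComparison:
    """ANOVA + Tukey-Kramer pairwise table + compact letters."""

    groups: dict
    anova: AnovaResult
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, se, q, p_adj, significant
    letters: dict
    alpha: float = 0.05
    means: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


def _clean_groups(groups: Mapping[str, Sequence[float]]) -> dict:
    out = {}
    for label, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} has n < 2")
        out[label] = arr
    if len(out) < 2:
        raise ValueError("need at least two groups")
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical between/within sums-of-squares decomposition."""
    g = _clean_groups(groups)
    all_vals = np.concatenate(list(g.values()))
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in g.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in g.values())
    df_between = len(g) - 1
    df_within = all_vals.size - len(g)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = 0.0 if ss_between == 0 else math.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f = ms_between / ms_within
        p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(F=float(f), df_between=df_between, df_within=df_within,
                       p=p, ms_within=float(ms_within))


def tukey_kramer(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> GroupComparison:
    """All-pairs Tukey-Kramer comparisons with compact letter display.

    For each pair, ``q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))``
    with the adjusted p-value from the studentized-range distribution at
    k groups and the within-group degrees of freedom. Two groups share a
    letter iff their adjusted p >= alpha.
    """
    g = _clean_groups(groups)
    anova = one_way_anova(g)
    labels = sorted(g, key=lambda lab: g[lab].mean())
    k = len(labels)
    rows = []
    sig_pairs = set()
    for a, b in itertools.combinations(labels, 2):
        na, nb = g[a].size, g[b].size
        diff = g[b].mean() - g[a].mean()
        se = math.sqrt(anova.ms_within / 2.0 * (1.0 / na + 1.0 / nb))
        if se == 0:
            q = 0.0 if diff == 0 else math.inf
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, anova.df_within))
        significant = p_adj < alpha
        if significant:
            sig_pairs.add(frozenset((a, b)))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": diff,
                "se": se,
                "q": q,
                "p_adj": p_adj,
                "significant": significant,
            }
        )
    letters = compact_letters(labels, sig_pairs)
    return GroupComparison(
        groups={lab: g[lab].tolist() for lab in labels},
        anova=anova,
        pairwise=pd.DataFrame(rows),
        letters=letters,
        alpha=alpha,
        means={lab: float(g[lab].mean()) for lab in labels},
    )


def compact_letters(ordered_labels: Sequence, sig_pairs: set) -> dict:
    """Insert-and-absorb compact letter display.

    ``sig_pairs`` holds frozensets of label pairs declared significantly
    different. Returns label -> letter string such that two labels share
    at least one letter iff their pair is NOT in ``sig_pairs``.
    """
    labels = list(ordered_labels)
    # columns are sets of mutually non-different labels
    columns: list[frozenset] = [frozenset(labels)]
    for pair in sorted(sig_pairs, key=lambda p: sorted(map(str, p))):
        a, b = sorted(pair, key=str)
        split: list[frozenset] = []
        for col in columns:
            if a in col and b in col:
                split.append(col - {a})
                split.append(col - {b})
            else:
                split.append(col)
        # absorb: keep only columns that are not subsets of another column
        split = [c for c in set(split) if c]
        columns = [c for c in split if not any(c < other for other in split)]
    # order columns by the position of their first member for stable letters
    pos = {lab: i for i, lab in enumerate(labels)}
    columns.sort(key=lambda c: min(pos[lab] for lab in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for i, col in enumerate(columns):
        letter = alphabet[i] if i < len(alphabet) else f"({i})"
        for lab in labels:
            if lab in col:
                out[lab] += letter
    return out


def fit_linear(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least-squares line with r^2 and the slope's p-value."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least three points")
    if np.all(xa == xa[0]):
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(xa, ya)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope=float(res.pvalue),
        n=int(xa.size),
    )


def compare_groups_table(
    table: pd.DataFrame, value: str, group: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Group a long table and report mean, sd, n and Tukey letters per group."""
    groups = {str(k): v[value].tolist() for k, v in table.groupby(group)}
    cmp = tukey_kramer(groups, alpha=alpha)
    rows = []
    for lab in cmp.letters:
        vals = np.asarray(cmp.groups[lab])
        rows.append(
            {
                group: lab,
                "n": vals.size,
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "letters": cmp.letters[lab],
                "anova_F": cmp.anova.F,
                "anova_p": cmp.anova.p,
            }
        )
    return pd.DataFrame(rows)
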