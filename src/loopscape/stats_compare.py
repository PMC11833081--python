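"""Group comparison of distance distributions.

One-way ANOVA across named groups of per-frame COM distances, followed by
pairwise two-sided t comparisons with a Dunn-Sidak multiple-testing
correction, p_adj = 1 - (1 - p)^m over the m = G(G-1)/2 pairs.

Caveat: consecutive MD frames are autocorrelated, so frame-level p-values
are anti-conservative.  No effective-sample-size correction is applied
here; treat significance on raw frames as an upper bound of evidence and
prefer per-simulation means where replicate simulations exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "GroupedDistances",
    "PairwiseComparison",
    "ComparisonResult",
    "sidak_adjust",
    "anova_oneway",
    "compare_groups",
]


@dataclass
class GroupedDistances:
    """Named groups of distances; at least two groups of two values each."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise InputError("need at least two groups")
        clean: dict[str, np.ndarray] = {}
        for name, vals in self.groups.items():
            arr = np.asarray(vals, dtype=float)
            if arr.ndim != 1 or arr.size < 2:
                raise InputError(f"group {name!r} needs >= 2 values")
            if not np.all(np.isfinite(arr)):
                raise InputError(f"group {name!r} contains non-finite values")
            clean[name] = arr
        self.groups = clean

    @property
    def names(self) -> list[str]:
        return list(self.groups)


@dataclass(frozen=True)
class PairwiseComparison:
    name_i: str
    name_j: str
    raw_p: float
    sidak_adjusted_p: float
    mean_difference: float  # mean_i - mean_j, Angstrom


@dataclass
class ComparisonResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: list[PairwiseComparison]


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Dunn-Sidak adjustment 1 - (1 - p)^m, clamped to [0, 1]."""
    if m < 1:
        raise InputError("m must be >= 1")
    adjusted = 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m
    adjusted = np.clip(adjusted, 0.0, 1.0)
    return float(adjusted) if np.isscalar(p) else adjusted


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA from explicit sums of squares.

    Returns (F, df_between, df_within, p).  Degenerate data with zero
    between- and within-group variance yields F = 0, p = 1 rather than an
    error (all groups identical constants carry no evidence of difference).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise InputError("ANOVA needs at least two groups")
    n_total = sum(a.size for a in arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_between = len(arrs) - 1
    df_within = n_total - len(arrs)
    if df_within < 1:
        raise InputError("not enough observations for within-group variance")
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, df_between, df_within, 1.0
        return float("inf"), df_between, df_within, 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f_stat, df_between, df_within))
    return float(f_stat), df_between, df_within, p


def compare_groups(data: GroupedDistances, welch: bool = False) -> ComparisonResult:
    """One-way ANOVA plus Sidak-corrected pairwise t comparisons.

    The default pairwise test uses the pooled within-group variance across
    all groups with N - G degrees of freedom (the classical post-hoc
    convention).  ``welch=True`` switches to per-pair Welch t-tests, which
    drop the equal-variance assumption.
    """
    names = data.names
    arrs = [data.groups[n] for n in names]
    f_stat, df_b, df_w, p_value = anova_oneway(arrs)

    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    pooled_var = ss_within / df_w

    m = len(names) * (len(names) - 1) // 2
    pairwise: list[PairwiseComparison] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrs[i], arrs[j]
            diff = float(a.mean() - b.mean())
            if welch:
                raw_p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
            else:
                se = np.sqrt(pooled_var * (1.0 / a.size + 1.0 / b.size))
                if se == 0.0:
                    raw_p = 1.0 if diff == 0.0 else 0.0
                else:
                    t = diff / se
                    raw_p = float(2.0 * sps.t.sf(abs(t), df_w))
            pairwise.append(
                PairwiseComparison(
                    name_i=names[i],
                    name_j=names[j],
                    raw_p=raw_p,
                    sidak_adjusted_p=sidak_adjust(raw_p, m),
                    mean_difference=diff,
                )
            )
    return ComparisonResult(
        f_statistic=f_stat,
        df_between=df_b,
        df_within=df_w,
        p_value=p_value,
        pairwise=pairwise,
    )
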