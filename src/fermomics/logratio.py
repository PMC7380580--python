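"""Feature-set log ratios and the two-group statistics reported alongside them.

The central object is a :class:`FeatureSetPair` — two disjoint, non-empty
sets of feature IDs. For every sample the log ratio is the natural log of
the summed numerator counts over the summed denominator counts. Because
numerator and denominator share the sample's (unknown) total, the ratio is
invariant to per-sample scaling: it is a statement about the composition,
not about absolute load. Samples where either sum is zero are excluded
outright (with a recorded reason) rather than imputed with pseudocounts.

Group comparisons use the unequal-variance (Welch) t test with a
pooled-standard-deviation Cohen's d, the two-sided Mann-Whitney/Wilcoxon
rank-sum test, and the Pearson chi-square test without continuity
correction, plus a Benjamini-Hochberg utility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class FeatureSetPair:
    """Disjoint numerator/denominator feature-ID sets defining a log ratio."""

    numerator: frozenset[str]
    denominator: frozenset[str]
    provenance: str = "curated"
    note: str = ""

    def __post_init__(self):
        num = frozenset(self.numerator)
        den = frozenset(self.denominator)
        object.__setattr__(self, "numerator", num)
        object.__setattr__(self, "denominator", den)
        if not num or not den:
            raise ValueError("numerator and denominator must both be non-empty")
        if num & den:
            raise ValueError(
                f"numerator and denominator overlap: {sorted(num & den)}"
            )

    def swapped(self) -> "FeatureSetPair":
        return FeatureSetPair(self.denominator, self.numerator,
                              self.provenance, self.note)


@dataclass
class LogRatioSeries:
    """Per-sample natural-log ratios, optional group labels, exclusions."""

    values: pd.Series
    groups: pd.Series | None = None
    excluded: Mapping[str, str] = field(default_factory=dict)

    def by_group(self) -> dict[str, np.ndarray]:
        if self.groups is None:
            raise ValueError("series carries no group labels")
        out = {}
        for label in sorted(self.groups.dropna().unique()):
            out[label] = self.values[self.groups == label].to_numpy(float)
        return out


def compute_log_ratio(
    table: pd.DataFrame,
    pair: FeatureSetPair,
    groups: pd.Series | None = None,
) -> LogRatioSeries:
    """Per-sample ln(sum numerator / sum denominator) for a feature-set pair.

    Samples whose numerator or denominator sum is zero are excluded with a
    reason; if every sample is excluded this raises.
    """
    missing = sorted((pair.numerator | pair.denominator) - set(table.columns))
    if missing:
        raise KeyError(f"features absent from table: {missing}")
    num = table[sorted(pair.numerator)].sum(axis=1).astype(float)
    den = table[sorted(pair.denominator)].sum(axis=1).astype(float)
    excluded: dict[str, str] = {}
    for sid in table.index:
        if num[sid] == 0 and den[sid] == 0:
            excluded[sid] = "zero numerator and denominator"
        elif num[sid] == 0:
            excluded[sid] = "zero numerator"
        elif den[sid] == 0:
            excluded[sid] = "zero denominator"
    keep = table.index.difference(pd.Index(excluded), sort=False)
    if len(keep) == 0:
        raise ValueError("all samples excluded (zero numerator or denominator)")
    values = pd.Series(np.log(num[keep] / den[keep]), index=keep, name="log_ratio")
    grp = None
    if groups is not None:
        grp = groups.reindex(keep)
    return LogRatioSeries(values=values, groups=grp, excluded=excluded)


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    cohens_d: float


def welch_t_arrays(a: Iterable[float], b: Iterable[float]) -> WelchResult:
    """Welch t, Welch-Satterthwaite df, two-sided p, pooled-SD Cohen's d.

    The effect size deliberately uses the pooled standard deviation (the
    standard Cohen's d) even though the test is the unequal-variance form.
    """
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0, 0.0)
        raise ValueError("both groups constant with different means")
    if va == 0 or vb == 0:
        raise ValueError("one group has zero variance; d is not defined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    pooled = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb)
                     / (len(a) + len(b) - 2))
    d = (a.mean() - b.mean()) / pooled
    return WelchResult(float(t), float(df), float(p), float(d))


def welch_t(series: LogRatioSeries) -> WelchResult:
    """Welch comparison of a log-ratio series between its two group labels.

    Groups are taken in sorted label order; the statistic is
    first-label minus second-label.
    """
    groups = series.by_group()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {sorted(groups)}")
    a, b = (groups[k] for k in sorted(groups))
    return welch_t_arrays(a, b)


def rank_sum(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact enumeration when both groups have fewer than 20 observations and
    there are no ties; otherwise the tie-corrected normal approximation
    (without continuity correction, so identical samples give p = 1).
    Returns (U statistic of the first group, p).
    """
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("need >= 1 sample per group")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) < 20 and len(y) < 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def chi_square(table2xk: Iterable[Iterable[float]]) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, no continuity correction.

    Returns (chi2, df, p) with df = (rows-1)(cols-1). A zero row or column
    marginal makes expected counts degenerate and raises.
    """
    obs = np.asarray(table2xk, float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a contingency table with >= 2 rows and columns")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def benjamini_hochberg(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR control)."""
    from statsmodels.stats.multitest import multipletests

    pvalues = np.asarray(list(pvalues), float)
    return multipletests(pvalues, method="fdr_bh")[1]
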