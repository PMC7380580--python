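"""Within-subject stability of per-sample statistics across time points.

Given a per-sample value (typically a feature-set log ratio) and metadata
with subject and time-point columns, pairs are formed between adjacent
*usable* time points within each subject (a sample excluded upstream, e.g.
for a zero log-ratio denominator, leaves a gap; pairs that bridge a gap
are flagged). Pooling all pairs, stability is quantified by the Spearman
rank correlation between the value at t and at the next usable time point,
together with an ordinary least-squares fit of y on x.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .logratio import LogRatioSeries


def consecutive_pairs(
    series: LogRatioSeries | pd.Series,
    meta: pd.DataFrame,
    subject_col: str = "subject",
    time_col: str = "timepoint",
) -> pd.DataFrame:
    """One (x, y) row per adjacent usable time-point pair per subject.

    Columns: subject, t_from, t_to, x, y, gap_bridged (True when the two
    time points are not consecutive integers, i.e. an intermediate sample
    was missing or excluded). Subjects with fewer than two usable samples
    contribute nothing; if no subject contributes, this raises.
    """
    values = series.values if isinstance(series, LogRatioSeries) else series
    for col in (subject_col, time_col):
        if col not in meta.columns:
            raise KeyError(f"metadata missing column {col!r}")
    joined = pd.DataFrame({
        "value": values,
        "subject": meta.loc[values.index, subject_col],
        "timepoint": pd.to_numeric(meta.loc[values.index, time_col]),
    })
    rows = []
    for subject, sub in joined.groupby("subject", sort=True):
        sub = sub.sort_values("timepoint")
        times = sub["timepoint"].to_numpy()
        if len(np.unique(times)) != len(times):
            raise ValueError(
                f"duplicate time points for subject {subject!r}")
        vals = sub["value"].to_numpy(float)
        for i in range(len(sub) - 1):
            rows.append({
                "subject": subject,
                "t_from": times[i], "t_to": times[i + 1],
                "x": vals[i], "y": vals[i + 1],
                "gap_bridged": bool(times[i + 1] - times[i] > 1),
            })
    if not rows:
        raise ValueError("no subject has >= 2 usable time points")
    return pd.DataFrame(rows)


class StabilityResult(NamedTuple):
    spearman_rho: float
    p: float
    ols_slope: float
    ols_intercept: float
    n_pairs: int


def stability_correlation(pairs: pd.DataFrame) -> StabilityResult:
    """Spearman rho (tie-handled) and OLS slope/intercept of y on x over
    pooled consecutive-time-point pairs."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = pairs["x"].to_numpy(float)
    y = pairs["y"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant values: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    ols = stats.linregress(x, y)
    return StabilityResult(float(rho), float(p), float(ols.slope),
                           float(ols.intercept), len(pairs))


def stability_by_group(
    series: LogRatioSeries,
    meta: pd.DataFrame,
    group_col: str = "group",
    **kwargs,
) -> dict[str, StabilityResult]:
    """Stability computed separately within each group label."""
    out = {}
    for label in sorted(meta.loc[series.values.index, group_col].unique()):
        mask = meta.loc[series.values.index, group_col] == label
        sub = LogRatioSeries(series.values[mask.to_numpy()],
                             excluded=series.excluded)
        out[label] = stability_correlation(
            consecutive_pairs(sub, meta, **kwargs))
    return out
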