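"""Random feature-set permutation null for selected log ratios.

A log ratio built from rank-selected feature sets will separate two groups
to some degree by construction; the question is whether it separates them
more than a log ratio of *randomly* chosen, nonoverlapping feature sets of
the same sizes. The null here redraws the feature selection B times
(features may recur across draws — a known, accepted dependence of this
null), computes the absolute Welch t between groups for each draw, and
ranks the observed statistic among them.

The p-value is the add-one permutation form rank/(B+1); for display it is
truncated (floored) to four decimals, so e.g. rank 16 of B=1000 shows as
0.0159 and rank 2 as 0.0019. The full-precision value is retained for
computation and can never be 0 (minimum 1/(B+1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .logratio import FeatureSetPair, compute_log_ratio, welch_t


def display_p(p: float, decimals: int = 4) -> str:
    """Truncate (not round) a p-value for display."""
    scale = 10**decimals
    return f"{math.floor(p * scale) / scale:.{decimals}f}"


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    rank: int          # 1 = observed more extreme than every null draw
    p_value: float     # rank / (B + 1), full precision
    B: int
    k_num: int
    k_den: int
    seed: int | None = None
    n_redraws: int = 0

    @classmethod
    def from_null(cls, observed: float, null_stats, *, k_num=0, k_den=0,
                  seed=None, n_redraws=0) -> "PermutationResult":
        null_stats = np.asarray(null_stats, float)
        B = len(null_stats)
        if B < 1:
            raise ValueError("need at least one null draw")
        rank = 1 + int((null_stats >= observed).sum())
        return cls(observed_stat=float(observed), null_stats=null_stats,
                   rank=rank, p_value=rank / (B + 1), B=B,
                   k_num=k_num, k_den=k_den, seed=seed, n_redraws=n_redraws)

    @property
    def display(self) -> str:
        return display_p(self.p_value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "observed_stat": self.observed_stat, "rank": self.rank,
            "p_value": self.p_value, "p_display": self.display,
            "B": self.B, "k_num": self.k_num, "k_den": self.k_den,
            "seed": self.seed, "n_redraws": self.n_redraws,
        }])


def random_pair(feature_pool, k_num: int, k_den: int,
                rng: np.random.Generator) -> FeatureSetPair:
    """Uniform draw of k_num + k_den distinct features from the pool;
    the first k_num go to the numerator, so the sets never overlap."""
    pool = sorted(feature_pool)
    if k_num + k_den > len(pool):
        raise ValueError(
            f"pool of {len(pool)} too small for k_num+k_den={k_num + k_den}")
    drawn = rng.choice(len(pool), size=k_num + k_den, replace=False)
    chosen = [pool[i] for i in drawn]
    return FeatureSetPair(frozenset(chosen[:k_num]),
                          frozenset(chosen[k_num:]), provenance="ranked",
                          note="random permutation draw")


def permutation_test(
    table: pd.DataFrame,
    groups: pd.Series,
    observed_pair: FeatureSetPair,
    B: int = 1000,
    stat: str = "welch_t_abs",
    seed: int = 0,
    max_redraws_per_draw: int = 100,
) -> PermutationResult:
    """Compare the observed pair's |Welch t| to B random-pair log ratios.

    Degenerate null draws (all samples excluded, or a group left with
    fewer than two usable samples) are redrawn, and the number of redraws
    is recorded in the result diagnostics.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if stat != "welch_t_abs":
        raise ValueError(f"unsupported statistic {stat!r}")
    k_num, k_den = len(observed_pair.numerator), len(observed_pair.denominator)
    observed = abs(welch_t(compute_log_ratio(table, observed_pair, groups)).t)

    rng = np.random.default_rng(seed)
    pool = sorted(table.columns)
    counts = table[pool].to_numpy(float)
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    masks = [(groups.reindex(table.index) == lab).to_numpy() for lab in labels]

    def null_stat_once() -> float | None:
        idx = rng.choice(len(pool), size=k_num + k_den, replace=False)
        num = counts[:, idx[:k_num]].sum(axis=1)
        den = counts[:, idx[k_num:]].sum(axis=1)
        usable = (num > 0) & (den > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.log(num / den)
        a = values[usable & masks[0]]
        b = values[usable & masks[1]]
        if len(a) < 2 or len(b) < 2:
            return None
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 or vb == 0:
            return None  # degenerate draw: Welch t undefined or infinite
        return abs((a.mean() - b.mean())
                   / np.sqrt(va / len(a) + vb / len(b)))

    null_stats = np.empty(B)
    redraws = 0
    for b in range(B):
        for attempt in range(max_redraws_per_draw + 1):
            value = null_stat_once()
            if value is not None:
                null_stats[b] = value
                break
            redraws += 1
        else:
            raise RuntimeError(
                f"could not find a usable null pair after "
                f"{max_redraws_per_draw} redraws (draw {b})")
    return PermutationResult.from_null(
        observed, null_stats, k_num=k_num, k_den=k_den, seed=seed,
        n_redraws=redraws)
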