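"""Participant, sample, and feature filtering for cohort count tables.

Implements the standard exclusion cascade for a citizen-science gut
microbiome cohort: host covariate bounds (age/BMI/height/weight, all
exclusive as printed in questionnaires of this kind), antibiotic exposure
in the last year, biological-replicate deduplication by read count, a
per-sample minimum read cutoff, removal of features on an exclusion list
(e.g. shipping-bloom sequences), a table-wide minimum feature total, an
optional per-sample relative-abundance floor, and rarefaction by seeded
subsampling without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: frequency answers that define a consumer / nonconsumer
_CONSUMER = frozenset({"occasionally", "regularly", "daily"})
_NONCONSUMER = frozenset({"never", "rarely"})

REQUIRED_PARTICIPANT_COLUMNS = (
    "age", "bmi", "height_cm", "weight_kg", "antibiotic_past_year",
)


@dataclass(frozen=True)
class FilterCriteria:
    """Bounds and cutoffs of the exclusion cascade.

    All host-covariate bounds are exclusive: a participant is retained only
    if the value lies strictly inside (min, max). Defaults follow common
    practice for adult stool cohorts: age in (19, 70) years, BMI in
    (15, 50) kg/m^2, height in (48, 210) cm, weight in (2.5, 200) kg,
    a 1,500-read sample cutoff, feature totals of at least 5 reads.
    """

    age_min: float = 19.0
    age_max: float = 70.0
    bmi_min: float = 15.0
    bmi_max: float = 50.0
    height_min: float = 48.0
    height_max: float = 210.0
    weight_min: float = 2.5
    weight_max: float = 200.0
    exclude_antibiotics_last_year: bool = True
    min_reads: int = 1500
    rarefaction_depth: int = 1500
    min_feature_total: int = 5
    min_relative_abundance: float = 0.0
    exclusion_list: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        for lo, hi in (("age_min", "age_max"), ("bmi_min", "bmi_max"),
                       ("height_min", "height_max"),
                       ("weight_min", "weight_max")):
            if getattr(self, lo) >= getattr(self, hi):
                raise ValueError(f"{lo} must be < {hi}")
        if not 0.0 <= self.min_relative_abundance < 1.0:
            raise ValueError("min_relative_abundance must be in [0, 1)")
        object.__setattr__(self, "exclusion_list",
                           frozenset(self.exclusion_list))


def metagenome_criteria(**overrides) -> FilterCriteria:
    """Criteria variant for mapped-read metagenome tables: a 0.01%
    per-sample relative-abundance floor, no read-depth gates."""
    base = dict(min_reads=1, rarefaction_depth=1, min_feature_total=1,
                min_relative_abundance=1e-4)
    base.update(overrides)
    return FilterCriteria(**base)


def _truthy(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"yes", "y", "true", "1"}


def filter_participants(
    meta: pd.DataFrame, crit: FilterCriteria
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop metadata rows violating any bound, flagged for antibiotics, or
    missing a required field.

    Returns the retained rows and an audit log of per-rule exclusion
    counts. Each removed row is attributed to the first rule it violates,
    in the order: missing field, age, BMI, height, weight, antibiotics —
    so the audit counts sum exactly to the number of rows removed.
    """
    missing_cols = [c for c in REQUIRED_PARTICIPANT_COLUMNS
                    if c not in meta.columns]
    if missing_cols:
        raise KeyError(f"metadata missing required columns: {missing_cols}")

    audit = {"missing_field": 0, "age": 0, "bmi": 0, "height": 0,
             "weight": 0, "antibiotics": 0}
    numeric = {c: pd.to_numeric(meta[c], errors="coerce")
               for c in ("age", "bmi", "height_cm", "weight_kg")}
    keep = []
    for sid in meta.index:
        vals = {c: numeric[c][sid] for c in numeric}
        abx = meta.at[sid, "antibiotic_past_year"]
        if any(pd.isna(v) for v in vals.values()) or pd.isna(abx):
            audit["missing_field"] += 1
        elif not crit.age_min < vals["age"] < crit.age_max:
            audit["age"] += 1
        elif not crit.bmi_min < vals["bmi"] < crit.bmi_max:
            audit["bmi"] += 1
        elif not crit.height_min < vals["height_cm"] < crit.height_max:
            audit["height"] += 1
        elif not crit.weight_min < vals["weight_kg"] < crit.weight_max:
            audit["weight"] += 1
        elif crit.exclude_antibiotics_last_year and _truthy(abx):
            audit["antibiotics"] += 1
        else:
            keep.append(sid)
    return meta.loc[keep], audit


def dedup_replicates(
    meta: pd.DataFrame,
    subject_col: str = "subject",
    time_col: str = "timepoint",
    reads_col: str = "read_count",
) -> pd.DataFrame:
    """Keep one sample per (subject, time point): the one with the most
    reads, ties broken by the lexicographically smallest sample ID."""
    if reads_col not in meta.columns:
        raise KeyError(f"metadata missing read-count column {reads_col!r}")
    # sort by ID first, then stable-sort by reads descending: ties keep
    # the smaller ID in front
    ordered = meta.loc[sorted(meta.index)]
    ordered = ordered.iloc[
        np.argsort(-pd.to_numeric(ordered[reads_col]).to_numpy(),
                   kind="stable")
    ]
    kept = ordered[~ordered.duplicated(subset=[subject_col, time_col])]
    return meta.loc[[sid for sid in meta.index if sid in set(kept.index)]]


def classify_consumption(
    meta: pd.DataFrame, column: str = "fermented_plant_frequency"
) -> pd.DataFrame:
    """Append a ``consumption_label`` column from the fermented-plant
    frequency answer.

    occasionally/regularly/daily -> consumer; never/rarely -> nonconsumer;
    anything else (including missing) -> unknown.
    """
    if column not in meta.columns:
        raise KeyError(f"metadata missing frequency column {column!r}")

    def label(value) -> str:
        if pd.isna(value):
            return "unknown"
        norm = str(value).strip().lower()
        if norm in _CONSUMER:
            return "consumer"
        if norm in _NONCONSUMER:
            return "nonconsumer"
        return "unknown"

    out = meta.copy()
    out["consumption_label"] = [label(v) for v in meta[column]]
    return out


def filter_table(
    table: pd.DataFrame, crit: FilterCriteria
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the feature/sample cascade to a count table, in fixed order:

    1. drop features on the exclusion list;
    2. drop samples with total reads below ``min_reads``;
    3. if ``min_relative_abundance`` > 0, zero per-sample entries below
       that fraction of the sample total;
    4. drop features whose table-wide total is below ``min_feature_total``.
    """
    audit: dict[str, int] = {}
    out = table.drop(columns=[c for c in table.columns
                              if c in crit.exclusion_list])
    audit["excluded_features"] = table.shape[1] - out.shape[1]

    totals = out.sum(axis=1)
    keep_samples = totals >= crit.min_reads
    audit["low_read_samples"] = int((~keep_samples).sum())
    out = out.loc[keep_samples]

    if crit.min_relative_abundance > 0 and len(out):
        arr = out.to_numpy(float)
        floor = crit.min_relative_abundance * arr.sum(axis=1, keepdims=True)
        zeroed = (arr > 0) & (arr < floor)
        audit["entries_zeroed"] = int(zeroed.sum())
        arr[zeroed] = 0
        out = pd.DataFrame(arr.astype(table.dtypes.iloc[0] if len(
            set(table.dtypes)) == 1 else float),
            index=out.index, columns=out.columns)
    else:
        audit["entries_zeroed"] = 0

    feature_totals = out.sum(axis=0)
    keep_features = feature_totals >= crit.min_feature_total
    audit["low_total_features"] = int((~keep_features).sum())
    out = out.loc[:, keep_features]
    if out.empty or out.shape[1] == 0:
        raise ValueError("filtering removed every sample or feature")
    return out, audit


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without
    replacement; samples with fewer total reads are dropped.

    Deterministic given the seed; zero counts can never become positive.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.to_numpy().astype(np.int64)
    totals = counts.sum(axis=1)
    rows, index = [], []
    for i, sid in enumerate(table.index):
        if totals[i] < depth:
            continue
        rows.append(rng.multivariate_hypergeometric(counts[i], depth))
        index.append(sid)
    return pd.DataFrame(np.asarray(rows, dtype=np.int64).reshape(
        len(index), table.shape[1]), index=index, columns=table.columns)
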