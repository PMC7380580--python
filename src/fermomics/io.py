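"""Readers and writers for the plain-text formats the pipeline exchanges.

Count tables are dense TSV with samples as rows and features as columns.
Sample metadata follows the QIIME2 dialect: a leading ``#SampleID`` column
holding sample identifiers. Feature-set pairs are two-column TSV
(``feature_id``, ``set`` in {numerator, denominator}); exclusion lists are
plain text with one feature ID per line.
"""

from __future__ import annotations

import os

import pandas as pd

METADATA_INDEX = "#SampleID"


def read_count_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a samples-by-features count table from TSV."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    return table


def write_count_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index_label="sampleid")


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read per-sample metadata (QIIME2-dialect TSV, ``#SampleID`` first)."""
    meta = pd.read_csv(path, sep="\t", dtype={0: str})
    first = meta.columns[0]
    if first not in (METADATA_INDEX, "sampleid", "sample-id", "SampleID"):
        raise ValueError(
            f"metadata must start with a sample identifier column; got {first!r}"
        )
    return meta.set_index(first).rename_axis(METADATA_INDEX)


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, sep="\t", index_label=METADATA_INDEX)


def read_exclusion_list(path: str | os.PathLike) -> frozenset[str]:
    with open(path) as handle:
        return frozenset(line.strip() for line in handle if line.strip())


def read_feature_sets(path: str | os.PathLike):
    """Read a numerator/denominator feature-set pair from two-column TSV."""
    from .logratio import FeatureSetPair

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"feature_id", "set"} <= set(df.columns):
        raise ValueError("feature-set file needs 'feature_id' and 'set' columns")
    num = df.loc[df["set"] == "numerator", "feature_id"]
    den = df.loc[df["set"] == "denominator", "feature_id"]
    return FeatureSetPair(frozenset(num), frozenset(den))


def write_feature_sets(pair, path: str | os.PathLike) -> None:
    rows = [(f, "numerator") for f in sorted(pair.numerator)]
    rows += [(f, "denominator") for f in sorted(pair.denominator)]
    pd.DataFrame(rows, columns=["feature_id", "set"]).to_csv(
        path, sep="\t", index=False
    )
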