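"""Composition and coverage arithmetic for annotation summary tables.

Consumes abundance tables (class, family, count) such as a transposable-element
annotation of a draft assembly, and computes the per-family frequencies within
the whole table and within each class, class shares, family-group shares, and
identified/total coverage percentages. Rounding is decimal half-up at the
precision conventional for such report tables (2 decimals for table columns,
1 decimal for prose-style percentages).

Rows whose class is in ``classless_labels`` (default: "Ambiguous") belong to no
class: they contribute to the grand total but get no within-class frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd

from ._util import ratio_percent

CLASSLESS_LABELS = frozenset({"Ambiguous"})


def load_abundance_table(path) -> pd.DataFrame:
    """Read a (class, family, count) TSV and validate it."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return validate_abundance_table(df)


def validate_abundance_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"class", "family", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"abundance table needs columns {sorted(required)}")
    if df.empty:
        raise ValueError("abundance table is empty")
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if df.duplicated(["class", "family"]).any():
        raise ValueError("duplicate (class, family) pairs")
    return df


def composition_table(
    table: pd.DataFrame, classless_labels: frozenset[str] = CLASSLESS_LABELS
) -> pd.DataFrame:
    """Add frequency_in_total and frequency_in_class columns (2 decimals)."""
    table = validate_abundance_table(table)
    grand_total = int(table["count"].sum())
    if grand_total <= 0:
        raise ValueError("grand total must be positive")
    class_totals = table.groupby("class")["count"].sum().to_dict()
    out = table.copy()
    out["frequency_in_total"] = [
        ratio_percent(int(c), grand_total, 2) for c in table["count"]
    ]
    out["frequency_in_class"] = [
        None if cls in classless_labels
        else ratio_percent(int(c), int(class_totals[cls]), 2)
        for cls, c in zip(table["class"], table["count"])
    ]
    return out


def class_share(table: pd.DataFrame, class_label: str, ndigits: int = 1) -> float:
    """Percentage of the grand total contributed by one class (1 decimal)."""
    table = validate_abundance_table(table)
    sub = table[table["class"] == class_label]
    if sub.empty:
        raise ValueError(f"unknown class {class_label!r}")
    return ratio_percent(int(sub["count"].sum()), int(table["count"].sum()), ndigits)


def family_group_share(
    table: pd.DataFrame, families: Sequence[str], denominator: str = "total",
    class_label: str | None = None, ndigits: int = 1,
) -> float:
    """Percentage of a named family group over the grand total or a class total."""
    table = validate_abundance_table(table)
    known = set(table["family"])
    missing = set(families) - known
    if missing:
        raise ValueError(f"unknown families: {sorted(missing)}")
    num = int(table[table["family"].isin(list(families))]["count"].sum())
    if denominator == "total":
        den = int(table["count"].sum())
    elif denominator == "class":
        if class_label is None:
            raise ValueError("denominator='class' requires class_label")
        sub = table[table["class"] == class_label]
        if sub.empty:
            raise ValueError(f"unknown class {class_label!r}")
        den = int(sub["count"].sum())
    else:
        raise ValueError("denominator must be 'total' or 'class'")
    return ratio_percent(num, den, ndigits)


@dataclass(frozen=True)
class CoverageStat:
    identified: int
    total: int
    percent: float


def coverage_percent(identified: int, total: int, ndigits: int = 1) -> CoverageStat:
    """Share of a reference catalogue recovered, e.g. TF homologs found."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= identified <= total:
        raise ValueError("identified must be within [0, total]")
    return CoverageStat(identified, total, ratio_percent(identified, total, ndigits))


def load_quince_te_counts() -> pd.DataFrame:
    """Bundled TE family counts reported for the quince draft assembly
    (GenBank JADOBS000000000); used for regression tests of the arithmetic."""
    with resources.files("premirscan.data").joinpath("quince_te_counts.tsv").open() as fh:
        return validate_abundance_table(pd.read_csv(fh, sep="\t", comment="#"))


def load_quince_ssr_counts() -> pd.DataFrame:
    """Bundled per-motif-length microsatellite counts reported for the quince
    draft assembly."""
    with resources.files("premirscan.data").joinpath("quince_ssr_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


#: Published summary constants for the quince draft assembly, used as inputs
#: to the arithmetic above in examples and regression tests.
QUINCE_ASSEMBLY_LENGTH_BP = 488_422_409
QUINCE_GENOME_SIZE_ESTIMATE_BP = 686_000_000  # flow-cytometry estimate
QUINCE_AT_DINUCLEOTIDE_LOCI = 27_583  # AT-motif loci among dinucleotide SSRs
QUINCE_TF_COVERAGE = {
    "arabidopsis": (2686, 2757),  # identified, annotated TFs
    "rice": (2981, 3119),
}
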