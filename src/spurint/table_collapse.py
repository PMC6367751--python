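"""Spurious interaction from collapsing exposure categories.

A stratified contingency table can show perfectly homogeneous relative
risks across strata — no interaction on the RR scale — and yet become
inhomogeneous after adjacent exposure categories are merged, because the
strata differ in how subjects are distributed over the merged
categories.  The bundled fixture is a two-stratum, four-category table
with RRs 1:2:3:4 in both strata; merging categories {1,2} and {3,4}
yields stratum RRs of 7/3 and 15/7 (2.33 vs 2.14 at two decimals).

Risks and RRs are kept as exact floats of integer count ratios; rounding
happens only at display.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "StratifiedCountTable",
    "CollapseMap",
    "RRTable",
    "HomogeneityReport",
    "load_table3",
    "relative_risks",
    "collapse",
    "interaction_check",
]

_COLUMNS = ["stratum", "category", "diseased", "not_diseased"]


@dataclass(frozen=True)
class StratifiedCountTable:
    """Disease/no-disease counts by exposure category within strata.

    ``counts`` has columns (stratum, category, diseased, not_diseased),
    one row per (stratum, category) cell.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (df[["diseased", "not_diseased"]] < 0).any().any():
            raise ValueError("counts must be non-negative")
        if df.duplicated(subset=["stratum", "category"]).any():
            raise ValueError("duplicate (stratum, category) cells")

    @classmethod
    def from_csv(cls, path: str | Path) -> "StratifiedCountTable":
        df = pd.read_csv(path, comment="#")
        try:
            df = df[_COLUMNS].astype(
                {"diseased": int, "not_diseased": int}
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"malformed count table {path}: {exc}") from exc
        return cls(df)

    @property
    def strata(self) -> list:
        return sorted(self.counts["stratum"].unique())

    @property
    def categories(self) -> list:
        return sorted(self.counts["category"].unique())

    def totals(self) -> pd.DataFrame:
        df = self.counts.copy()
        df["total"] = df["diseased"] + df["not_diseased"]
        return df


@dataclass(frozen=True)
class CollapseMap:
    """Surjective map from old category labels to new ones."""

    mapping: Mapping

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) < 2:
            raise ValueError("collapse must leave at least 2 categories")

    def apply(self, category):
        try:
            return self.mapping[category]
        except KeyError:
            raise KeyError(f"category {category!r} not covered by collapse map")


@dataclass(frozen=True)
class RRTable:
    """Per-cell risks and relative risks versus the reference category."""

    table: pd.DataFrame  # stratum, category, diseased, total, risk, rr
    reference: object


def load_table3() -> StratifiedCountTable:
    """The bundled two-stratum, four-category demonstration table."""
    with resources.as_file(
        resources.files("spurint").joinpath("data/table3.csv")
    ) as path:
        return StratifiedCountTable.from_csv(path)


def relative_risks(
    t: StratifiedCountTable, reference=None
) -> RRTable:
    """Risks and stratum-wise RRs relative to the reference category.

    The reference defaults to the lowest-labelled category; its RR is
    exactly 1.0 in every stratum.

    Raises
    ------
    ValueError
        On an empty (zero-total) cell or a zero-risk reference.
    """
    if reference is None:
        reference = t.categories[0]
    df = t.totals()
    if (df["total"] == 0).any():
        raise ValueError("zero-total cell: risk undefined")
    df["risk"] = df["diseased"] / df["total"]
    out = []
    for stratum, sub in df.groupby("stratum", sort=True):
        ref_rows = sub[sub["category"] == reference]
        if ref_rows.empty:
            raise ValueError(f"reference {reference!r} missing in stratum {stratum!r}")
        ref_risk = float(ref_rows["risk"].iloc[0])
        if ref_risk == 0.0:
            raise ValueError(f"zero reference risk in stratum {stratum!r}")
        sub = sub.copy()
        sub["rr"] = sub["risk"] / ref_risk
        out.append(sub)
    table = pd.concat(out, ignore_index=True)[
        ["stratum", "category", "diseased", "total", "risk", "rr"]
    ]
    return RRTable(table=table, reference=reference)


def collapse(t: StratifiedCountTable, m: CollapseMap) -> StratifiedCountTable:
    """Merge categories by summing counts within each stratum.

    Totals are preserved exactly: the merge only re-labels and sums
    integer counts.
    """
    df = t.counts.copy()
    df["category"] = [m.apply(c) for c in df["category"]]
    merged = (
        df.groupby(["stratum", "category"], as_index=False, sort=True)[
            ["diseased", "not_diseased"]
        ].sum()
    )
    return StratifiedCountTable(merged)


@dataclass(frozen=True)
class HomogeneityReport:
    """Max/min ratio of stratum RRs per non-reference category."""

    ratios: pd.DataFrame  # category, rr_min, rr_max, ratio, flagged
    homogeneous: bool
    threshold: float


def interaction_check(
    r: RRTable, threshold: float = 1.0 + 1e-9
) -> HomogeneityReport:
    """Flag categories whose RR varies across strata.

    A category is flagged when max(RR)/min(RR) over strata exceeds
    ``threshold``; the default flags any inhomogeneity beyond numerical
    noise.  A single-stratum table is trivially homogeneous.
    """
    df = r.table[r.table["category"] != r.reference]
    rows = []
    for category, sub in df.groupby("category", sort=True):
        rr_min, rr_max = float(sub["rr"].min()), float(sub["rr"].max())
        ratio = rr_max / rr_min if rr_min > 0 else float("inf")
        rows.append(
            {
                "category": category,
                "rr_min": rr_min,
                "rr_max": rr_max,
                "ratio": ratio,
                "flagged": ratio > threshold,
            }
        )
    ratios = pd.DataFrame(
        rows, columns=["category", "rr_min", "rr_max", "ratio", "flagged"]
    )
    return HomogeneityReport(
        ratios=ratios,
        homogeneous=not bool(ratios["flagged"].any()),
        threshold=threshold,
    )
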