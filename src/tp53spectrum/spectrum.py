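"""Mutation-spectrum count tables and Pearson chi-square comparisons.

Spectra are tabulated either eight-way (the three A:T substitution
classes kept separate) or six-group, where all mutations at A:T base
pairs are merged into a single "A:T" category — the grouping used when
comparing cohorts whose published tables pool those rare classes.
"Others" collects every non-single-base-substitution event (deletions,
insertions, complex and splice changes).

Comparisons use the uncorrected Pearson chi-square: a global test on the
2 x k table and per-category post-hoc 2 x 2 tests (category vs all
others, cohort vs cohort).  No continuity correction and no
multiple-testing adjustment are applied by default; Bonferroni-adjusted
post-hoc p-values are available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .annotate import MutationRecord

EIGHT_WAY = ("AT>CG", "AT>GC", "AT>TA", "Others", "GC>AT", "GC>AT_CpG", "GC>CG", "GC>TA")
SIX_GROUP = ("A:T", "Others", "GC>AT", "GC>AT_CpG", "GC>CG", "GC>TA")
_AT_CLASSES = ("AT>CG", "AT>GC", "AT>TA")
_OTHERS_SOURCE = ("deletion", "insertion", "complex_other")


@dataclass(frozen=True)
class SpectrumTable:
    """Counts per mutation category for one cohort."""

    cohort_label: str
    counts: Mapping[str, int]
    grouping: str = "eight_way"  # eight_way | six_group
    exon_filter: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        order = EIGHT_WAY if self.grouping == "eight_way" else SIX_GROUP
        if self.grouping not in {"eight_way", "six_group"}:
            raise ValueError(f"unknown grouping {self.grouping!r}")
        unknown = set(self.counts) - set(order)
        if unknown:
            raise ValueError(f"unknown categories for {self.grouping}: {sorted(unknown)}")
        full = {cat: int(self.counts.get(cat, 0)) for cat in order}
        if any(v < 0 for v in full.values()):
            raise ValueError("negative category count")
        object.__setattr__(self, "counts", full)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def vector(self) -> np.ndarray:
        return np.array(list(self.counts.values()), dtype=float)

    def to_six_group(self) -> "SpectrumTable":
        """Merge the three A:T substitution classes into one category."""
        if self.grouping == "six_group":
            return self
        counts = {"A:T": sum(self.counts[c] for c in _AT_CLASSES)}
        counts.update({c: self.counts[c] for c in SIX_GROUP if c != "A:T"})
        return SpectrumTable(self.cohort_label, counts, "six_group", self.exon_filter)


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square test result with expected counts."""

    statistic: float
    df: int
    p_value: float
    expected: tuple = ()
    warning_small_expected: bool = False


def count_spectrum(
    records: Iterable[MutationRecord],
    exon_filter: tuple[int, int] | None = None,
    grouping: str = "eight_way",
    cohort_label: str = "cohort",
) -> SpectrumTable:
    """Tabulate annotated mutations into a :class:`SpectrumTable`.

    ``exon_filter=(lo, hi)`` keeps records whose exon lies in the range;
    splice records use the exon of their nearest exonic anchor, and
    records with no exon assignment are excluded with a warning.
    """
    counts = {cat: 0 for cat in EIGHT_WAY}
    for rec in records:
        if exon_filter is not None:
            if rec.exon is None:
                warnings.warn(
                    f"{rec.variant.raw}: no exon assignment, excluded from "
                    f"exon-filtered spectrum", stacklevel=2,
                )
                continue
            if not exon_filter[0] <= rec.exon <= exon_filter[1]:
                continue
        if rec.category in _OTHERS_SOURCE:
            counts["Others"] += 1
        else:
            counts[rec.category] += 1
    table = SpectrumTable(cohort_label, counts, "eight_way", exon_filter)
    return table.to_six_group() if grouping == "six_group" else table


def _chi2(table: np.ndarray) -> ChiSquareResult:
    res = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        expected=tuple(map(tuple, res.expected_freq)),
        warning_small_expected=bool((res.expected_freq < 5).any()),
    )


def global_compare(a: SpectrumTable, b: SpectrumTable) -> ChiSquareResult:
    """Global Pearson chi-square on the 2 x k cohort-by-category table.

    Degrees of freedom are k - 1 (e.g. 5 for the six-group table).  The
    ``warning_small_expected`` flag is set when any expected cell is
    below 5; the test is not switched to an exact test.
    """
    if a.grouping != b.grouping or a.categories != b.categories:
        raise ValueError("spectra have mismatched groupings")
    if a.total == 0 or b.total == 0:
        raise ValueError("cannot compare an empty spectrum")
    table = np.vstack([a.vector(), b.vector()])
    # categories absent from both cohorts carry no information and would
    # inflate the degrees of freedom / break the expected-count matrix
    nonzero = table.sum(axis=0) > 0
    return _chi2(table[:, nonzero])


def posthoc_compare(a: SpectrumTable, b: SpectrumTable, category: str) -> ChiSquareResult:
    """Per-category 2x2 chi-square: category vs all others, cohort a vs b."""
    if category not in a.counts or category not in b.counts:
        raise ValueError(f"category {category!r} absent from spectra")
    table = np.array(
        [
            [a.counts[category], a.total - a.counts[category]],
            [b.counts[category], b.total - b.counts[category]],
        ],
        dtype=float,
    )
    return _chi2(table)


def spectrum_to_tsv(table: SpectrumTable, path) -> None:
    """Write a count table (columns: cohort, category, count)."""
    import pandas as pd

    pd.DataFrame(
        {
            "cohort": table.cohort_label,
            "category": list(table.counts),
            "count": list(table.counts.values()),
        }
    ).to_csv(path, sep="\t", index=False)


def spectrum_from_tsv(path, cohort_label: str | None = None) -> SpectrumTable:
    """Read a count table written by :func:`spectrum_to_tsv`.

    The grouping is inferred from the category labels (a merged "A:T"
    row implies the six-group table).
    """
    from .io_core import _read_table

    df = _read_table(path)
    counts = {r["category"]: int(r["count"]) for r in df.to_dict("records")}
    grouping = "six_group" if "A:T" in counts else "eight_way"
    label = cohort_label or (df["cohort"].iloc[0] if "cohort" in df else "cohort")
    return SpectrumTable(label, counts, grouping)


def posthoc_all(
    a: SpectrumTable, b: SpectrumTable, bonferroni: bool = False
) -> dict[str, ChiSquareResult]:
    """Post-hoc tests for every category (optionally Bonferroni-adjusted)."""
    out = {}
    k = len(a.categories)
    for cat in a.categories:
        res = posthoc_compare(a, b, cat)
        if bonferroni:
            res = ChiSquareResult(res.statistic, res.df, min(1.0, res.p_value * k),
                                  res.expected, res.warning_small_expected)
        out[cat] = res
    return out
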