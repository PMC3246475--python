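"""p53 immunohistochemistry scoring, inter-antibody agreement, and the
association between mutation functional class and protein expression.

Each rating multiplies the percent-stained category (0-4) by the staining
intensity (0-3) into a composite score 0-12, binned negative (0), weak
(1-4), moderate (5-8) or strong (9-12).  A sample is "positive" when
moderate or strong.  Missense mutants typically accumulate and stain
positive, whereas protein-null mutations (nonsense, splice, frameshift)
predict absent staining — the contrast tested here with Pearson
chi-square tests reused from the spectrum module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotate import MutationRecord, PROTEIN_NULL_EFFECTS
from .io_core import IHCRatingRow
from .spectrum import ChiSquareResult, _chi2

CATEGORY_ORDER = ("negative", "weak", "moderate", "strong")
POSITIVE_CATEGORIES = frozenset({"moderate", "strong"})

FUNCTIONAL_CLASSES = ("missense", "protein_null", "other_mutant", "wild_type")


@dataclass(frozen=True)
class ExpressionCall:
    """Per-sample, per-antibody composite expression call."""

    sample_id: str
    antibody: str
    composite: int
    category: str
    positive: bool


def composite_score(pct_category: int, intensity: int) -> tuple[int, str, bool]:
    """Composite score = pct_category * intensity, binned into four groups.

    0 -> negative, 1-4 -> weak, 5-8 -> moderate, 9-12 -> strong; positive
    means moderate or strong.
    """
    if not 0 <= pct_category <= 4:
        raise ValueError(f"pct_category {pct_category} outside 0..4")
    if not 0 <= intensity <= 3:
        raise ValueError(f"intensity {intensity} outside 0..3")
    score = pct_category * intensity
    if score == 0:
        category = "negative"
    elif score <= 4:
        category = "weak"
    elif score <= 8:
        category = "moderate"
    else:
        category = "strong"
    return score, category, category in POSITIVE_CATEGORIES


def score_ratings(rows: Iterable[IHCRatingRow]) -> list[ExpressionCall]:
    """Composite calls for every rating row."""
    calls = []
    for r in rows:
        score, category, positive = composite_score(r.pct_category, r.intensity)
        calls.append(ExpressionCall(r.sample_id, r.antibody, score, category, positive))
    return calls


def _paired(
    calls_ab1: Sequence[ExpressionCall], calls_ab2: Sequence[ExpressionCall]
) -> list[tuple[ExpressionCall, ExpressionCall]]:
    by1 = {c.sample_id: c for c in calls_ab1}
    by2 = {c.sample_id: c for c in calls_ab2}
    common = sorted(set(by1) & set(by2))
    dropped = (set(by1) | set(by2)) - set(common)
    if dropped:
        import warnings

        warnings.warn(f"{len(dropped)} unpaired samples dropped from agreement",
                      stacklevel=3)
    return [(by1[s], by2[s]) for s in common]


def percent_agreement(
    calls_ab1: Sequence[ExpressionCall], calls_ab2: Sequence[ExpressionCall]
) -> float:
    """Percent of paired samples with identical expression category."""
    pairs = _paired(calls_ab1, calls_ab2)
    if not pairs:
        raise ValueError("no paired samples")
    agree = sum(c1.category == c2.category for c1, c2 in pairs)
    return 100.0 * agree / len(pairs)


def weighted_kappa(
    calls_ab1: Sequence[ExpressionCall],
    calls_ab2: Sequence[ExpressionCall],
    weights: str = "linear",
) -> float:
    """Weighted Cohen's kappa over the four ordered expression categories.

    kappa = 1 - sum(w * O) / sum(w * E) with disagreement weights
    w_ij = |i-j|/(k-1) (linear, default) or its square (quadratic), and E
    from the product of the two raters' marginals.  Undefined (raises)
    when both raters use a single identical category.
    """
    pairs = _paired(calls_ab1, calls_ab2)
    if not pairs:
        raise ValueError("no paired samples")
    k = len(CATEGORY_ORDER)
    idx = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    observed = np.zeros((k, k))
    for c1, c2 in pairs:
        observed[idx[c1.category], idx[c2.category]] += 1
    observed /= observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    i, j = np.indices((k, k))
    w = np.abs(i - j) / (k - 1)
    if weights == "quadratic":
        w = w**2
    elif weights != "linear":
        raise ValueError(f"unknown weight scheme {weights!r}")
    denom = float((w * expected).sum())
    if denom == 0:
        raise ValueError("kappa undefined: no expected disagreement")
    return 1.0 - float((w * observed).sum()) / denom


def sample_functional_class(
    sample_ids: Iterable[str], mutations: Sequence[MutationRecord]
) -> dict[str, str]:
    """Per-sample class: missense-bearing, protein-null, other mutant, wild-type.

    A sample with any missense mutation is ``missense``; otherwise any
    nonsense/splice/frameshift mutation makes it ``protein_null``;
    remaining mutated samples (silent or in-frame events only) are
    ``other_mutant``; samples without mutations are ``wild_type``.
    """
    by_sample: dict[str, list[str]] = {}
    for m in mutations:
        by_sample.setdefault(m.sample_id, []).append(m.effect)
    out = {}
    for sid in sample_ids:
        effects = by_sample.get(sid)
        if not effects:
            out[sid] = "wild_type"
        elif "missense" in effects:
            out[sid] = "missense"
        elif set(effects) & PROTEIN_NULL_EFFECTS:
            out[sid] = "protein_null"
        else:
            out[sid] = "other_mutant"
    return out


def expression_association(
    classes: Mapping[str, str],
    calls: Sequence[ExpressionCall],
    class_a: str = "missense",
    class_b: str | None = None,
) -> ChiSquareResult | None:
    """Pearson chi-square for functional class vs binary p53 positivity.

    ``class_b=None`` contrasts ``class_a`` against all other evaluable
    samples; otherwise the two named classes are contrasted.  Samples
    without an expression call are not evaluable.  Returns ``None`` with
    a warning when a class is empty.
    """
    positive = {c.sample_id: c.positive for c in calls}
    rows = {"a": [0, 0], "b": [0, 0]}
    for sid, cls in classes.items():
        if sid not in positive:
            continue
        if cls == class_a:
            key = "a"
        elif class_b is None and cls != class_a:
            key = "b"
        elif cls == class_b:
            key = "b"
        else:
            continue
        rows[key][0 if positive[sid] else 1] += 1
    table = np.array([rows["a"], rows["b"]], dtype=float)
    if table.sum(axis=1).min() == 0:
        import warnings

        warnings.warn("empty functional class; contrast skipped", stacklevel=2)
        return None
    return _chi2(table)
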