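"""IHC composite scoring, agreement statistics, class association."""

import numpy as np
import pytest

from tp53spectrum.ihc import (CATEGORY_ORDER, ExpressionCall, composite_score,
                              expression_association, percent_agreement,
                              sample_functional_class, score_ratings,
                              weighted_kappa)
from tp53spectrum.io_core import IHCRatingRow


@pytest.mark.parametrize(
    "pct, intensity, score, category, positive",
    [
        (4, 3, 12, "strong", True),
        (0, 3, 0, "negative", False),
        (2, 2, 4, "weak", False),
        (3, 2, 6, "moderate", True),
        (1, 1, 1, "weak", False),
        (3, 3, 9, "strong", True),
    ],
)
def test_composite_score_mapping(pct, intensity, score, category, positive):
    assert composite_score(pct, intensity) == (score, category, positive)


@pytest.mark.parametrize("pct, intensity", [(5, 1), (-1, 2), (2, 4)])
def test_composite_score_range_errors(pct, intensity):
    with pytest.raises(ValueError):
        composite_score(pct, intensity)


def test_composite_score_monotone_in_each_argument():
    for pct in range(4):
        for inten in range(3):
            assert composite_score(pct + 1, inten)[0] >= composite_score(pct, inten)[0]
            assert composite_score(pct, inten + 1)[0] >= composite_score(pct, inten)[0]


def _calls(categories, antibody="DO7"):
    rating = {"negative": (0, 0), "weak": (2, 2), "moderate": (3, 2), "strong": (4, 3)}
    return score_ratings(
        [IHCRatingRow(f"S{i}", antibody, *rating[c]) for i, c in enumerate(categories)]
    )


def test_percent_agreement_extremes():
    cats = ["negative", "weak", "moderate", "strong"] * 5
    assert percent_agreement(_calls(cats), _calls(cats, "1801")) == 100.0
    flipped = ["strong", "moderate", "weak", "negative"] * 5
    assert percent_agreement(_calls(cats), _calls(flipped, "1801")) == 0.0


def test_percent_agreement_fixture_value(cohort):
    calls = score_ratings(cohort.ihc_rows)
    do7 = [c for c in calls if c.antibody == "DO7"]
    ab2 = [c for c in calls if c.antibody == "1801"]
    assert len(do7) == len(ab2) == 107  # evaluable cases only
    # 95 concordant pairs of 107
    assert percent_agreement(do7, ab2) == pytest.approx(100 * 95 / 107, abs=1e-9)
    assert round(percent_agreement(do7, ab2), 1) == 88.8


def test_unpaired_samples_dropped_with_warning():
    a = _calls(["strong", "weak"])
    b = _calls(["strong"], "1801")
    with pytest.warns(UserWarning, match="unpaired"):
        assert percent_agreement(a, b) == 100.0


def test_kappa_identity_and_bounds():
    cats = ["negative", "weak", "moderate", "strong"] * 6
    assert weighted_kappa(_calls(cats), _calls(cats, "1801")) == pytest.approx(1.0)
    flipped = ["strong", "moderate", "weak", "negative"] * 6
    k = weighted_kappa(_calls(cats), _calls(flipped, "1801"))
    assert -1.0 <= k < 0


def test_kappa_near_zero_under_independence():
    """Two raters assigning categories independently (n=10^5)."""
    rng = np.random.default_rng(73)
    cats = np.array(CATEGORY_ORDER)
    a = _calls(cats[rng.integers(0, 4, size=100_000)])
    b = _calls(cats[rng.integers(0, 4, size=100_000)], "1801")
    assert abs(weighted_kappa(a, b)) < 0.02
    assert abs(weighted_kappa(a, b, weights="quadratic")) < 0.02


def test_kappa_matches_sklearn():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(4)
    idx_a = rng.integers(0, 4, size=500)
    # correlated second rater
    idx_b = np.clip(idx_a + rng.integers(-1, 2, size=500), 0, 3)
    cats = np.array(CATEGORY_ORDER)
    a, b = _calls(cats[idx_a]), _calls(cats[idx_b], "1801")
    for scheme in ("linear", "quadratic"):
        expected = cohen_kappa_score(idx_a, idx_b, weights=scheme)
        assert weighted_kappa(a, b, weights=scheme) == pytest.approx(expected, abs=1e-12)


def test_kappa_undefined_for_single_shared_category():
    a = _calls(["strong"] * 10)
    b = _calls(["strong"] * 10, "1801")
    with pytest.raises(ValueError, match="undefined"):
        weighted_kappa(a, b)


def test_functional_class_assignment(cohort, annotated):
    classes = sample_functional_class(
        [p.sample_id for p in cohort.participants], annotated
    )
    from collections import Counter

    counts = Counter(classes.values())
    assert counts["wild_type"] == 12
    assert counts["missense"] == 56
    assert counts["protein_null"] == 40
    assert counts["other_mutant"] == 11


def test_missense_vs_protein_null_association(cohort, annotated):
    """41/50 missense-positive vs 8/36 null-positive gives p < 0.001."""
    calls = [c for c in score_ratings(cohort.ihc_rows) if c.antibody == "DO7"]
    classes = sample_functional_class(
        [p.sample_id for p in cohort.participants], annotated
    )
    res = expression_association(classes, calls, "missense", "protein_null")
    assert res.df == 1
    assert res.p_value < 0.001


def test_perfectly_predictive_classes_p_tiny():
    calls = _calls(["strong"] * 30 + ["negative"] * 30)
    classes = {f"S{i}": ("missense" if i < 30 else "protein_null") for i in range(60)}
    res = expression_association(classes, calls, "missense", "protein_null")
    assert res.p_value < 1e-10


def test_empty_class_skips_with_warning():
    calls = _calls(["strong"] * 5)
    classes = {f"S{i}": "missense" for i in range(5)}
    with pytest.warns(UserWarning, match="empty"):
        assert expression_association(classes, calls, "missense", "protein_null") is None
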