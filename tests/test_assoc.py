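"""Record units, crude/Woolf odds ratios, and the IRLS logistic fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tp53spectrum.annotate import annotate_mutation, parse_variant
from tp53spectrum.assoc import (AGE_CUTOFF, ContingencyTable2x2,
                                build_record_units, category_strata_counts,
                                crude_or, fit_logistic, irls_logistic,
                                stratum_table, woolf_ci)
from tp53spectrum.io_core import Participant

cells = st.integers(min_value=1, max_value=500)


def _mini_cohort(tp53_model, n_participants, mutated_hgvs):
    """Participants P001..P00n; sample i carries mutated_hgvs.get(i, [])."""
    participants = [Participant(sample_id=f"P{i:03d}") for i in range(n_participants)]
    records = []
    for i, descs in mutated_hgvs.items():
        for d in descs:
            records.append(annotate_mutation(tp53_model, parse_variant(d, f"P{i:03d}")))
    return participants, records


def test_record_conservation(cohort, annotated):
    records = build_record_units(cohort.participants, annotated)
    wild_type = 119 - len({m.sample_id for m in annotated})
    assert len(records) == 120 + wild_type == 132
    assert sum(r.outcome_class == "WILD_TYPE" for r in records) == 12


def test_multi_mutation_participant_yields_one_record_per_mutation(tp53_model):
    participants, records = _mini_cohort(
        tp53_model, 3, {0: ["c.524G>A", "c.733C>A"], 1: ["c.817C>A"]}
    )
    units = build_record_units(participants, records)
    assert len(units) == 3 + 1  # 3 mutations + 1 wild-type participant
    assert sum(u.sample_id == "P000" for u in units) == 2


def test_orphan_mutation_sample_errors(tp53_model):
    participants, records = _mini_cohort(tp53_model, 1, {0: ["c.524G>A"]})
    bad = annotate_mutation(tp53_model, parse_variant("c.733C>A", "GHOST"))
    with pytest.raises(ValueError, match="GHOST"):
        build_record_units(participants, records + [bad])


def test_wild_type_only_cohort(tp53_model):
    participants, _ = _mini_cohort(tp53_model, 5, {})
    units = build_record_units(participants, [])
    assert len(units) == 5
    assert all(u.outcome_class == "WILD_TYPE" for u in units)


def test_stratum_record_totals_follow_derived_convention(cohort, annotated):
    """Records per tea stratum = mutations there + unmutated participants."""
    records = build_record_units(cohort.participants, annotated)
    counts = category_strata_counts(records, "GC>AT_CpG", "tea_interval")
    assert counts["4plus"][1] == 49   # 47 mutations + 2 wild-type
    assert counts["0-1"][1] == 19     # 15 mutations + 4 wild-type
    assert counts["0-1"][0] == 5
    assert counts["0-1"][2] == pytest.approx(26.3, abs=0.05)


@pytest.mark.parametrize(
    "table, expected_or, ci",
    [
        ((5, 14, 3, 46), 5.48, (1.16, 25.84)),
        ((4, 15, 2, 47), 6.27, (1.04, 37.69)),
        ((1, 1, 1, 1), 1.00, None),
    ],
)
def test_crude_or_and_woolf_ci(table, expected_or, ci):
    res = crude_or(ContingencyTable2x2(*table))
    assert res.or_point == pytest.approx(expected_or, abs=0.005)
    if ci is not None:
        assert res.ci_low == pytest.approx(ci[0], abs=0.005)
        assert res.ci_high == pytest.approx(ci[1], abs=0.005)


def test_zero_cell_is_undefined_unless_haldane():
    t = ContingencyTable2x2(0, 19, 7, 42)
    res = crude_or(t)
    assert not res.defined and res.undefined_reason == "zero_cell"
    corrected = crude_or(t, haldane=True)
    assert corrected.defined and corrected.or_point < 1


@given(a=cells, b=cells, c=cells, d=cells)
@settings(max_examples=100, deadline=None)
def test_or_reciprocity_and_woolf_symmetry(a, b, c, d):
    t = ContingencyTable2x2(a, b, c, d)
    swapped = ContingencyTable2x2(c, d, a, b)
    r1, r2 = crude_or(t), crude_or(swapped)
    assert r1.or_point * r2.or_point == pytest.approx(1.0, rel=1e-9)
    # Woolf interval is symmetric about the point on the log scale
    assert math.log(r1.ci_high / r1.or_point) == pytest.approx(
        math.log(r1.or_point / r1.ci_low), rel=1e-9
    )


def test_symmetric_table_ci_is_log_symmetric_about_one():
    low, high = woolf_ci(ContingencyTable2x2(10, 10, 10, 10))
    assert low * high == pytest.approx(1.0, rel=1e-9)


def test_woolf_width_shrinks_with_proportional_scaling():
    widths = []
    for scale in (1, 2, 5, 10):
        low, high = woolf_ci(ContingencyTable2x2(5 * scale, 14 * scale,
                                                 3 * scale, 46 * scale))
        widths.append(math.log(high) - math.log(low))
    assert widths == sorted(widths, reverse=True)


# -- logistic regression -----------------------------------------------------

def _bernoulli_design(rng, n, beta):
    X = np.column_stack([np.ones(n), rng.integers(0, 2, size=n),
                         rng.normal(size=n)])
    p = 1 / (1 + np.exp(-(X @ beta)))
    y = (rng.random(n) < p).astype(float)
    return X, y


def test_irls_matches_statsmodels_mle():
    import statsmodels.api as sm

    rng = np.random.default_rng(11)
    for _ in range(5):
        X, y = _bernoulli_design(rng, 400, np.array([-0.5, 0.8, 0.3]))
        fit = irls_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert fit.converged and not fit.separation
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)


def test_single_binary_covariate_equals_crude_or(cohort, annotated):
    """Saturated-model identity: one binary covariate's adjusted OR equals
    the crude 2x2 odds ratio."""
    records = build_record_units(cohort.participants, annotated)
    adj = fit_logistic(records, lambda oc: oc == "GC>AT", ["residence"])
    t = stratum_table(records, "GC>AT", "residence", "urban", "rural")
    crude = crude_or(t)
    assert adj["residence[urban]"].or_point == pytest.approx(crude.or_point, abs=1e-6)


def test_complete_separation_reported_not_converged(cohort, annotated):
    """The hottest-tea stratum has no G:C>T:A records, so the tea term
    separates and is reported rather than silently estimated."""
    records = build_record_units(cohort.participants, annotated)
    adj = fit_logistic(records, lambda oc: oc == "GC>TA", ["tea_interval"])
    assert adj["tea_interval[0-1]"].undefined_reason == "not_converged"
    # the estimable level is still reported
    assert adj["tea_interval[2-3]"].defined


def test_constant_outcome_errors(cohort, annotated):
    records = build_record_units(cohort.participants, annotated)
    with pytest.raises(ValueError, match="constant"):
        fit_logistic(records, lambda oc: False, ["sex"])


def test_collinear_design_errors(cohort, annotated):
    records = build_record_units(cohort.participants, annotated)
    # duplicating a covariate makes the dummy columns collinear
    with pytest.raises(ValueError, match="collinear"):
        fit_logistic(records, lambda oc: oc == "GC>AT", ["sex", "sex"])
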