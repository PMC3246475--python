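"""Synthetic case-series generator with the statistical structure the
analysis chain assumes.

Participants receive covariates drawn from the study's marginal
distributions; each carries 0-3 somatic mutations (multiplicity matching
the observed 12/96/9/2 split, which makes the expected mutation total
119 * (96 + 18 + 6)/119 = 120); mutation categories are drawn from a
multinomial logit: baseline log-odds (the observed spectrum) plus
additive covariate-dependent shifts, so a shift of delta on one category
is a true odds ratio of exp(delta) for that category against all other
mutation categories.  Variant descriptions are drawn from the toy gene
model's exhaustive site index, so they re-annotate to the intended
category by construction.  IHC calls are conditioned on the sample's
functional class (missense vs protein-null) with the observed positivity
rates.

The default covariate effect reproduces the study's headline shift: an
excess of CpG transitions, and a near-absence of transversions and
changes at A:T pairs, in the hottest-tea (0-1 minute) stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np

from .assoc import COVARIATE_LEVELS, build_record_units, crude_or, stratum_table
from .io_core import GeneModel, IHCRatingRow, Participant, RawVariantRow
from .paper_cohort import PaperCohort, build_site_index, toy_gene_model

#: generator-level category space (splice junctions annotate as complex_other)
GENERATOR_CATEGORIES = (
    "AT>CG", "AT>GC", "AT>TA", "GC>AT", "GC>AT_CpG", "GC>CG", "GC>TA",
    "deletion", "insertion", "splice",
)

_DEFAULT_SPECTRUM = {
    # observed 120-mutation composition
    "AT>CG": 9 / 120, "AT>GC": 12 / 120, "AT>TA": 4 / 120,
    "GC>AT": 30 / 120, "GC>AT_CpG": 16 / 120, "GC>CG": 6 / 120,
    "GC>TA": 20 / 120, "deletion": 16 / 120, "insertion": 3 / 120,
    "splice": 4 / 120,
}

_DEFAULT_MARGINALS = {
    "sex": {"female": 60 / 119, "male": 59 / 119},
    "ethnicity": {"non_turkmen": 54 / 119, "turkmen": 65 / 119},
    "residence": {"rural": 85 / 119, "urban": 34 / 119},
    "tobacco_opium": {"neither": 67 / 119, "tobacco": 16 / 119,
                      "opium": 15 / 119, "both": 21 / 119},
    "tea_interval": {"4plus": 46 / 106, "2-3": 43 / 106, "0-1": 17 / 106},
}

# hottest-tea spectrum shift: CpG transitions enriched, transversions and
# A:T changes essentially absent
_DEFAULT_EFFECTS = (
    ("tea_interval", "0-1", "GC>AT_CpG", math.log(5.5)),
    ("tea_interval", "0-1", "GC>TA", -4.0),
    ("tea_interval", "0-1", "GC>CG", -4.0),
    ("tea_interval", "0-1", "AT>GC", -4.0),
    ("tea_interval", "0-1", "AT>CG", -4.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable parameters of the cohort simulator (defaults = study scale)."""

    n_participants: int = 119
    covariate_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _DEFAULT_MARGINALS
    )
    covariate_missing: Mapping[str, float] = field(
        default_factory=lambda: {"tea_interval": 13 / 119}
    )
    age_mean: float = 65.5
    age_sd: float = 11.0
    multiplicity_probs: tuple[float, ...] = (12 / 119, 96 / 119, 9 / 119, 2 / 119)
    baseline_spectrum: Mapping[str, float] = field(
        default_factory=lambda: _DEFAULT_SPECTRUM
    )
    effects: tuple[tuple[str, str, str, float], ...] = _DEFAULT_EFFECTS
    p_positive_missense: float = 0.82
    p_positive_null: float = 1 - 0.778
    p_positive_wild: float = 0.10
    p_core_lost: float = 12 / 119
    p_antibody_agree: float = 0.888
    with_ihc: bool = True

    def __post_init__(self) -> None:
        for name, probs in [("multiplicity_probs", list(self.multiplicity_probs)),
                            ("baseline_spectrum", list(self.baseline_spectrum.values()))]:
            if abs(sum(probs) - 1) > 1e-9 or min(probs) < 0:
                raise ValueError(f"{name} is not a probability vector")
        for cov, marg in self.covariate_marginals.items():
            if abs(sum(marg.values()) - 1) > 1e-9:
                raise ValueError(f"covariate_marginals[{cov}] does not sum to 1")


@lru_cache(maxsize=1)
def _spectrum_sites() -> dict[str, list[tuple[str, str]]]:
    """(hgvs, effect) pools per generator category on the toy model."""
    model = toy_gene_model()
    index = build_site_index(model)
    pools: dict[str, list[tuple[str, str]]] = {}
    for (category, effect, _exon), sites in index.items():
        pools.setdefault(category, []).extend(
            (f"c.{pos}{ref}>{alt}", effect) for pos, ref, alt in sites
        )
    for cat in pools:
        pools[cat].sort()
    dels, inss = [], []
    for _exon, start, end in model.exon_bounds:
        for pos in range(start + 1, end - 1, 7):
            ref = model.cds_sequence[pos - 1:pos + 1]
            dels.append((f"c.{pos}_{pos + 1}del{ref}", "frameshift"))
            inss.append((f"c.{pos}_{pos + 1}insA", "frameshift"))
    pools["deletion"] = dels
    pools["insertion"] = inss
    pools["splice"] = [(f"c.{end}+1G>T", "splice")
                       for _, _, end in model.exon_bounds[:-1]]
    return pools


@dataclass
class SimulatedCohort(PaperCohort):
    """A simulated cohort (same shape as the deterministic fixture)."""

    drawn_categories: list[str] = field(default_factory=list)


def simulate_cohort(config: SimulationConfig, seed: int) -> SimulatedCohort:
    """Draw a full cohort (participants, mutations, IHC) reproducibly.

    The same seed always yields byte-identical tables; draws are grouped
    (not per-participant) so large cohorts simulate quickly.
    """
    rng = np.random.default_rng(seed)
    model = toy_gene_model()
    pools = _spectrum_sites()
    categories = list(config.baseline_spectrum)
    with np.errstate(divide="ignore"):  # zero-probability categories -> -inf
        base_logit = np.log(np.array([config.baseline_spectrum[c]
                                      for c in categories]))
    n = config.n_participants

    # covariates, vectorized per variable
    cov_values: dict[str, list] = {}
    for name, marg in config.covariate_marginals.items():
        levels = list(marg)
        idx = rng.choice(len(levels), size=n, p=list(marg.values()))
        vals = [levels[i] for i in idx]
        p_missing = config.covariate_missing.get(name, 0.0)
        if p_missing:
            miss = rng.random(n) < p_missing
            vals = [None if m else v for v, m in zip(vals, miss)]
        cov_values[name] = vals
    ages = np.round(np.clip(rng.normal(config.age_mean, config.age_sd, size=n),
                            30, 95), 1)
    participants = [
        Participant(
            sample_id=f"SIM{i + 1:05d}", age_years=float(ages[i]),
            **{name: cov_values[name][i] for name in cov_values},
        )
        for i in range(n)
    ]

    # per-participant category distribution, grouped by effect signature
    signatures: list[tuple] = []
    for i in range(n):
        sig = tuple(
            (categories.index(cat), shift)
            for cov_name, level, cat, shift in config.effects
            if cov_values.get(cov_name, [None] * n)[i] == level
        )
        signatures.append(sig)
    probs_by_sig: dict[tuple, np.ndarray] = {}
    for sig in set(signatures):
        logits = base_logit.copy()
        for cat_idx, shift in sig:
            logits[cat_idx] += shift
        p = np.exp(logits - logits.max())
        probs_by_sig[sig] = p / p.sum()

    multiplicity = rng.choice(len(config.multiplicity_probs), size=n,
                              p=list(config.multiplicity_probs))
    # draw all categories per signature group in one call, then deal them
    # back to participants in index order
    need: dict[tuple, int] = {}
    for i in range(n):
        need[signatures[i]] = need.get(signatures[i], 0) + int(multiplicity[i])
    queues = {
        sig: [categories[k] for k in
              rng.choice(len(categories), size=count, p=probs_by_sig[sig])]
        for sig, count in sorted(need.items()) if count
    }
    mutation_rows: list[RawVariantRow] = []
    drawn: list[str] = []
    effects_by_sample: dict[str, list[str]] = {}
    for i in range(n):
        sid = participants[i].sample_id
        effs: list[str] = []
        for _ in range(int(multiplicity[i])):
            cat = queues[signatures[i]].pop()
            pool = pools[cat]
            hgvs, effect = pool[rng.integers(0, len(pool))]
            mutation_rows.append(RawVariantRow(sample_id=sid, hgvs_c=hgvs))
            drawn.append(cat)
            effs.append(effect)
        effects_by_sample[sid] = effs

    ihc_rows = (_simulate_ihc(rng, effects_by_sample, config)
                if config.with_ihc else [])
    return SimulatedCohort(model, participants, mutation_rows, ihc_rows,
                           drawn_categories=drawn)


_POSITIVE_RATINGS = ((3, 2), (4, 3))   # moderate, strong
_NEGATIVE_RATINGS = ((0, 0), (2, 2))   # negative, weak


def _functional_class(effects: list[str]) -> str:
    if not effects:
        return "wild_type"
    if "missense" in effects:
        return "missense"
    if {"nonsense", "frameshift", "splice"} & set(effects):
        return "protein_null"
    return "other_mutant"


def _simulate_ihc(rng, effects_by_sample: Mapping[str, list],
                  config: SimulationConfig) -> list[IHCRatingRow]:
    p_positive = {"missense": config.p_positive_missense,
                  "protein_null": config.p_positive_null,
                  "other_mutant": config.p_positive_wild,
                  "wild_type": config.p_positive_wild}
    rows = []
    for sid, effects in effects_by_sample.items():
        if rng.random() < config.p_core_lost:
            continue
        positive = rng.random() < p_positive[_functional_class(effects)]
        pool = _POSITIVE_RATINGS if positive else _NEGATIVE_RATINGS
        pct, inten = pool[rng.integers(0, len(pool))]
        rows.append(IHCRatingRow(sid, "DO7", pct, inten))
        if rng.random() < config.p_antibody_agree:
            rows.append(IHCRatingRow(sid, "1801", pct, inten))
        else:
            alt = _NEGATIVE_RATINGS if positive else _POSITIVE_RATINGS
            pct2, inten2 = alt[rng.integers(0, len(alt))]
            rows.append(IHCRatingRow(sid, "1801", pct2, inten2))
    return rows


def recover_parameters(
    config: SimulationConfig,
    covariate: str,
    level: str,
    category: str,
    true_log_or: float,
    n_replicates: int = 200,
    seed: int = 0,
    include_wildtype: bool = False,
) -> dict:
    """Bias and CI coverage of the crude OR across simulation replicates.

    Each replicate simulates a cohort, runs the annotate -> record-unit ->
    crude-OR chain, and compares the estimated log odds ratio for
    ``category`` (``level`` vs the covariate's reference level) with the
    generating value.  With ``include_wildtype=False`` the contrast is
    among mutation records only, where the multinomial-logit shift is
    exactly the log odds ratio.
    """
    ref = COVARIATE_LEVELS[covariate][1]
    log_ors: list[float] = []
    covered = 0
    n_defined = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cohort = simulate_cohort(config, int(rng.integers(0, 2**31 - 1)))
        records = build_record_units(cohort.participants, cohort.annotated())
        if not include_wildtype:
            records = [r for r in records if r.outcome_class != "WILD_TYPE"]
        table = stratum_table(records, category, covariate, level, ref)
        res = crude_or(table)
        if not res.defined:
            continue
        n_defined += 1
        log_ors.append(math.log(res.or_point))
        if res.ci_low <= math.exp(true_log_or) <= res.ci_high:
            covered += 1
    mean_log_or = float(np.mean(log_ors)) if log_ors else float("nan")
    return {
        "n_replicates": n_replicates,
        "n_defined": n_defined,
        "mean_log_or": mean_log_or,
        "bias": mean_log_or - true_log_or,
        "coverage": covered / n_defined if n_defined else float("nan"),
    }


def spectrum_frequencies(cohort: SimulatedCohort) -> dict[str, float]:
    """Observed generator-category frequencies of a simulated cohort."""
    counts = dict.fromkeys(GENERATOR_CATEGORIES, 0)
    for cat in cohort.drawn_categories:
        counts[cat] += 1
    total = sum(counts.values())
    return {c: k / total for c, k in counts.items()} if total else dict(counts)
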