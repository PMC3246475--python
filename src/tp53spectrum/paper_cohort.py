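"""Deterministic study-scale fixture cohort with published-table margins.

This module builds, entirely in code, a 119-participant cohort whose
stratum margins reproduce the published cohort tables: participant,
mutated-participant and mutation counts per covariate stratum, and the
per-stratum counts of the three analysed mutation categories (G:C>A:T
outside CpG, G:C>A:T at CpG, G:C>T:A).  Running the full analysis chain
on this cohort therefore reproduces the published spectrum table,
chi-square p-values, crude odds ratios and IHC class association from
first principles.

The gene model uses the real TP53 exon boundaries in coding coordinates
but a synthetic coding sequence (the fixture is sequence-agnostic: every
statistic depends only on category/effect/exon composition).  Selected
codons are engineered so that the recurrent-hotspot and PAH-adduct-site
placements admit the intended substitution classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .annotate import (CodingVariant, MutationRecord, annotate_mutation,
                       parse_variant)
from .io_core import (GeneModel, IHCRatingRow, Participant, RawVariantRow)

# Real TP53 exon boundaries in 1-based coding coordinates (exons 2-11
# carry the CDS; exon 2 opens the reading frame).
TP53_EXON_BOUNDS = (
    (2, 1, 74), (3, 75, 96), (4, 97, 375), (5, 376, 559), (6, 560, 672),
    (7, 673, 782), (8, 783, 919), (9, 920, 993), (10, 994, 1100), (11, 1101, 1182),
)

_STOPS = {"TAA", "TAG", "TGA"}
# codons engineered to host the hotspot / PAH-site placements
_ENGINEERED = {
    156: "AAA", 157: "CCA", 158: "GAA", 175: "CGA", 245: "CGT",
    248: "GCA", 273: "CGT", 281: "AAA", 282: "GGA",
}
# a block of codons planted in every exon guaranteeing at least one site
# for each substitution class x effect the mutation plan may request
_UTILITY_BLOCK = ("CAG", "CAA", "TGG", "ACG", "TCA", "GAA",
                  "CTG", "TAT", "GCA", "CGA", "CTC", "CCA")
_UTILITY_START = {4: 40, 5: 130, 6: 195, 7: 230, 8: 290, 9: 310, 10: 340}
_CDS_SEED = 20110419  # internal; fixes the synthetic sequence


@lru_cache(maxsize=1)
def toy_gene_model() -> GeneModel:
    """Synthetic 1182-nt CDS with real TP53 exon structure.

    The sequence is deterministically generated (no internal stop
    codons, ATG start, TAA stop) and is *not* the real TP53 sequence;
    engineered codons guarantee sites for the hotspot/PAH placements.
    """
    rng = np.random.default_rng(_CDS_SEED)
    bases = "ACGT"
    codons = ["ATG"]
    while len(codons) < 393:
        c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    for start in _UTILITY_START.values():
        for k, seq in enumerate(_UTILITY_BLOCK):
            codons[start - 1 + k] = seq
    for codon_n, seq in _ENGINEERED.items():
        codons[codon_n - 1] = seq
    return GeneModel(cds_sequence="".join(codons), exon_bounds=TP53_EXON_BOUNDS)


# -- substitution site index --------------------------------------------------

def build_site_index(model: GeneModel) -> dict:
    """Map (category, effect, exon) -> ordered list of (pos, ref, alt).

    Enumerates every possible single-base substitution of the CDS and
    classifies it with the annotator, so generated variant descriptions
    round-trip to their intended class by construction.
    """
    index: dict[tuple[str, str, int], list[tuple[int, str, str]]] = {}
    for pos in range(1, len(model.cds_sequence) + 1):
        exon = model.exon_of(pos)
        if exon is None:
            continue
        ref = model.base(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            var = CodingVariant(sample_id="", kind="substitution",
                                cds_position=pos, ref=ref, alt=alt,
                                raw=f"c.{pos}{ref}>{alt}")
            rec = annotate_mutation(model, var)
            index.setdefault((rec.category, rec.effect, exon), []).append(
                (pos, ref, alt)
            )
    return index


class SitePicker:
    """Deterministic, non-repeating site chooser over a site index."""

    def __init__(self, model: GeneModel):
        self.model = model
        self.index = build_site_index(model)
        self._used: set[tuple[int, str]] = set()
        self._special = set(model.hotspot_codons) | set(model.pah_codons)

    def pick(self, category: str, effect: str, exon: int,
             codon: int | None = None) -> str:
        sites = self.index.get((category, effect, exon), [])
        for pos, ref, alt in sites:
            c = self.model.codon_number(pos)
            if codon is not None and c != codon:
                continue
            # keep unsolicited mutations off hotspot/PAH codons so the
            # fixture's hotspot and PAH-site tallies stay exact
            if codon is None and c in self._special:
                continue
            if (pos, alt) in self._used:
                continue
            self._used.add((pos, alt))
            return f"c.{pos}{ref}>{alt}"
        raise RuntimeError(
            f"no unused site for {category}/{effect}/exon{exon}/codon{codon}"
        )


# -- the 120-mutation plan ----------------------------------------------------
# (category, effect, exon, preferred codon) x count; substitution part.
# Exon 5-8 totals per category match the published spectrum table
# (A:T>C:G 8, A:T>G:C 11, A:T>T:A 3, Others 16, G:C>A:T 26, CpG 15,
# G:C>C:G 5, G:C>T:A 17); full-cohort totals match the reported 46
# G:C>A:T (16 at CpG), 20 G:C>T:A and 16 deletions.
_SUBSTITUTION_PLAN: tuple[tuple[str, str, int, int | None, int], ...] = (
    # G:C>A:T outside CpG (30)
    ("GC>AT", "nonsense", 5, None, 2), ("GC>AT", "silent", 5, None, 1),
    ("GC>AT", "missense", 5, None, 5),
    ("GC>AT", "nonsense", 6, None, 2), ("GC>AT", "missense", 6, None, 4),
    ("GC>AT", "nonsense", 7, None, 2), ("GC>AT", "missense", 7, None, 4),
    ("GC>AT", "nonsense", 8, None, 1), ("GC>AT", "silent", 8, None, 1),
    ("GC>AT", "missense", 8, 282, 2), ("GC>AT", "missense", 8, None, 2),
    ("GC>AT", "nonsense", 4, None, 1), ("GC>AT", "missense", 4, None, 1),
    ("GC>AT", "missense", 9, None, 1), ("GC>AT", "missense", 10, None, 1),
    # G:C>A:T at CpG (16)
    ("GC>AT_CpG", "nonsense", 5, 175, 1), ("GC>AT_CpG", "missense", 5, 175, 1),
    ("GC>AT_CpG", "missense", 5, None, 2),
    ("GC>AT_CpG", "nonsense", 6, None, 1), ("GC>AT_CpG", "silent", 6, None, 1),
    ("GC>AT_CpG", "missense", 6, None, 2),
    ("GC>AT_CpG", "nonsense", 7, None, 1), ("GC>AT_CpG", "missense", 7, 245, 1),
    ("GC>AT_CpG", "missense", 7, None, 2),
    ("GC>AT_CpG", "nonsense", 8, None, 1), ("GC>AT_CpG", "missense", 8, 273, 1),
    ("GC>AT_CpG", "missense", 8, None, 1),
    ("GC>AT_CpG", "missense", 4, None, 1),
    # G:C>T:A (20)
    ("GC>TA", "nonsense", 5, 158, 1), ("GC>TA", "missense", 5, 157, 2),
    ("GC>TA", "missense", 5, None, 2),
    ("GC>TA", "nonsense", 6, None, 2), ("GC>TA", "missense", 6, None, 2),
    ("GC>TA", "missense", 7, 248, 2), ("GC>TA", "missense", 7, 245, 1),
    ("GC>TA", "missense", 7, None, 1),
    ("GC>TA", "nonsense", 8, None, 1), ("GC>TA", "silent", 8, None, 1),
    ("GC>TA", "missense", 8, 273, 2),
    ("GC>TA", "nonsense", 4, None, 1),
    ("GC>TA", "missense", 9, None, 1), ("GC>TA", "missense", 10, None, 1),
    # A:T>C:G (9)
    ("AT>CG", "missense", 5, None, 2),
    ("AT>CG", "silent", 6, None, 1), ("AT>CG", "missense", 6, None, 1),
    ("AT>CG", "missense", 7, None, 2), ("AT>CG", "missense", 8, None, 2),
    ("AT>CG", "missense", 4, None, 1),
    # A:T>G:C (12)
    ("AT>GC", "missense", 5, None, 3),
    ("AT>GC", "silent", 6, None, 1), ("AT>GC", "missense", 6, None, 2),
    ("AT>GC", "silent", 7, None, 1), ("AT>GC", "missense", 7, None, 2),
    ("AT>GC", "missense", 8, None, 2), ("AT>GC", "missense", 9, None, 1),
    # A:T>T:A (4)
    ("AT>TA", "missense", 5, None, 1), ("AT>TA", "nonsense", 6, None, 1),
    ("AT>TA", "missense", 7, None, 1), ("AT>TA", "missense", 4, None, 1),
    # G:C>C:G (6)
    ("GC>CG", "nonsense", 5, None, 1), ("GC>CG", "missense", 5, None, 1),
    ("GC>CG", "silent", 6, None, 1), ("GC>CG", "nonsense", 7, None, 1),
    ("GC>CG", "missense", 8, None, 1), ("GC>CG", "missense", 10, None, 1),
)

# frameshift 2-nt deletions: exon -> how many
_FSDEL_EXONS = (5, 5, 5, 6, 6, 6, 7, 7, 7, 8, 8, 8, 4, 9)
_IFDEL_EXONS = (5, 8)          # in-frame 3-nt deletions
_FSINS_EXONS = (6, 7)          # frameshift 1-nt insertions
_IFINS_EXONS = (10,)           # in-frame 3-nt insertion
_SPLICE_DESCRIPTIONS = ("c.375+1G>T", "c.97-1G>A", "c.993+1G>T", "c.1100+1G>A")

_EXON_START = {e: s for e, s, _ in TP53_EXON_BOUNDS}


def _indel_descriptions(model: GeneModel) -> dict[str, list[str]]:
    """Deterministic indel HGVS strings placed mid-exon, off special codons."""
    out = {"fsdel": [], "ifdel": [], "fsins": [], "ifins": []}
    counters: dict[int, int] = {}
    for exon in _FSDEL_EXONS:
        i = counters.get(exon, 0)
        counters[exon] = i + 1
        start = _EXON_START[exon] + 10 + 5 * i
        ref = model.cds_sequence[start - 1:start + 1]
        out["fsdel"].append(f"c.{start}_{start + 1}del{ref}")
    for exon in _IFDEL_EXONS:
        start = _EXON_START[exon] + 40
        ref = model.cds_sequence[start - 1:start + 2]
        out["ifdel"].append(f"c.{start}_{start + 2}del{ref}")
    for exon in _FSINS_EXONS:
        start = _EXON_START[exon] + 10
        out["fsins"].append(f"c.{start}_{start + 1}insA")
    for exon in _IFINS_EXONS:
        start = _EXON_START[exon] + 10
        out["ifins"].append(f"c.{start}_{start + 1}insACT")
    return out


# -- participant profiles -----------------------------------------------------

_MULTI_PROFILES: tuple[tuple[str, ...], ...] = (
    ("GC>AT", "GC>AT_CpG"), ("GC>AT", "AT>GC"), ("GC>AT_CpG", "AT>CG"),
    ("GC>AT", "GC>TA"), ("GC>TA", "AT>GC"), ("GC>AT", "GC>AT"),
    ("GC>AT", "GC>AT_CpG"), ("GC>TA", "AT>CG"), ("AT>GC", "AT>TA"),
    ("GC>AT", "GC>TA", "AT>GC"), ("GC>AT", "GC>AT_CpG", "GC>CG"),
)

_NULL_SINGLES = (
    [("GC>AT", "nonsense")] * 8 + [("GC>AT_CpG", "nonsense")] * 4
    + [("GC>TA", "nonsense")] * 5 + [("AT>TA", "nonsense")] * 1
    + [("GC>CG", "nonsense")] * 2
    + [("deletion", "frameshift")] * 14 + [("insertion", "frameshift")] * 2
    + [("splice", "splice")] * 4
)
_OTHER_SINGLES = (
    [("GC>AT", "silent")] * 2 + [("GC>AT_CpG", "silent")] * 1
    + [("GC>TA", "silent")] * 1 + [("AT>GC", "silent")] * 2
    + [("AT>CG", "silent")] * 1 + [("GC>CG", "silent")] * 1
    + [("deletion", "inframe")] * 2 + [("insertion", "inframe")] * 1
)
_MISSENSE_SINGLES = (
    [("GC>AT", "missense")] * 12 + [("GC>AT_CpG", "missense")] * 7
    + [("GC>TA", "missense")] * 10 + [("AT>CG", "missense")] * 6
    + [("AT>GC", "missense")] * 6 + [("AT>TA", "missense")] * 2
    + [("GC>CG", "missense")] * 2
)

N_WILD_TYPE = 12


# -- published stratum constraints -------------------------------------------
# per stratum: (participants, mutated, mutations, GC>AT, CpG, GC>TA,
#               forbidden-in-hottest-tea count); None = unconstrained.

_CONSTRAINTS: dict[str, dict[object, tuple]] = {
    "age_group": {
        "<66": (58, 54, 60, 15, 8, 13, None),
        ">=66": (61, 53, 60, 15, 8, 7, None),
    },
    "sex": {
        "female": (60, 52, 62, 13, 6, 9, None),
        "male": (59, 55, 58, 17, 10, 11, None),
    },
    "ethnicity": {
        "non_turkmen": (54, 50, 58, 14, 8, 10, None),
        "turkmen": (65, 57, 62, 16, 8, 10, None),
    },
    "residence": {
        "rural": (85, 77, 88, 25, 12, 13, None),
        "urban": (34, 30, 32, 5, 4, 7, None),
    },
    "tobacco_opium": {
        "neither": (67, 61, 69, 19, 8, 14, None),
        "tobacco": (16, 12, 15, 3, 1, 1, None),
        "opium": (15, 15, 16, 4, 3, 1, None),
        "both": (21, 19, 20, 4, 4, 4, None),
    },
    "tea_interval": {
        "4plus": (46, 44, 47, 12, 3, 7, None),
        "2-3": (43, 39, 45, 9, 6, 10, None),
        "0-1": (17, 13, 15, 6, 5, 0, 0),
        None: (13, 11, 13, 3, 2, 3, None),
    },
    "tumor_size": {
        "<5": (27, 25, 28, None, None, None, None),
        "5-8": (67, 62, 70, None, None, None, None),
        ">8": (15, 12, 14, None, None, None, None),
        None: (10, 8, 8, None, None, None, None),
    },
    # stage mutation totals are left unconstrained: the published
    # per-stage mutation counts are not jointly consistent with the
    # participant margins (stage is not used by any analysis here)
    "stage": {
        "I": (4, 3, None, None, None, None, None),
        "II": (14, 12, None, None, None, None, None),
        "III": (37, 32, None, None, None, None, None),
        "IV": (52, 49, None, None, None, None, None),
        None: (12, 11, None, None, None, None, None),
    },
}

# categories absent from the hottest-tea stratum (transversions and
# changes at A:T pairs other than A:T>T:A are seen only with longer
# pour-to-drink intervals)
_HOT_TEA_FORBIDDEN = frozenset({"GC>TA", "GC>CG", "AT>GC", "AT>CG"})


def _profile_vector(categories: tuple[str, ...]) -> np.ndarray:
    """(1, mutated, n_mut, GC>AT, CpG, GC>TA, forbidden) for one participant."""
    return np.array(
        [
            1,
            1 if categories else 0,
            len(categories),
            sum(c == "GC>AT" for c in categories),
            sum(c == "GC>AT_CpG" for c in categories),
            sum(c == "GC>TA" for c in categories),
            sum(c in _HOT_TEA_FORBIDDEN for c in categories),
        ],
        dtype=int,
    )


def _solve_partition(
    profiles: np.ndarray, strata: list[tuple], rng: np.random.Generator,
    max_steps: int = 400_000,
) -> np.ndarray:
    """Assign each participant to a stratum matching all exact targets.

    Deterministic seeded local search: start from a sequential fill,
    then swap random participant pairs whenever the summed absolute
    deviation from the targets does not increase.  Raises if the exact
    solution is not reached (the shipped constraints are feasible).
    """
    n = profiles.shape[0]
    sizes = [c[0] for _, c in strata]
    assert sum(sizes) == n
    assign = np.repeat(np.arange(len(strata)), sizes)
    assign = assign[rng.permutation(n)]

    targets = []
    masks = []
    for _, cons in strata:
        t = np.array([x if x is not None else 0 for x in cons], dtype=int)
        m = np.array([x is not None for x in cons], dtype=bool)
        targets.append(t)
        masks.append(m)
    targets = np.array(targets)
    masks = np.array(masks)

    def totals(a: np.ndarray) -> np.ndarray:
        return np.array([profiles[a == s].sum(axis=0) for s in range(len(strata))])

    cur = totals(assign)
    cost = int(np.abs((cur - targets))[masks].sum())
    for _ in range(max_steps):
        if cost == 0:
            break
        i, j = rng.integers(0, n, size=2)
        si, sj = assign[i], assign[j]
        if si == sj:
            continue
        delta = profiles[j] - profiles[i]
        new_i = cur[si] + delta
        new_j = cur[sj] - delta
        new_cost = cost \
            - int(np.abs(cur[si] - targets[si])[masks[si]].sum()) \
            - int(np.abs(cur[sj] - targets[sj])[masks[sj]].sum()) \
            + int(np.abs(new_i - targets[si])[masks[si]].sum()) \
            + int(np.abs(new_j - targets[sj])[masks[sj]].sum())
        if new_cost <= cost:
            assign[i], assign[j] = sj, si
            cur[si], cur[sj] = new_i, new_j
            cost = new_cost
    if cost != 0:
        raise RuntimeError("stratum constraint solve did not reach zero deviation")
    return assign


# -- cohort assembly ----------------------------------------------------------

@dataclass
class PaperCohort:
    """The deterministic fixture cohort and its gene model."""

    model: GeneModel
    participants: list[Participant]
    mutation_rows: list[RawVariantRow]
    ihc_rows: list[IHCRatingRow]

    def annotated(self) -> list[MutationRecord]:
        return [
            annotate_mutation(self.model, parse_variant(r.hgvs_c, r.sample_id))
            for r in self.mutation_rows
        ]


def _category_queues(model: GeneModel) -> dict[tuple[str, str], list[str]]:
    """Expand the mutation plan into per-(category, effect) HGVS queues."""
    picker = SitePicker(model)
    queues: dict[tuple[str, str], list[str]] = {}
    for category, effect, exon, codon, count in _SUBSTITUTION_PLAN:
        for _ in range(count):
            queues.setdefault((category, effect), []).append(
                picker.pick(category, effect, exon, codon)
            )
    indels = _indel_descriptions(model)
    queues[("deletion", "frameshift")] = indels["fsdel"]
    queues[("deletion", "inframe")] = indels["ifdel"]
    queues[("insertion", "frameshift")] = indels["fsins"]
    queues[("insertion", "inframe")] = indels["ifins"]
    queues[("splice", "splice")] = list(_SPLICE_DESCRIPTIONS)
    return queues


def paper_cohort() -> PaperCohort:
    """Build the full deterministic fixture cohort.

    119 participants (12 wild-type, 96 with one mutation, 9 with two and
    2 with three; 120 mutations), with covariates assigned so that every
    published stratum margin in the constraint table holds exactly, and
    IHC ratings whose agreement and class association match the reported
    evaluable-case counts.
    """
    model = toy_gene_model()
    queues = _category_queues(model)
    iters = {k: iter(v) for k, v in queues.items()}

    def take(category: str, effect: str) -> str:
        return next(iters[(category, effect)])

    # assemble per-participant mutation lists in a fixed order
    participant_muts: list[tuple[tuple[str, str], ...]] = []
    participant_muts += [()] * N_WILD_TYPE
    participant_muts += [(ce,) for ce in _NULL_SINGLES]
    participant_muts += [(ce,) for ce in _OTHER_SINGLES]
    participant_muts += [(ce,) for ce in _MISSENSE_SINGLES]
    participant_muts += [
        tuple((c, "missense") for c in cats) for cats in _MULTI_PROFILES
    ]
    assert len(participant_muts) == 119
    assert sum(len(m) for m in participant_muts) == 120

    sample_ids = [f"GS{i + 1:03d}" for i in range(119)]
    mutation_rows: list[RawVariantRow] = []
    for sid, muts in zip(sample_ids, participant_muts):
        for category, effect in muts:
            mutation_rows.append(RawVariantRow(sample_id=sid,
                                               hgvs_c=take(category, effect)))
    for key, it in iters.items():
        assert next(it, None) is None, f"unconsumed sites for {key}"

    # covariate assignment: one independent partition per covariate
    profiles = np.array(
        [_profile_vector(tuple(c for c, _ in m)) for m in participant_muts]
    )
    rng = np.random.default_rng(171230)
    values: dict[str, list] = {}
    for cov, strata_map in _CONSTRAINTS.items():
        strata = list(strata_map.items())
        assign = _solve_partition(profiles, strata, rng)
        labels = [strata[s][0] for s in assign]
        values[cov] = labels

    # deterministic ages consistent with the age-group split
    young = np.round(np.linspace(38.0, 65.0, 58), 1)
    old = np.round(np.linspace(66.0, 88.0, 61), 1)
    yi = iter(young)
    oi = iter(old)
    size_map = {"<5": 4.0, "5-8": 6.5, ">8": 9.5, None: None}

    participants = []
    for i, sid in enumerate(sample_ids):
        age_group = values["age_group"][i]
        participants.append(
            Participant(
                sample_id=sid,
                age_years=float(next(yi) if age_group == "<66" else next(oi)),
                sex=values["sex"][i],
                ethnicity=values["ethnicity"][i],
                residence=values["residence"][i],
                tobacco_opium=values["tobacco_opium"][i],
                tea_interval=values["tea_interval"][i],
                tumor_size_cm=size_map[values["tumor_size"][i]],
                stage=values["stage"][i],
            )
        )

    ihc_rows = _ihc_rows(sample_ids, participant_muts)
    return PaperCohort(model, participants, mutation_rows, ihc_rows)


# IHC design: 12 cores lost (not evaluable); among evaluable cases the
# positivity counts follow the reported class table (41/50 missense
# positive, 28/36 protein-null negative), and the second antibody agrees
# on the expression category for all but 12 samples.
_RATING_BY_CATEGORY = {"negative": (0, 0), "weak": (2, 2),
                       "moderate": (3, 2), "strong": (4, 3)}
_CATEGORY_STEP = {"negative": "weak", "weak": "negative",
                  "moderate": "weak", "strong": "moderate"}


def _ihc_rows(sample_ids, participant_muts) -> list[IHCRatingRow]:
    def klass(muts) -> str:
        effects = [e for _, e in muts]
        if not effects:
            return "wild_type"
        if "missense" in effects:
            return "missense"
        if {"nonsense", "frameshift", "splice"} & set(effects):
            return "protein_null"
        return "other_mutant"

    groups: dict[str, list[str]] = {}
    for sid, muts in zip(sample_ids, participant_muts):
        groups.setdefault(klass(muts), []).append(sid)

    lost = set(groups["missense"][:6] + groups["protein_null"][:4]
               + groups["other_mutant"][:2])
    n_positive = {"missense": 41, "protein_null": 8, "other_mutant": 2,
                  "wild_type": 2}

    rows: list[IHCRatingRow] = []
    discordant: list[str] = []
    for cls in ("missense", "protein_null", "other_mutant", "wild_type"):
        evaluable = [s for s in groups[cls] if s not in lost]
        for j, sid in enumerate(evaluable):
            positive = j < n_positive[cls]
            category = ("strong" if j % 2 else "moderate") if positive \
                else ("weak" if j % 2 else "negative")
            pct, inten = _RATING_BY_CATEGORY[category]
            rows.append(IHCRatingRow(sid, "DO7", pct, inten))
            rows.append(IHCRatingRow(sid, "1801", pct, inten))
            discordant.append((sid, category))
    # make exactly 12 of the 107 evaluable pairs disagree by one category
    flip = {sid: cat for sid, cat in discordant[5::9][:12]}
    assert len(flip) == 12
    out = []
    for r in rows:
        if r.antibody == "1801" and r.sample_id in flip:
            pct, inten = _RATING_BY_CATEGORY[_CATEGORY_STEP[flip[r.sample_id]]]
            out.append(IHCRatingRow(r.sample_id, "1801", pct, inten))
        else:
            out.append(r)
    return out


def tehran_spectrum():
    """Comparison-cohort spectrum (exons 5-8, n=85) from published counts."""
    from .spectrum import SpectrumTable

    return SpectrumTable(
        cohort_label="Tehran",
        counts={"AT>CG": 4, "AT>GC": 9, "AT>TA": 5, "Others": 11,
                "GC>AT": 14, "GC>AT_CpG": 29, "GC>CG": 3, "GC>TA": 10},
        grouping="eight_way",
        exon_filter=(5, 8),
    )
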