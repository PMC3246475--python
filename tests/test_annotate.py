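"""Variant parsing and strand-normalized classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tp53spectrum.annotate import (CodingVariant, VariantParseError,
                                   annotate_mutation, basepair_change,
                                   cpg_context, effect_class, parse_variant)
from tp53spectrum.io_core import GeneModel

from .oracles import brute_force_category, brute_force_effect


@pytest.mark.parametrize(
    "desc, kind, pos, offset, ref, alt, end",
    [
        ("c.524G>A", "substitution", 524, 0, "G", "A", None),
        ("c.375+1G>T", "splice", 375, 1, "G", "T", None),
        ("c.97-1G>A", "splice", 97, -1, "G", "A", None),
        ("c.5_6delCG", "deletion", 5, 0, "CG", "", 6),
        ("c.5delC", "deletion", 5, 0, "C", "", 5),
        ("c.7_8insAA", "insertion", 7, 0, "", "AA", 8),
        ("c.5_7delinsAT", "delins", 5, 0, "", "AT", 7),
    ],
)
def test_parse_variant_grammar(desc, kind, pos, offset, ref, alt, end):
    v = parse_variant(desc, sample_id="S1")
    assert (v.kind, v.cds_position, v.offset) == (kind, pos, offset)
    assert (v.ref, v.alt) == (ref, alt)
    if end is not None:
        assert v.end == end
    assert v.raw == desc and v.sample_id == "S1"


@pytest.mark.parametrize("bad", ["c.5G>", "524G>A", "c.G>A", "c.5_4insA", "p.R175H"])
def test_parse_variant_rejects_bad_grammar(bad):
    with pytest.raises(VariantParseError, match="(unrecognized|adjacent)"):
        parse_variant(bad)


@pytest.mark.parametrize(
    "ref, alt, category",
    [
        ("G", "A", "GC>AT"), ("C", "T", "GC>AT"),
        ("G", "T", "GC>TA"), ("C", "A", "GC>TA"),
        ("G", "C", "GC>CG"), ("C", "G", "GC>CG"),
        ("A", "C", "AT>CG"), ("T", "G", "AT>CG"),
        ("A", "G", "AT>GC"), ("T", "C", "AT>GC"),
        ("A", "T", "AT>TA"), ("T", "A", "AT>TA"),
    ],
)
def test_basepair_change_strand_normalization(ref, alt, category):
    assert basepair_change(ref, alt) == category


def test_basepair_change_complement_symmetry():
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for ref in "ACGT":
        for alt in "ACGT":
            if ref == alt:
                continue
            assert basepair_change(ref, alt) == basepair_change(comp[ref], comp[alt])


def test_basepair_change_identical_bases_error():
    with pytest.raises(ValueError):
        basepair_change("G", "G")


@pytest.mark.parametrize("pos, expected", [(5, True), (6, True), (4, False), (11, True)])
def test_cpg_context_on_toy_cds(toy12, pos, expected):
    # ATGCCGTTACGA: CG at 1-based (5,6) and (10,11)
    assert cpg_context(toy12, pos) is expected


def test_cpg_context_undefined_for_at_bases(toy12):
    with pytest.raises(ValueError, match="undefined"):
        cpg_context(toy12, 1)  # A


@pytest.mark.parametrize(
    "desc, effect",
    [
        ("c.4C>T", "missense"),   # codon 2 CCG->TCG, Pro->Ser
        ("c.8T>G", "nonsense"),   # codon 3 TTA->TGA
        ("c.9A>G", "silent"),     # codon 3 TTA->TTG, Leu->Leu
        ("c.1_2delAT", "frameshift"),
        ("c.4_6delCCG", "inframe_indel"),
        ("c.7_8insAA", "frameshift"),
        ("c.6+1G>T", "splice"),
    ],
)
def test_effect_class_examples(toy12, desc, effect):
    assert effect_class(toy12, parse_variant(desc)) == effect


def test_annotate_cpg_substitution(toy12):
    rec = annotate_mutation(toy12, parse_variant("c.5C>T"))
    assert rec.category == "GC>AT_CpG"
    assert rec.codon == 2 and rec.exon == 1
    assert rec.effect == "missense"


def test_annotate_checks_reference_base(toy12):
    with pytest.raises(ValueError, match="does not match"):
        annotate_mutation(toy12, parse_variant("c.5G>A"))


def test_annotate_hotspot_flag(tp53_model):
    # codon 175 (engineered CGA): c.524G>A is a CpG transition
    rec = annotate_mutation(tp53_model, parse_variant("c.524G>A"))
    assert rec.codon == 175 and rec.is_hotspot and rec.is_pah_site is False
    assert rec.category == "GC>AT_CpG" and rec.exon == 5


def test_annotate_splice_has_no_flags_or_codon(tp53_model):
    rec = annotate_mutation(tp53_model, parse_variant("c.375+1G>T"))
    assert rec.effect == "splice" and rec.category == "complex_other"
    assert rec.codon is None and not rec.is_hotspot and not rec.is_pah_site
    assert rec.exon == 4  # nearest exonic anchor


def test_indels_never_carry_substitution_category(tp53_model):
    for desc, cat in [("c.400_401delAG", "deletion"), ("c.400_401insA", "insertion"),
                      ("c.400_402delinsTT", "complex_other")]:
        assert annotate_mutation(tp53_model, parse_variant(desc)).category == cat


def test_annotator_matches_brute_force_classifier():
    """Exact category and effect agreement with an independent classifier
    over random toy coding sequences (10^4 random substitutions)."""
    rng = np.random.default_rng(20121227)
    n_checked = 0
    while n_checked < 10_000:
        length = 3 * int(rng.integers(20, 80))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        model = GeneModel(seq, ((1, 1, length),), frozenset(), frozenset())
        for _ in range(200):
            pos = int(rng.integers(1, length + 1))
            ref = seq[pos - 1]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            rec = annotate_mutation(
                model,
                CodingVariant(sample_id="", kind="substitution",
                              cds_position=pos, ref=ref, alt=alt),
            )
            assert rec.category == brute_force_category(seq, pos, alt)
            assert rec.effect == brute_force_effect(seq, pos, alt)
            n_checked += 1


def test_category_partition(annotated):
    """Every record has exactly one category; counts add up to the input."""
    from tp53spectrum.annotate import CATEGORIES

    assert len(annotated) == 120
    per_cat = {c: sum(r.category == c for r in annotated) for c in CATEGORIES}
    assert sum(per_cat.values()) == len(annotated)
    assert all(r.category in CATEGORIES for r in annotated)


def test_cpg_subset_of_gc_pairs(cohort, annotated):
    """CpG-classified records sit on C/G bases inside a CG dinucleotide,
    verified against a brute-force scan of the CDS."""
    seq = cohort.model.cds_sequence
    cg_starts = {i for i in range(len(seq) - 1) if seq[i:i + 2] == "CG"}
    for rec in annotated:
        if rec.category == "GC>AT_CpG":
            i = rec.variant.cds_position - 1
            ref = seq[i]
            assert ref in "CG"
            assert (ref == "C" and i in cg_starts) or (ref == "G" and i - 1 in cg_starts)
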