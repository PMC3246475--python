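"""Parse coding-variant descriptions and classify mutations.

Each somatic event is reduced to a strand-normalized base-pair category
(the grouping used by the IARC TP53 mutation database), with G:C>A:T
transitions split by CpG dinucleotide context, plus a predicted protein
effect, the affected codon and exon, and hotspot / PAH-adduct-site flags.

Strand normalization means a substitution and its reverse-complement
description fall in the same class: G>A and C>T are both "GC>AT".  CpG
context is evaluated on the coding strand; because a CpG on the coding
strand pairs with a CpG on the template strand, checking "C followed by
G, or G preceded by C" covers both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

from .io_core import GeneModel

# flat codon -> amino-acid map (stops as '*') for fast translation
_CODON_AA = dict(standard_dna_table.forward_table)
_CODON_AA.update({c: "*" for c in standard_dna_table.stop_codons})

# -- category labels ---------------------------------------------------------

SUBSTITUTION_CATEGORIES = ("AT>CG", "AT>GC", "AT>TA", "GC>AT", "GC>AT_CpG", "GC>CG", "GC>TA")
CATEGORIES = SUBSTITUTION_CATEGORIES + ("deletion", "insertion", "complex_other")
EFFECTS = ("missense", "nonsense", "silent", "frameshift", "inframe_indel", "splice")
#: Effects predicting absence of p53 protein.
PROTEIN_NULL_EFFECTS = frozenset({"nonsense", "frameshift", "splice"})

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class VariantParseError(ValueError):
    """Raised for variant descriptions outside the supported grammar."""


@dataclass(frozen=True)
class CodingVariant:
    """One parsed somatic event in coding-DNA (HGVS ``c.``) coordinates.

    ``cds_position`` is the 1-based anchor position (start for spans);
    ``offset`` is the intronic offset (0 for exonic positions, e.g. +1
    for the first intronic base after the anchor).  ``ref``/``alt`` are
    empty for pure insertions/deletions respectively.
    """

    sample_id: str
    kind: str  # substitution | deletion | insertion | delins | splice
    cds_position: int
    offset: int = 0
    end: int | None = None
    ref: str = ""
    alt: str = ""
    raw: str = ""


@dataclass(frozen=True)
class MutationRecord:
    """A :class:`CodingVariant` plus its derived classification."""

    variant: CodingVariant
    category: str
    effect: str
    codon: int | None
    exon: int | None
    is_hotspot: bool
    is_pah_site: bool

    @property
    def sample_id(self) -> str:
        return self.variant.sample_id


# -- parsing -----------------------------------------------------------------

_POS = r"(?P<pos>\d+)(?P<off>[+-]\d+)?"
_SUB_RE = re.compile(rf"^c\.{_POS}(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_DEL_RE = re.compile(r"^c\.(?P<start>\d+)(?:_(?P<end>\d+))?del(?P<bases>[ACGT]+)?$")
_INS_RE = re.compile(r"^c\.(?P<start>\d+)_(?P<end>\d+)ins(?P<bases>[ACGT]+)$")
_DELINS_RE = re.compile(r"^c\.(?P<start>\d+)(?:_(?P<end>\d+))?delins(?P<bases>[ACGT]+)$")


def parse_variant(description: str, sample_id: str = "") -> CodingVariant:
    """Parse an HGVS-c style description into a :class:`CodingVariant`.

    Supported grammar: ``c.<pos><ref>><alt>`` (with optional intronic
    offset, e.g. ``c.375+1G>T``), ``c.<start>_<end>del<bases>``,
    ``c.<pos>del<base>``, ``c.<start>_<end>ins<bases>`` and
    ``c.<start>_<end>delins<bases>``.  Any coordinate with an intronic
    offset yields ``kind='splice'``.
    """
    desc = description.strip()
    m = _SUB_RE.match(desc)
    if m:
        off = int(m.group("off") or 0)
        return CodingVariant(
            sample_id=sample_id,
            kind="splice" if off else "substitution",
            cds_position=int(m.group("pos")),
            offset=off,
            ref=m.group("ref"),
            alt=m.group("alt"),
            raw=desc,
        )
    m = _DELINS_RE.match(desc)
    if m:
        start = int(m.group("start"))
        end = int(m.group("end") or start)
        return CodingVariant(sample_id=sample_id, kind="delins", cds_position=start,
                             end=end, alt=m.group("bases"), raw=desc)
    m = _DEL_RE.match(desc)
    if m:
        start = int(m.group("start"))
        end = int(m.group("end") or start)
        return CodingVariant(sample_id=sample_id, kind="deletion", cds_position=start,
                             end=end, ref=m.group("bases") or "", raw=desc)
    m = _INS_RE.match(desc)
    if m:
        start = int(m.group("start"))
        end = int(m.group("end"))
        if end != start + 1:
            raise VariantParseError(f"insertion span must be adjacent: {desc!r}")
        return CodingVariant(sample_id=sample_id, kind="insertion", cds_position=start,
                             end=end, alt=m.group("bases"), raw=desc)
    raise VariantParseError(f"unrecognized variant description: {description!r}")


# -- classification primitives ----------------------------------------------

def basepair_change(ref: str, alt: str) -> str:
    """Strand-normalized base-pair category of a single-base substitution.

    A change and its reverse complement map to the same label, written
    with the purine first on the reference side (G>A and C>T -> "GC>AT").
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref in "CT":  # write the pyrimidine-reference change on the other strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}{_COMPLEMENT[ref]}>{alt}{_COMPLEMENT[alt]}"


def cpg_context(model: GeneModel, cds_position: int) -> bool:
    """Whether the G:C pair at an exonic position lies in a CpG dinucleotide.

    True iff the base participates in a 5'-CG-3' on the coding strand:
    a C whose next base is G, or a G whose previous base is C.  Ends of
    the (spliced) CDS use only the available neighbor.  Undefined (and
    an error) for A/T positions.
    """
    base = model.base(cds_position)
    if base not in "CG":
        raise ValueError(f"CpG context undefined for base {base} at c.{cds_position}")
    seq = model.cds_sequence
    if base == "C":
        return cds_position < len(seq) and seq[cds_position] == "G"
    return cds_position > 1 and seq[cds_position - 2] == "C"


def _indel_length(variant: CodingVariant) -> int:
    if variant.kind == "deletion":
        return (variant.end or variant.cds_position) - variant.cds_position + 1
    if variant.kind == "insertion":
        return len(variant.alt)
    if variant.kind == "delins":
        span = (variant.end or variant.cds_position) - variant.cds_position + 1
        return len(variant.alt) - span
    raise ValueError(f"not an indel: {variant.kind}")


def effect_class(model: GeneModel, variant: CodingVariant) -> str:
    """Predicted protein effect of a parsed variant.

    Substitutions translate the affected codon before/after; indels are
    frameshift unless the net length change is a multiple of 3; variants
    with an intronic offset are splice.
    """
    if variant.kind == "splice" or variant.offset != 0:
        return "splice"
    if variant.kind in {"deletion", "insertion", "delins"}:
        return "frameshift" if _indel_length(variant) % 3 != 0 else "inframe_indel"
    pos = variant.cds_position
    if not 1 <= pos <= len(model.cds_sequence):
        raise ValueError(f"position c.{pos} beyond CDS without intronic offset")
    codon_n = model.codon_number(pos)
    codon = model.codon_seq(codon_n)
    within = (pos - 1) % 3
    mutated = codon[:within] + variant.alt + codon[within + 1:]
    aa_before = _CODON_AA.get(codon, "X")
    aa_after = _CODON_AA.get(mutated, "X")
    if aa_before == aa_after:
        return "silent"
    if aa_after == "*":
        return "nonsense"
    return "missense"


def annotate_mutation(model: GeneModel, variant: CodingVariant) -> MutationRecord:
    """Full classification of one variant against a gene model.

    The category is the strand-normalized base-pair change with G:C>A:T
    split into CpG / non-CpG; indels map to deletion/insertion; splice
    and multi-base events map to ``complex_other``.  The reference base
    of an exonic substitution is checked against the model.
    """
    effect = effect_class(model, variant)
    codon: int | None = None
    exon: int | None = None
    if variant.kind == "substitution":
        pos = variant.cds_position
        if model.base(pos) != variant.ref:
            raise ValueError(
                f"{variant.raw or variant}: ref {variant.ref} does not match "
                f"model base {model.base(pos)} at c.{pos}"
            )
        category = basepair_change(variant.ref, variant.alt)
        if category == "GC>AT" and cpg_context(model, pos):
            category = "GC>AT_CpG"
        codon = model.codon_number(pos)
        exon = model.exon_of(pos)
    elif variant.kind == "deletion":
        category = "deletion"
        codon = model.codon_number(variant.cds_position)
        exon = model.exon_of(variant.cds_position)
    elif variant.kind == "insertion":
        category = "insertion"
        codon = model.codon_number(variant.cds_position)
        exon = model.exon_of(variant.cds_position)
    elif variant.kind == "delins":
        category = "complex_other"
        codon = model.codon_number(variant.cds_position)
        exon = model.exon_of(variant.cds_position)
    elif variant.kind == "splice":
        # anchored to the nearest exonic base; no CpG context in introns
        category = "complex_other"
        exon = model.exon_of(variant.cds_position)
    else:
        raise ValueError(f"unknown variant kind {variant.kind!r}")
    return MutationRecord(
        variant=variant,
        category=category,
        effect=effect,
        codon=codon,
        exon=exon,
        is_hotspot=codon in model.hotspot_codons if codon is not None else False,
        is_pah_site=codon in model.pah_codons if codon is not None else False,
    )


def annotate_table(model: GeneModel, rows) -> list[MutationRecord]:
    """Annotate raw mutation-table rows (``RawVariantRow``) in file order."""
    records = []
    for row in rows:
        if row.hgvs_c:
            variant = parse_variant(row.hgvs_c, sample_id=row.sample_id)
        else:
            variant = CodingVariant(
                sample_id=row.sample_id, kind=row.kind, cds_position=row.position,
                ref=row.ref or "", alt=row.alt or "",
                raw=f"{row.kind}@{row.position}",
            )
        records.append(annotate_mutation(model, variant))
    return records


def records_to_frame(records) -> "pd.DataFrame":
    """Annotated mutations as a DataFrame (the annotated-TSV schema)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "hgvs_c": [r.variant.raw for r in records],
            "category": [r.category for r in records],
            "effect": [r.effect for r in records],
            "codon": [r.codon for r in records],
            "exon": [r.exon for r in records],
            "is_hotspot": [r.is_hotspot for r in records],
            "is_pah_site": [r.is_pah_site for r in records],
        }
    )
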