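"""Readers/writers for the tabular and sequence inputs of the analysis.

The package consumes four kinds of input:

* a coding reference sequence (single-record FASTA) plus a gene model
  giving exon boundaries in 1-based coding (HGVS ``c.``) coordinates;
* a mutation table, one row per confirmed somatic mutation;
* a participant table with epidemiological covariates;
* an immunohistochemistry (IHC) rating table.

TSV is the canonical dialect; a comma fallback is auto-detected from the
header line.  Missing covariate values are kept as explicit ``None`` and
excluded per-analysis (complete-case) downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("tp53spectrum")

#: Recurrently mutated TP53 codons ("hotspots" across cancer types).
DEFAULT_HOTSPOT_CODONS = frozenset({175, 245, 273, 282})
#: Codons experimentally identified as sites of PAH-adduct formation,
#: recurrently mutated (G:C>T:A) in smokers' lung tumors.
DEFAULT_PAH_CODONS = frozenset({157, 158, 245, 248, 273})

SEX_LEVELS = ("female", "male")
ETHNICITY_LEVELS = ("non_turkmen", "turkmen")
RESIDENCE_LEVELS = ("rural", "urban")
TOBACCO_OPIUM_LEVELS = ("neither", "tobacco", "opium", "both")
TEA_LEVELS = ("0-1", "2-3", "4plus")
STAGE_LEVELS = ("I", "II", "III", "IV")


class GeneModelError(ValueError):
    """Raised when a gene model violates its invariants."""


@dataclass(frozen=True)
class GeneModel:
    """A coding sequence plus exon structure in coding coordinates.

    ``exon_bounds`` is an ordered list of ``(exon_number, cds_start,
    cds_end)`` tuples, 1-based inclusive on the coding strand.  Intervals
    must be non-overlapping and ordered; every CDS position belongs to at
    most one exon.
    """

    cds_sequence: str
    exon_bounds: tuple[tuple[int, int, int], ...]
    hotspot_codons: frozenset[int] = DEFAULT_HOTSPOT_CODONS
    pah_codons: frozenset[int] = DEFAULT_PAH_CODONS

    def __post_init__(self) -> None:
        seq = self.cds_sequence.upper()
        object.__setattr__(self, "cds_sequence", seq)
        if not seq or set(seq) - set("ACGT"):
            raise GeneModelError("CDS must be a non-empty A/C/G/T string")
        if len(seq) % 3 != 0:
            warnings.warn("CDS length is not a multiple of 3", stacklevel=2)
        bounds = tuple(tuple(b) for b in self.exon_bounds)
        object.__setattr__(self, "exon_bounds", bounds)
        prev_end = 0
        for exon, start, end in bounds:
            if start > end or start < 1:
                raise GeneModelError(f"exon {exon}: bad interval ({start},{end})")
            if start <= prev_end:
                raise GeneModelError(f"exon {exon} overlaps or is out of order")
            prev_end = end
        n_codons = self.n_codons
        for name, codons in (("hotspot", self.hotspot_codons), ("pah", self.pah_codons)):
            bad = {c for c in codons if not 1 <= c <= n_codons}
            if bad:
                raise GeneModelError(f"{name} codons outside CDS: {sorted(bad)}")
        object.__setattr__(self, "hotspot_codons", frozenset(self.hotspot_codons))
        object.__setattr__(self, "pah_codons", frozenset(self.pah_codons))

    @property
    def n_codons(self) -> int:
        return math.ceil(len(self.cds_sequence) / 3)

    def base(self, pos: int) -> str:
        """Reference base at 1-based coding position ``pos``."""
        if not 1 <= pos <= len(self.cds_sequence):
            raise IndexError(f"position {pos} outside CDS (1..{len(self.cds_sequence)})")
        return self.cds_sequence[pos - 1]

    def codon_number(self, pos: int) -> int:
        return math.ceil(pos / 3)

    def codon_seq(self, codon: int) -> str:
        start = 3 * (codon - 1)
        return self.cds_sequence[start:start + 3]

    def exon_of(self, pos: int) -> int | None:
        """Exon number containing coding position ``pos`` (None if in no exon)."""
        for exon, start, end in self.exon_bounds:
            if start <= pos <= end:
                return exon
        return None


@dataclass(frozen=True)
class Participant:
    """One study participant with epidemiological covariates.

    Any covariate may be missing (``None``); analyses are complete-case.
    ``tea_interval`` is the minutes between tea being poured and drunk,
    coded 0-1 / 2-3 / 4plus (a validated surrogate for tea temperature).
    """

    sample_id: str
    age_years: float | None = None
    sex: str | None = None
    ethnicity: str | None = None
    residence: str | None = None
    tobacco_opium: str | None = None
    tea_interval: str | None = None
    tumor_size_cm: float | None = None
    stage: str | None = None

    def __post_init__(self) -> None:
        for attr, levels in (
            ("sex", SEX_LEVELS),
            ("ethnicity", ETHNICITY_LEVELS),
            ("residence", RESIDENCE_LEVELS),
            ("tobacco_opium", TOBACCO_OPIUM_LEVELS),
            ("tea_interval", TEA_LEVELS),
            ("stage", STAGE_LEVELS),
        ):
            val = getattr(self, attr)
            if val is not None and val not in levels:
                raise ValueError(f"{attr}={val!r} not in {levels}")


@dataclass(frozen=True)
class IHCRatingRow:
    """One immunostaining rating: percent-stained category and intensity.

    ``pct_category``: 0 (no staining) to 4 (76-100% of tumor cells).
    ``intensity``: 0 (negative) to 3 (strong).
    """

    sample_id: str
    antibody: str
    pct_category: int
    intensity: int

    def __post_init__(self) -> None:
        if not 0 <= self.pct_category <= 4:
            raise ValueError(f"pct_category {self.pct_category} outside 0..4")
        if not 0 <= self.intensity <= 3:
            raise ValueError(f"intensity {self.intensity} outside 0..3")


@dataclass(frozen=True)
class RawVariantRow:
    """One row of a mutation table before parsing/annotation."""

    sample_id: str
    hgvs_c: str | None = None
    position: int | None = None
    ref: str | None = None
    alt: str | None = None
    kind: str | None = None
    line_no: int | None = None


@dataclass
class TableReadResult:
    """Parsed rows plus rejected rows with line numbers and reasons.

    Row counts are conserved: ``rows_in == len(rows) + len(rejected)``.
    """

    rows: list
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def rows_in(self) -> int:
        return len(self.rows) + len(self.rejected)


def _detect_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header or "," not in header else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    return df.replace("", None)


def _opt_float(v: Any) -> float | None:
    if v is None or v == "":
        return None
    return float(v)


def read_mutation_table(path: str | Path) -> TableReadResult:
    """Read a mutation TSV: one row per confirmed somatic mutation.

    Requires a ``sample_id`` column and either ``hgvs_c`` or the quartet
    ``position``/``ref``/``alt``/``kind``.  Rows missing those fields are
    collected in ``rejected`` with their 1-based data line numbers, never
    silently dropped.
    """
    df = _read_table(path)
    if len(df) == 0:
        warnings.warn(f"{path}: empty mutation table", stacklevel=2)
    cols = set(df.columns)
    if "sample_id" not in cols:
        raise ValueError("mutation table is missing required column 'sample_id'")
    pos_style = {"position", "ref", "alt", "kind"} <= cols
    if "hgvs_c" not in cols and not pos_style:
        raise ValueError(
            "mutation table needs column 'hgvs_c' or columns position/ref/alt/kind"
        )
    result = TableReadResult(rows=[])
    for i, row in enumerate(df.to_dict("records"), start=1):
        sid = row.get("sample_id")
        hgvs = row.get("hgvs_c")
        if not sid:
            result.rejected.append((i, "missing sample_id"))
            continue
        if not hgvs and not (pos_style and row.get("position")):
            result.rejected.append((i, "no variant description"))
            continue
        result.rows.append(
            RawVariantRow(
                sample_id=sid,
                hgvs_c=hgvs,
                position=int(row["position"]) if row.get("position") else None,
                ref=row.get("ref"),
                alt=row.get("alt"),
                kind=row.get("kind"),
                line_no=i,
            )
        )
    return result


def read_participant_table(path: str | Path) -> list[Participant]:
    """Read the participant/covariate TSV (missing cells become ``None``)."""
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise ValueError("participant table is missing required column 'sample_id'")
    out = []
    for row in df.to_dict("records"):
        out.append(
            Participant(
                sample_id=row["sample_id"],
                age_years=_opt_float(row.get("age_years")),
                sex=row.get("sex"),
                ethnicity=row.get("ethnicity"),
                residence=row.get("residence"),
                tobacco_opium=row.get("tobacco_opium"),
                tea_interval=row.get("tea_interval"),
                tumor_size_cm=_opt_float(row.get("tumor_size_cm")),
                stage=row.get("stage"),
            )
        )
    ids = [p.sample_id for p in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in participant table")
    return out


def read_ihc_table(path: str | Path) -> list[IHCRatingRow]:
    """Read the IHC rating TSV (sample_id, antibody, pct_category, intensity)."""
    df = _read_table(path)
    required = {"sample_id", "antibody", "pct_category", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"IHC table missing columns: {sorted(missing)}")
    return [
        IHCRatingRow(
            sample_id=row["sample_id"],
            antibody=row["antibody"],
            pct_category=int(row["pct_category"]),
            intensity=int(row["intensity"]),
        )
        for row in df.to_dict("records")
    ]


def read_gene_model(
    fasta_path: str | Path,
    model_path: str | Path,
    hotspot_codons: Iterable[int] | None = None,
    pah_codons: Iterable[int] | None = None,
) -> GeneModel:
    """Load a :class:`GeneModel` from a single-record FASTA plus a model file.

    ``model_path`` is either a TSV with columns ``exon``/``cds_start``/
    ``cds_end``, or a YAML/JSON mapping with keys ``exons`` (list of
    [exon, start, end]) and optional ``hotspot_codons`` / ``pah_codons``.
    When no hotspot/PAH lists are given the TP53 defaults apply.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected exactly 1 FASTA record, got {len(records)}")
    cds = str(records[0].seq).upper()

    model_path = Path(model_path)
    hot = set(hotspot_codons) if hotspot_codons is not None else None
    pah = set(pah_codons) if pah_codons is not None else None
    if model_path.suffix.lower() in {".yaml", ".yml", ".json"}:
        cfg = yaml.safe_load(model_path.read_text())
        exons = [tuple(int(x) for x in row) for row in cfg["exons"]]
        if hot is None and cfg.get("hotspot_codons") is not None:
            hot = {int(c) for c in cfg["hotspot_codons"]}
        if pah is None and cfg.get("pah_codons") is not None:
            pah = {int(c) for c in cfg["pah_codons"]}
    else:
        df = _read_table(model_path)
        exons = [
            (int(r["exon"]), int(r["cds_start"]), int(r["cds_end"]))
            for r in df.to_dict("records")
        ]
    # default hotspot/PAH sets are clipped to short (toy) coding sequences;
    # user-supplied sets are validated strictly by GeneModel
    n_codons = math.ceil(len(cds) / 3)
    if hot is None:
        hot = {c for c in DEFAULT_HOTSPOT_CODONS if c <= n_codons}
    if pah is None:
        pah = {c for c in DEFAULT_PAH_CODONS if c <= n_codons}
    return GeneModel(
        cds_sequence=cds,
        exon_bounds=tuple(exons),
        hotspot_codons=frozenset(hot),
        pah_codons=frozenset(pah),
    )


def write_gene_model(model: GeneModel, fasta_path: str | Path, model_path: str | Path) -> None:
    """Write a gene model back to FASTA + YAML (round-trips read_gene_model)."""
    with open(fasta_path, "w") as fh:
        fh.write(">cds synthetic coding sequence\n")
        for i in range(0, len(model.cds_sequence), 60):
            fh.write(model.cds_sequence[i:i + 60] + "\n")
    cfg = {
        "exons": [list(b) for b in model.exon_bounds],
        "hotspot_codons": sorted(model.hotspot_codons),
        "pah_codons": sorted(model.pah_codons),
    }
    Path(model_path).write_text(yaml.safe_dump(cfg))


def write_participant_table(participants: Sequence[Participant], path: str | Path) -> None:
    df = pd.DataFrame([asdict(p) for p in participants])
    df.to_csv(path, sep="\t", index=False)


def write_ihc_table(rows: Sequence[IHCRatingRow], path: str | Path) -> None:
    df = pd.DataFrame([asdict(r) for r in rows])
    df.to_csv(path, sep="\t", index=False)


def _json_default(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def config_hash(obj: Any) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=_json_default)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_report(results: dict, path: str | Path, fmt: str = "json",
                 seed: int | None = None, config: Any = None) -> None:
    """Serialize a run-level report.

    JSON output embeds tool version, a configuration hash and the seed;
    undefined odds ratios serialize as ``null`` with their reason kept
    alongside.  ``fmt='tsv'`` flattens scalar leaves into a two-column
    key/value table for human consumption.
    """
    from . import __version__

    path = Path(path)
    meta = {
        "tool": "tp53spectrum",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump({"meta": meta, "results": results}, fh, indent=2,
                      default=_json_default, sort_keys=True)
            fh.write("\n")
    elif fmt == "tsv":
        flat: list[tuple[str, Any]] = []

        def _walk(prefix: str, obj: Any) -> None:
            if is_dataclass(obj) and not isinstance(obj, type):
                obj = asdict(obj)
            if isinstance(obj, dict):
                for k, v in obj.items():
                    _walk(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    _walk(f"{prefix}[{i}]", v)
            else:
                flat.append((prefix, obj))

        _walk("", results)
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            for k, v in flat:
                fh.write(f"{k}\t{v}\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
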