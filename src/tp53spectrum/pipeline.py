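"""End-to-end orchestration: annotate -> spectrum -> association -> IHC.

``run_analysis`` is the in-memory pipeline over already-loaded inputs;
``full_run`` wraps it with file IO, logging and a manifest, and the CLI
wraps ``full_run``.  Reports are deterministic given inputs and seed
(modulo the manifest timestamp).
"""

from __future__ import annotations

import datetime
import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .annotate import annotate_table, records_to_frame
from .assoc import association_table, build_record_units
from .ihc import (expression_association, percent_agreement,
                  sample_functional_class, score_ratings, weighted_kappa)
from .io_core import (GeneModel, config_hash, read_gene_model, read_ihc_table,
                      read_mutation_table, read_participant_table, write_report)
from .spectrum import SpectrumTable, count_spectrum, global_compare, posthoc_all

logger = logging.getLogger("tp53spectrum")


@dataclass
class RunManifest:
    """Provenance for one pipeline run."""

    version: str
    seed: int | None
    config_hash: str | None
    timestamp: str
    input_hashes: dict[str, str] = field(default_factory=dict)
    output_hashes: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)


def _file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_analysis(
    model: GeneModel,
    participants,
    mutation_rows,
    ihc_rows=None,
    comparison: SpectrumTable | None = None,
    exon_filter: tuple[int, int] = (5, 8),
    adjusted: bool = True,
) -> dict:
    """Run every analysis stage over in-memory inputs and collect results."""
    records = annotate_table(model, mutation_rows)
    mutated_samples = {r.sample_id for r in records}
    n = len(participants)
    results: dict = {
        "summary": {
            "n_participants": n,
            "n_mutations": len(records),
            "n_mutated": len(mutated_samples),
            "mutation_prevalence_pct": 100.0 * len(mutated_samples) / n if n else 0.0,
            "n_hotspot": sum(r.is_hotspot for r in records),
            "n_gcta": sum(r.category == "GC>TA" for r in records),
            "n_gcta_at_pah": sum(r.is_pah_site for r in records
                                 if r.category == "GC>TA"),
        }
    }
    full = count_spectrum(records, exon_filter=None, cohort_label="cohort")
    restricted = count_spectrum(records, exon_filter=exon_filter,
                                cohort_label="cohort")
    results["spectrum"] = {
        "all_exons": dict(full.counts),
        "exon_filtered": dict(restricted.counts),
        "exon_filter": list(exon_filter),
    }
    if comparison is not None:
        a6 = restricted.to_six_group()
        b6 = comparison.to_six_group()
        results["comparison"] = {
            "cohorts": [a6.cohort_label, b6.cohort_label],
            "global": asdict(global_compare(a6, b6)),
            "posthoc": {cat: asdict(r) for cat, r in posthoc_all(a6, b6).items()},
        }
    if participants:
        if not records:
            results["association"] = {"skipped": "no mutations"}
        else:
            results["association"] = association_table(
                participants, records, adjusted=adjusted
            )
    if ihc_rows:
        calls = score_ratings(ihc_rows)
        by_ab: dict[str, list] = {}
        for c in calls:
            by_ab.setdefault(c.antibody, []).append(c)
        ihc_res: dict = {"n_evaluable": len({c.sample_id for c in calls})}
        if len(by_ab) == 2:
            ab1, ab2 = sorted(by_ab)
            ihc_res["antibodies"] = [ab1, ab2]
            ihc_res["percent_agreement"] = percent_agreement(by_ab[ab1], by_ab[ab2])
            ihc_res["weighted_kappa_linear"] = weighted_kappa(by_ab[ab1], by_ab[ab2])
        primary = by_ab.get("DO7") or next(iter(by_ab.values()))
        classes = sample_functional_class(
            [p.sample_id for p in participants], records
        )
        contrast = expression_association(classes, primary, "missense", "protein_null")
        ihc_res["missense_vs_protein_null"] = asdict(contrast) if contrast else None
        rest = expression_association(classes, primary, "missense", None)
        ihc_res["missense_vs_rest"] = asdict(rest) if rest else None
        results["ihc"] = ihc_res
    return results


def full_run(
    out_dir: str | Path,
    mutations_path: str | Path | None = None,
    participants_path: str | Path | None = None,
    ihc_path: str | Path | None = None,
    fasta_path: str | Path | None = None,
    gene_model_path: str | Path | None = None,
    comparison: SpectrumTable | None = None,
    use_fixture: bool = False,
    seed: int | None = None,
    adjusted: bool = True,
) -> dict:
    """File-level pipeline run; writes report.json, annotated.tsv, manifest.json.

    With ``use_fixture=True`` the bundled deterministic study-scale
    cohort (and the bundled comparison spectrum) is analysed instead of
    reading input files.  Stage errors propagate with the stage named.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__, seed=seed, config_hash=None,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    try:
        if use_fixture:
            from .paper_cohort import paper_cohort, tehran_spectrum

            cohort = paper_cohort()
            model = cohort.model
            participants = cohort.participants
            mutation_rows = cohort.mutation_rows
            ihc_rows = cohort.ihc_rows
            if comparison is None:
                comparison = tehran_spectrum()
        else:
            model = read_gene_model(fasta_path, gene_model_path)
            mut_result = read_mutation_table(mutations_path)
            if mut_result.rejected:
                logger.warning("rejected %d mutation rows: %s",
                               len(mut_result.rejected), mut_result.rejected)
            mutation_rows = mut_result.rows
            participants = (read_participant_table(participants_path)
                            if participants_path else [])
            ihc_rows = read_ihc_table(ihc_path) if ihc_path else None
            for name, p in [("mutations", mutations_path),
                            ("participants", participants_path),
                            ("ihc", ihc_path), ("fasta", fasta_path),
                            ("gene_model", gene_model_path)]:
                if p:
                    manifest.input_hashes[name] = _file_hash(p)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise RuntimeError(f"io_core stage failed: {exc}") from exc

    results = run_analysis(model, participants, mutation_rows, ihc_rows,
                           comparison=comparison, adjusted=adjusted)
    manifest.stage_counts = {
        "participants": len(participants),
        "mutations": len(mutation_rows),
        "ihc_ratings": len(ihc_rows) if ihc_rows else 0,
    }

    report_path = out_dir / "report.json"
    write_report(results, report_path, fmt="json", seed=seed)
    annotated_path = out_dir / "annotated.tsv"
    records_to_frame(annotate_table(model, mutation_rows)).to_csv(
        annotated_path, sep="\t", index=False
    )
    for p in (report_path, annotated_path):
        manifest.output_hashes[p.name] = _file_hash(p)
    write_report(asdict(manifest), out_dir / "manifest.json", fmt="json", seed=seed)
    logger.info("full run complete: %s", out_dir)
    return results
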