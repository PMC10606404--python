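"""Four-phase orchestration: prepare, locate, recall, replace.

:func:`fill_assembly` is the in-memory core used by the tests and the
acceptance script; :func:`run_pipeline` wraps it with file I/O, adapter
construction from a :class:`~contigrecall.config.PipelineConfig`, and
per-phase logging.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from .io_formats import (
    AlignmentRecord,
    GeneStatusTable,
    SequenceRecord,
    write_busco_full_table,
    write_fasta,
    write_paf,
)
from .locate import MissingRegion, build_missing_regions, write_region_report
from .markers import MarkerCatalog, fillable_genes, missing_genes, toy_marker_scan
from .recall import (
    DEFAULT_FLANK_BP,
    DEFAULT_MIN_OLAP,
    assemble_candidates,
    recall_reads,
    select_candidate,
)
from .replace import (
    EditLedger,
    RegressionReport,
    ReplacementEvent,
    apply_replacements,
    plan_replacement,
    verify_no_regression,
)
from .synthetic import toy_align

logger = logging.getLogger(__name__)

Assessor = Callable[[Sequence[SequenceRecord]], GeneStatusTable]
Aligner = Callable[[Sequence[SequenceRecord], Sequence[SequenceRecord]], list[AlignmentRecord]]
Assembler = Callable[[Sequence[SequenceRecord]], list[SequenceRecord]]


class PhaseError(RuntimeError):
    """A pipeline phase failed; carries the phase name."""

    def __init__(self, phase: str, cause: Exception):
        super().__init__(f"phase '{phase}' failed: {cause}")
        self.phase = phase
        self.cause = cause


@dataclass
class PipelineResult:
    """Everything one run produces, before any files are written."""

    assembly: list[SequenceRecord]
    ledger: EditLedger
    summary: dict
    before_table: GeneStatusTable
    after_table: GeneStatusTable
    regions: list[MissingRegion]
    regression: RegressionReport
    alignments: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.regression.ok


def _order_genes(regions: Sequence[MissingRegion]) -> list[tuple[str, MissingRegion]]:
    """Processing order: ascending (chromosome, anchor start), unanchored last."""
    anchored, unanchored = [], []
    for region in regions:
        for gene in sorted(region.gene_ids):
            if region.anchor is None:
                unanchored.append((gene, region))
            else:
                anchored.append((gene, region))
    anchored.sort(key=lambda gr: (gr[1].anchor.chrom_id, gr[1].anchor.start, gr[0]))
    unanchored.sort(key=lambda gr: gr[0])
    return anchored + unanchored


def fill_assembly(
    chrom_assembly: Sequence[SequenceRecord],
    merged_contigs: Sequence[SequenceRecord],
    reads: Sequence[SequenceRecord],
    catalog: MarkerCatalog,
    assessor: Assessor | None = None,
    aligner: Aligner | None = None,
    assembler: Assembler | None = None,
    flank_bp: int = DEFAULT_FLANK_BP,
    min_anchor_matches: int = 500,
    min_query_coverage: float = 0.8,
    min_overlap_bp: int = 1,
    min_olap: int = DEFAULT_MIN_OLAP,
    include_fragmented: bool = False,
) -> PipelineResult:
    """Run all four phases in memory and return the edited assembly.

    Adapters default to the built-in toys (exact marker scan, k-mer chain
    aligner, greedy overlap assembler).  The final assembly in the result
    is always the edited one; callers decide, via ``result.ok``, whether
    a regression makes it unfit to write out.
    """
    assessor = assessor or (lambda recs: toy_marker_scan(recs, catalog))
    aligner = aligner or toy_align
    assembler_fn = assembler

    # ---- Phase 1: assess both inputs, set difference -----------------------
    t0 = time.perf_counter()
    chrom_table = assessor(chrom_assembly)
    contig_table = assessor(merged_contigs)
    fillable = fillable_genes(chrom_table, contig_table, include_fragmented)
    missing_before = missing_genes(chrom_table)
    unfillable = {
        g: (
            "not_in_contig_table"
            if g not in contig_table.by_gene
            else f"contig_status_{contig_table.status_of(g).lower()}"
        )
        for g in sorted(missing_before - set(fillable))
    }
    logger.info(
        "phase 1: %d missing on chromosomes, %d fillable (%.1fs)",
        len(missing_before), len(fillable), time.perf_counter() - t0,
    )

    if len(fillable) == 0:
        ledger = EditLedger()
        report = verify_no_regression(chrom_table, chrom_table)
        return PipelineResult(
            assembly=list(chrom_assembly),
            ledger=ledger,
            summary=_summarize([], [], fillable, unfillable, chrom_table, chrom_table, ledger, report),
            before_table=chrom_table,
            after_table=chrom_table,
            regions=[],
            regression=report,
        )

    # ---- Phase 1 alignments + Phase 2: locate ------------------------------
    t0 = time.perf_counter()
    contigs_to_chrom = aligner(merged_contigs, chrom_assembly)
    # one pass for the reads against chromosomes and contigs together
    combined = list(chrom_assembly) + list(merged_contigs)
    chrom_ids = {r.id for r in chrom_assembly}
    reads_to_all = aligner(reads, combined)
    reads_to_chrom = [a for a in reads_to_all if a.target_id in chrom_ids]
    reads_to_contigs = [a for a in reads_to_all if a.target_id not in chrom_ids]
    regions = build_missing_regions(
        fillable, contig_table, merged_contigs, contigs_to_chrom, min_anchor_matches
    )
    logger.info(
        "phase 2: %d regions (%d anchored) from %d fillable genes (%.1fs)",
        len(regions), sum(r.anchor is not None for r in regions), len(fillable),
        time.perf_counter() - t0,
    )

    # ---- Phase 3: recall, assemble, select ---------------------------------
    t0 = time.perf_counter()
    ordered = _order_genes(regions)
    candidate_pool: dict[str, list[SequenceRecord]] = {}
    recall_sizes: dict[str, int] = {}
    for region in regions:
        recall_set = recall_reads(
            region, reads_to_contigs, reads_to_chrom, reads,
            flank_bp=flank_bp, min_overlap_bp=min_overlap_bp,
        )
        recall_sizes[region.contig_id] = len(recall_set)
        if len(recall_set) == 0:
            candidate_pool[region.contig_id] = []
            continue
        candidate_pool[region.contig_id] = assemble_candidates(
            recall_set, assembler=assembler_fn, min_olap=min_olap
        )

    selections: list[tuple[str, MissingRegion, object]] = []
    gene_stage: dict[str, str] = {}
    cand_records: list[SequenceRecord] = []
    for gene, region in ordered:
        chosen = select_candidate(candidate_pool[region.contig_id], gene, catalog)
        if chosen is None:
            gene_stage[gene] = "recall_failed_no_candidate"
            selections.append((gene, region, None))
            continue
        renamed = SequenceRecord(f"cand_{gene}", chosen.record.bases)
        chosen = type(chosen)(renamed, chosen.gene_status, chosen.gene_interval)
        cand_records.append(renamed)
        selections.append((gene, region, chosen))
    logger.info(
        "phase 3: %d/%d genes got a candidate (%.1fs)",
        sum(1 for _, _, c in selections if c is not None), len(selections),
        time.perf_counter() - t0,
    )

    # ---- Phase 4: align candidates, plan, splice, verify -------------------
    t0 = time.perf_counter()
    cand_to_chrom = aligner(cand_records, chrom_assembly) if cand_records else []
    events: list[ReplacementEvent] = []
    for gene, region, chosen in selections:
        if chosen is None:
            continue
        event = plan_replacement(
            chosen, gene, region.anchor, cand_to_chrom, min_query_coverage
        )
        gene_stage[gene] = event.status
        events.append(event)

    edited, ledger = apply_replacements(chrom_assembly, events)
    for event in ledger.events:  # pick up overlap demotions
        gene_stage[event.gene_id] = event.status
    after_table = assessor(edited)
    report = verify_no_regression(chrom_table, after_table)
    logger.info(
        "phase 4: %d applied, missing %d -> %d, regression_ok=%s (%.1fs)",
        len(ledger.applied()), report.missing_before, report.missing_after,
        report.ok, time.perf_counter() - t0,
    )

    summary = _summarize(
        [(g, r) for g, r in ordered], recall_sizes, fillable, unfillable,
        chrom_table, after_table, ledger, report, gene_stage, regions,
    )
    return PipelineResult(
        assembly=edited,
        ledger=ledger,
        summary=summary,
        before_table=chrom_table,
        after_table=after_table,
        regions=regions,
        regression=report,
        alignments={
            "contigs_to_chrom": contigs_to_chrom,
            "reads_to_chrom": reads_to_chrom,
            "reads_to_contigs": reads_to_contigs,
            "candidates_to_chrom": cand_to_chrom,
        },
    )


def _summarize(
    ordered,
    recall_sizes,
    fillable,
    unfillable,
    before_table: GeneStatusTable,
    after_table: GeneStatusTable,
    ledger: EditLedger,
    report: RegressionReport,
    gene_stage: dict | None = None,
    regions: Sequence[MissingRegion] = (),
) -> dict:
    gene_stage = gene_stage or {}
    gene_outcomes = {}
    for gene in fillable:
        recovered = (
            gene in after_table.by_gene and after_table.status_of(gene) == "Complete"
        )
        gene_outcomes[gene] = {
            "recovered": recovered,
            "stage": gene_stage.get(gene, "recovered" if recovered else "unprocessed"),
        }
    return {
        "fillable_genes": list(fillable),
        "n_fillable": len(fillable),
        "unfillable_missing": unfillable,
        "missing_before": report.missing_before,
        "missing_after": report.missing_after,
        "n_recovered": sum(1 for o in gene_outcomes.values() if o["recovered"]),
        "regions": {
            "total": len(regions),
            "anchored": sum(r.anchor is not None for r in regions),
            "recall_set_sizes": dict(recall_sizes) if recall_sizes else {},
        },
        "gene_outcomes": gene_outcomes,
        "replacements": ledger.counts_by_status(),
        "regression_ok": report.ok,
        "worsened": [list(w) for w in report.worsened],
    }


def run_pipeline(config) -> PipelineResult:
    """File-level orchestration driven by a :class:`PipelineConfig`.

    Reads all inputs, builds the configured adapters, runs
    :func:`fill_assembly`, and writes the report files into the output
    directory.  The filled assembly itself is only written when the
    no-regression check passes or ``config.force`` is set.  Any phase
    error aborts with the phase name; partial artifacts stay on disk for
    inspection.
    """
    from .adapters import make_adapters
    from .config import PipelineConfig
    from .io_formats import read_fasta, read_fastq

    assert isinstance(config, PipelineConfig)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        chrom_assembly = read_fasta(config.chrom_assembly)
        from .config import merge_contig_sets

        contig_sets = [read_fasta(p) for p in config.contig_sets]
        merged = merge_contig_sets(contig_sets)
        reads_path = str(config.reads)
        if reads_path.endswith((".fq", ".fastq")):
            reads = read_fastq(reads_path)
        else:
            reads = read_fasta(reads_path)
        catalog = MarkerCatalog.from_fasta(config.catalog)
    except Exception as exc:
        raise PhaseError("load_inputs", exc) from exc

    assessor, aligner, assembler = make_adapters(config, catalog, out_dir)

    try:
        result = fill_assembly(
            chrom_assembly,
            merged,
            reads,
            catalog,
            assessor=assessor,
            aligner=aligner,
            assembler=assembler,
            flank_bp=config.flank_bp,
            min_anchor_matches=config.min_anchor_matches,
            min_query_coverage=config.min_query_coverage,
            min_overlap_bp=config.min_overlap_bp,
            min_olap=config.assembler_min_olap,
            include_fragmented=config.include_fragmented,
        )
    except PhaseError:
        raise
    except Exception as exc:
        raise PhaseError("fill_assembly", exc) from exc

    write_region_report(result.regions, out_dir)
    write_busco_full_table(result.before_table, out_dir / "full_table_before.tsv")
    write_busco_full_table(result.after_table, out_dir / "full_table_after.tsv")
    for name, alns in result.alignments.items():
        write_paf(alns, out_dir / f"{name}.paf")
    _write_ledger(result.ledger, out_dir)
    (out_dir / "summary.json").write_text(json.dumps(result.summary, indent=2))
    if result.ok or config.force:
        write_fasta(result.assembly, out_dir / "filled_assembly.fasta")
    else:
        logger.error("regression check failed; filled assembly not written (use force)")
    return result


def _write_ledger(ledger: EditLedger, out_dir: Path) -> None:
    rows = ["gene_id\tchrom_id\told_start\told_end\tnew_len\tcandidate_id\tstatus"]
    payload = []
    for e in ledger.events:
        start, end = e.old_interval if e.old_interval else ("", "")
        rows.append(
            f"{e.gene_id}\t{e.chrom_id}\t{start}\t{end}\t{len(e.new_bases)}\t"
            f"{e.candidate_id}\t{e.status}"
        )
        payload.append(
            {
                "gene_id": e.gene_id,
                "chrom_id": e.chrom_id,
                "old_interval": list(e.old_interval) if e.old_interval else None,
                "new_len": len(e.new_bases),
                "candidate_id": e.candidate_id,
                "status": e.status,
            }
        )
    (out_dir / "ledger.tsv").write_text("\n".join(rows) + "\n")
    (out_dir / "ledger.json").write_text(
        json.dumps({"events": payload, "offsets": ledger.offsets}, indent=2)
    )
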