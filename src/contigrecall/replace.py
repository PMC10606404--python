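"""Phase 4 — splice selected candidates into the chromosomes.

A candidate is aligned back to the chromosome-level assembly; the splice
is only planned when the alignment covers enough of the candidate and
the target gene lies fully inside the aligned query span (a gene outside
the aligned region is a named failure mode and leaves the gap unfilled).
Applied splices are tracked in an :class:`EditLedger` so every untouched
locus of the input can be mapped to its post-edit coordinate, and a final
assessor run guards against any completeness regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import (
    AlignmentRecord,
    GeneStatusTable,
    SequenceRecord,
    reverse_complement,
)
from .locate import ChromosomeAnchor, alignment_rank
from .recall import CandidateSequence

logger = logging.getLogger(__name__)

DEFAULT_MIN_QUERY_COVERAGE = 0.8

APPLIED = "applied"
SKIPPED_NO_ALIGNMENT = "skipped_no_alignment"
SKIPPED_GENE_OUTSIDE = "skipped_gene_outside_alignment"
SKIPPED_LOW_COVERAGE = "skipped_low_coverage"
SKIPPED_OVERLAP = "skipped_overlap"
EVENT_STATUSES = (
    APPLIED,
    SKIPPED_NO_ALIGNMENT,
    SKIPPED_GENE_OUTSIDE,
    SKIPPED_LOW_COVERAGE,
    SKIPPED_OVERLAP,
)

_STATUS_RANK = {"Complete": 3, "Duplicated": 2, "Fragmented": 1, "Missing": 0}


@dataclass
class ReplacementEvent:
    """A planned or applied splice of new sequence into one chromosome."""

    gene_id: str
    chrom_id: str
    old_interval: tuple[int, int] | None
    new_bases: str
    candidate_id: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in EVENT_STATUSES:
            raise ValueError(f"unknown event status {self.status!r}")
        if self.status == APPLIED:
            if not self.new_bases:
                raise ValueError("applied event with empty new_bases")
            if self.old_interval is None or not self.old_interval[0] < self.old_interval[1]:
                raise ValueError("applied event needs a valid old_interval")


@dataclass
class EditLedger:
    """Applied splices per chromosome plus the coordinate offset map.

    ``offsets[chrom]`` is a list of ``(old_start, old_end, delta)``
    breakpoints in ascending order; the cumulative delta of all splices
    strictly left of an untouched locus maps it to its post-edit
    position.
    """

    events: list[ReplacementEvent] = field(default_factory=list)
    offsets: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    def map_position(self, chrom_id: str, pos: int) -> int | None:
        """Post-edit coordinate of a pre-edit locus; None inside a splice."""
        delta = 0
        for old_start, old_end, d in self.offsets.get(chrom_id, []):
            if pos >= old_end:
                delta += d
            elif pos >= old_start:
                return None
        return pos + delta

    def applied(self) -> list[ReplacementEvent]:
        return [e for e in self.events if e.status == APPLIED]

    def counts_by_status(self) -> dict[str, int]:
        counts = {s: 0 for s in EVENT_STATUSES}
        for e in self.events:
            counts[e.status] += 1
        return counts


def plan_replacement(
    candidate: CandidateSequence,
    gene_id: str,
    anchor: ChromosomeAnchor | None,
    cand_to_chrom: Sequence[AlignmentRecord],
    min_query_coverage: float = DEFAULT_MIN_QUERY_COVERAGE,
) -> ReplacementEvent:
    """Decide whether (and where) a candidate replaces chromosome sequence.

    The alignment with the most residue matches is chosen among those of
    this candidate overlapping the anchor's chromosome interval (or
    genome-wide for unanchored regions).  All failure modes are statuses,
    never exceptions: no alignment at all, query span below
    ``min_query_coverage`` of the candidate, or the gene interval not
    fully inside the aligned query span.  On success the event carries
    the alignment's target interval and the candidate's query-span bases,
    reverse-complemented to chromosome-forward when the strand is '-'.
    """
    if candidate.gene_status != "Complete" or candidate.gene_interval is None:
        raise ValueError("plan_replacement requires a Complete candidate gene")
    cand_id = candidate.record.id
    pool = [a for a in cand_to_chrom if a.query_id == cand_id]
    if anchor is not None:
        pool = [
            a
            for a in pool
            if a.target_id == anchor.chrom_id
            and min(a.target_end, anchor.end) > max(a.target_start, anchor.start)
        ]
    fallback_chrom = anchor.chrom_id if anchor is not None else ""
    if not pool:
        return ReplacementEvent(gene_id, fallback_chrom, None, "", cand_id, SKIPPED_NO_ALIGNMENT)

    best = min(pool, key=alignment_rank)
    span = best.query_end - best.query_start
    if span < min_query_coverage * len(candidate.record.bases):
        return ReplacementEvent(
            gene_id, best.target_id, None, "", cand_id, SKIPPED_LOW_COVERAGE
        )
    g_start, g_end = candidate.gene_interval
    if not (best.query_start <= g_start and g_end <= best.query_end):
        return ReplacementEvent(
            gene_id, best.target_id, None, "", cand_id, SKIPPED_GENE_OUTSIDE
        )
    new_bases = candidate.record.bases[best.query_start : best.query_end]
    if best.strand == "-":
        new_bases = reverse_complement(new_bases)
    return ReplacementEvent(
        gene_id,
        best.target_id,
        (best.target_start, best.target_end),
        new_bases,
        cand_id,
        APPLIED,
    )


def apply_replacements(
    assembly: Sequence[SequenceRecord], events: Sequence[ReplacementEvent]
) -> tuple[list[SequenceRecord], EditLedger]:
    """Splice applied events into the assembly, left to right per chromosome.

    Overlapping old intervals demote the later event (in positional
    order) to ``skipped_overlap`` — partial success, gene-by-gene
    accounting.  Untouched bases are preserved exactly and the returned
    ledger's offsets reproduce the coordinate shift of every splice.
    """
    by_id = {rec.id: rec for rec in assembly}
    final_events: list[ReplacementEvent] = []
    per_chrom: dict[str, list[ReplacementEvent]] = {}

    for event in events:
        if event.status != APPLIED:
            final_events.append(event)
            continue
        if event.chrom_id not in by_id:
            raise ValueError(f"event for gene {event.gene_id} references unknown chromosome {event.chrom_id}")
        start, end = event.old_interval
        if end > len(by_id[event.chrom_id].bases):
            raise ValueError(
                f"old_interval [{start},{end}) out of bounds on {event.chrom_id}"
            )
        per_chrom.setdefault(event.chrom_id, []).append(event)

    ledger = EditLedger()
    edited: dict[str, str] = {}
    for chrom_id, chrom_events in per_chrom.items():
        chrom_events.sort(key=lambda e: e.old_interval)
        kept: list[ReplacementEvent] = []
        prev_end = -1
        for event in chrom_events:
            start, end = event.old_interval
            if start < prev_end:
                demoted = ReplacementEvent(
                    event.gene_id, event.chrom_id, event.old_interval,
                    "", event.candidate_id, SKIPPED_OVERLAP,
                )
                logger.warning(
                    "event for gene %s on %s overlaps a prior splice; demoted",
                    event.gene_id, chrom_id,
                )
                final_events.append(demoted)
                continue
            kept.append(event)
            prev_end = end

        bases = by_id[chrom_id].bases
        parts: list[str] = []
        cursor = 0
        breakpoints: list[tuple[int, int, int]] = []
        for event in kept:
            start, end = event.old_interval
            parts.append(bases[cursor:start])
            parts.append(event.new_bases)
            breakpoints.append((start, end, len(event.new_bases) - (end - start)))
            cursor = end
            final_events.append(event)
        parts.append(bases[cursor:])
        edited[chrom_id] = "".join(parts)
        ledger.offsets[chrom_id] = breakpoints

    out = [
        SequenceRecord(rec.id, edited.get(rec.id, rec.bases), rec.description)
        for rec in assembly
    ]
    ledger.events = final_events
    return out, ledger


@dataclass
class RegressionReport:
    """Outcome of the final no-regression check on marker statuses."""

    worsened: list[tuple[str, str, str]]  # gene, before, after
    missing_before: int
    missing_after: int

    @property
    def ok(self) -> bool:
        return not self.worsened and self.missing_after <= self.missing_before


def verify_no_regression(
    before: GeneStatusTable, after: GeneStatusTable
) -> RegressionReport:
    """List genes whose status worsened on the Complete > Duplicated >
    Fragmented > Missing lattice; ok iff none did and the Missing count
    did not increase.  A gene absent from one table counts as Missing."""
    genes = before.gene_ids | after.gene_ids

    def status(table: GeneStatusTable, gene: str) -> str:
        return table.status_of(gene) if gene in table.by_gene else "Missing"

    worsened = []
    for gene in sorted(genes):
        s_before, s_after = status(before, gene), status(after, gene)
        if _STATUS_RANK[s_after] < _STATUS_RANK[s_before]:
            worsened.append((gene, s_before, s_after))
    return RegressionReport(
        worsened=worsened,
        missing_before=sum(1 for g in genes if status(before, g) == "Missing"),
        missing_after=sum(1 for g in genes if status(after, g) == "Missing"),
    )
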