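"""Phase 3 — recall reads around a missing region and reassemble them.

Reads are recruited from two sources and merged: every read aligning to
the lost contig itself, and (for anchored regions) every read aligning to
the chromosome neighborhood around the anchor, padded by ``flank_bp`` on
each side so junction-spanning reads are captured.  The merged set is fed
to an assembler; among the resulting sequences the one in which the
target gene is intact (and longest) is selected per gene.

The built-in assembler is a greedy maximal exact suffix-prefix overlap
merger, suitable only for the error-free reads of synthetic fixtures;
real error profiles go through the external assembler adapter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

from .io_formats import AlignmentRecord, SequenceRecord, reverse_complement
from .locate import MissingRegion
from .markers import MarkerCatalog, toy_marker_scan

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 50_000
DEFAULT_MIN_OLAP = 500


@dataclass
class RecallSet:
    """Reads recruited for one missing region, with per-read provenance."""

    region: MissingRegion
    reads: list[SequenceRecord]
    provenance: dict[str, str]  # read id -> contig | chromosome_neighborhood | both

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate read ids in recall set")
        for rid in ids:
            if rid not in self.provenance:
                raise ValueError(f"read {rid} lacks a provenance source")

    @property
    def read_ids(self) -> set[str]:
        return {r.id for r in self.reads}

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class CandidateSequence:
    """An assembled sequence judged by the integrity of one target gene."""

    record: SequenceRecord
    gene_status: str
    gene_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if (self.gene_status == "Complete") != (self.gene_interval is not None):
            raise ValueError("gene_interval present iff status Complete")


def reads_overlapping_interval(
    alignments: Sequence[AlignmentRecord],
    target_id: str,
    interval: tuple[int, int],
    min_overlap_bp: int = 1,
) -> set[str]:
    """Query ids whose target interval overlaps ``interval`` by >= min_overlap_bp."""
    start, end = interval
    if not start < end:
        raise ValueError(f"empty interval [{start},{end})")
    hits = set()
    for a in alignments:
        if a.target_id != target_id:
            continue
        overlap = min(a.target_end, end) - max(a.target_start, start)
        if overlap >= min_overlap_bp:
            hits.add(a.query_id)
    return hits


def recall_reads(
    region: MissingRegion,
    reads_to_contigs: Sequence[AlignmentRecord],
    reads_to_chrom: Sequence[AlignmentRecord],
    reads: Sequence[SequenceRecord],
    flank_bp: int = DEFAULT_FLANK_BP,
    min_overlap_bp: int = 1,
) -> RecallSet:
    """Union of contig-recalled and neighborhood-recalled reads.

    Source (i): reads overlapping the whole lost contig.  Source (ii),
    anchored regions only: reads overlapping the anchor interval padded by
    ``flank_bp`` and clamped to the chromosome.  Reads found by both get
    provenance ``both``.  A recalled id absent from the read set is an
    error (the alignments and the read file disagree).
    """
    from_contig = reads_overlapping_interval(
        reads_to_contigs, region.contig_id, (0, region.contig_len), min_overlap_bp
    )
    from_chrom: set[str] = set()
    if region.anchor is not None:
        chrom_len = region.anchor.source_alignment.target_len
        window = (
            max(0, region.anchor.start - flank_bp),
            min(chrom_len, region.anchor.end + flank_bp),
        )
        from_chrom = reads_overlapping_interval(
            reads_to_chrom, region.anchor.chrom_id, window, min_overlap_bp
        )

    by_id = {r.id: r for r in reads}
    provenance: dict[str, str] = {}
    for rid in sorted(from_contig | from_chrom):
        if rid not in by_id:
            raise ValueError(f"recalled read {rid!r} absent from the read set")
        if rid in from_contig and rid in from_chrom:
            provenance[rid] = "both"
        elif rid in from_contig:
            provenance[rid] = "contig"
        else:
            provenance[rid] = "chromosome_neighborhood"
    recalled = [by_id[rid] for rid in sorted(provenance)]
    return RecallSet(region=region, reads=recalled, provenance=provenance)


# ---------------------------------------------------------------------------
# built-in greedy overlap assembler


def _max_suffix_prefix_overlap(a: str, b: str, probe_len: int = 32) -> int:
    """Largest t with a[-t:] == b[:t]; 0 when none.

    Seeds candidate offsets with a short prefix probe of ``b`` searched in
    the relevant suffix window of ``a``; the leftmost verified hit gives
    the maximal overlap.
    """
    w = min(len(a), len(b))
    if w < probe_len:
        probe_len = w
    if probe_len == 0:
        return 0
    probe = b[:probe_len]
    pos = a.find(probe, len(a) - w)
    while pos != -1:
        t = len(a) - pos
        if a[pos:] == b[:t]:
            return t
        pos = a.find(probe, pos + 1)
    return 0


def toy_assemble(
    reads: Sequence[SequenceRecord], min_olap: int = DEFAULT_MIN_OLAP
) -> list[SequenceRecord]:
    """Greedy merging by maximal exact suffix-prefix overlap.

    Both strands are considered; the seed order is deterministic (longest
    sequence first, lexicographic id as tie-break) and each round merges
    the seed with its best partner — by largest overlap, then partner id,
    forward orientation before reverse, right extension before left.  A
    partner fully contained in the seed (either strand) is absorbed.
    Terminates when no pair can merge.  Exact-overlap-only: intended for
    error-free fixture reads.
    """
    if not reads:
        raise ValueError("assembler needs at least one read")
    pool: dict[str, str] = {}
    for r in reads:
        if r.id in pool:
            raise ValueError(f"duplicate read id {r.id}")
        pool[r.id] = r.bases

    def order_ids() -> list[str]:
        return sorted(pool, key=lambda i: (-len(pool[i]), i))

    merged = True
    while merged and len(pool) > 1:
        merged = False
        ordering = order_ids()
        for seed in ordering:
            a = pool[seed]
            # (overlap, partner_id, orient_rank, mode_rank, mode, orient)
            best: tuple | None = None
            for pid in ordering:
                if pid == seed:
                    continue
                raw = pool[pid]
                for orient_rank, orient in ((0, "+"), (1, "-")):
                    b = raw if orient == "+" else reverse_complement(raw)
                    if len(b) <= len(a) and b in a:
                        cand = (len(b), pid, orient_rank, 0, "contain", orient)
                    else:
                        t_right = _max_suffix_prefix_overlap(a, b)
                        t_left = _max_suffix_prefix_overlap(b, a)
                        if t_right >= t_left:
                            cand = (t_right, pid, orient_rank, 1, "right", orient)
                        else:
                            cand = (t_left, pid, orient_rank, 2, "left", orient)
                    if cand[0] >= min_olap and (
                        best is None
                        or (-cand[0], cand[1], cand[2], cand[3])
                        < (-best[0], best[1], best[2], best[3])
                    ):
                        best = cand
            if best is None:
                continue
            t, pid, _, _, mode, orient = best
            b = pool[pid] if orient == "+" else reverse_complement(pool[pid])
            if mode == "contain":
                new = a
            elif mode == "right":
                new = a + b[t:]
            else:
                new = b[: len(b) - t] + a
            del pool[pid]
            pool[seed] = new
            merged = True
            break

    return [
        SequenceRecord(id=rid, bases=pool[rid])
        for rid in sorted(pool, key=lambda i: (-len(pool[i]), i))
    ]


def assemble_candidates(
    recall_set: RecallSet,
    assembler: Callable[[Sequence[SequenceRecord]], list[SequenceRecord]] | None = None,
    min_olap: int = DEFAULT_MIN_OLAP,
) -> list[SequenceRecord]:
    """Run the assembler adapter (default: built-in greedy merger)."""
    if len(recall_set) == 0:
        raise ValueError("recall set is empty; nothing to assemble")
    if assembler is None:
        return toy_assemble(recall_set.reads, min_olap=min_olap)
    return list(assembler(recall_set.reads))


def select_candidate(
    candidates: Sequence[SequenceRecord],
    gene_id: str,
    catalog: MarkerCatalog,
    assessor: Callable[[Sequence[SequenceRecord]], object] | None = None,
) -> CandidateSequence | None:
    """Pick the candidate on which the target gene is intact.

    Each candidate is assessed independently (they are alternative
    reconstructions, not a joint assembly).  Among candidates where the
    gene is Complete the longest wins, ties broken by lexicographically
    smaller id; None means the recall failed for this gene.
    """
    marker_only = catalog.subset([gene_id])
    scan = assessor if assessor is not None else (
        lambda recs: toy_marker_scan(recs, marker_only)
    )
    qualifying: list[CandidateSequence] = []
    for cand in candidates:
        table = scan([cand])
        if gene_id not in table.by_gene:
            continue
        hit = table.by_gene[gene_id][0]
        if table.status_of(gene_id) == "Complete":
            qualifying.append(
                CandidateSequence(cand, "Complete", hit.interval)
            )
    if not qualifying:
        logger.info("recall failed for gene %s: no candidate carries it intact", gene_id)
        return None
    return min(qualifying, key=lambda c: (-len(c.record.bases), c.record.id))
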