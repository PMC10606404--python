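"""Phase 2 — turn fillable genes into anchored missing regions.

Each fillable gene is looked up in the contig-set assessor table to find
its host contig; the whole contig is taken as the missing genomic region
(broad on purpose, so the later read recall is complete).  The contig is
then anchored to a chromosome interval by choosing its best
contig-to-chromosome alignment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io_formats import AlignmentRecord, GeneStatusTable, SequenceRecord
from .markers import FillableGeneList

logger = logging.getLogger(__name__)

DEFAULT_MIN_ANCHOR_MATCHES = 500


@dataclass
class ChromosomeAnchor:
    """The chromosome interval a lost contig aligns to best."""

    chrom_id: str
    start: int
    end: int
    strand: str
    source_alignment: AlignmentRecord

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end <= self.source_alignment.target_len:
            raise ValueError("anchor interval outside chromosome")
        if self.strand != self.source_alignment.strand:
            raise ValueError("anchor strand disagrees with source alignment")


@dataclass
class MissingRegion:
    """A lost contig hosting one or more fillable genes, plus its anchor."""

    contig_id: str
    contig_len: int
    gene_ids: list[str]
    gene_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    anchor: ChromosomeAnchor | None = None

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("region must host at least one gene")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in region")
        for gene, (start, end) in self.gene_intervals.items():
            if not 0 <= start < end <= self.contig_len:
                raise ValueError(
                    f"gene {gene} interval [{start},{end}) outside contig "
                    f"{self.contig_id} of length {self.contig_len}"
                )


def locate_gene_in_contigs(
    gene_id: str, contig_table: GeneStatusTable
) -> tuple[str, tuple[int, int]]:
    """Host contig and 0-based half-open interval of a Complete gene."""
    if gene_id not in contig_table.by_gene:
        raise ValueError(f"gene {gene_id} absent from contig table")
    hits = contig_table.by_gene[gene_id]
    if contig_table.status_of(gene_id) != "Complete" or len(hits) != 1:
        raise ValueError(
            f"gene {gene_id} is {contig_table.status_of(gene_id)} in the contig "
            "table; locating requires exactly one Complete hit"
        )
    hit = hits[0]
    return hit.sequence_id, hit.interval


def alignment_rank(a: AlignmentRecord) -> tuple:
    """Sort key for choosing among alignments: most matches first, then
    longest block, then lexicographically smallest target, then leftmost."""
    return (-a.residue_matches, -a.block_len, a.target_id, a.target_start)


def select_anchor_alignment(
    contig_id: str,
    alignments: Sequence[AlignmentRecord],
    min_anchor_matches: int = DEFAULT_MIN_ANCHOR_MATCHES,
) -> ChromosomeAnchor | None:
    """Best primary contig-to-chromosome alignment for one contig.

    Records without a ``tp`` tag count as primary.  Among candidates with
    ``residue_matches >= min_anchor_matches`` the maximum under
    :func:`alignment_rank` wins; returns None when nothing passes the
    floor (the contig stays unanchored).
    """
    pool = [
        a
        for a in alignments
        if a.query_id == contig_id
        and a.is_primary()
        and a.residue_matches >= min_anchor_matches
    ]
    if not pool:
        return None
    best = min(pool, key=alignment_rank)
    others = {a.target_id for a in pool if a.target_id != best.target_id}
    if others:
        logger.info(
            "contig %s also aligns to %s; keeping single best anchor on %s",
            contig_id, sorted(others), best.target_id,
        )
    return ChromosomeAnchor(
        chrom_id=best.target_id,
        start=best.target_start,
        end=best.target_end,
        strand=best.strand,
        source_alignment=best,
    )


def build_missing_regions(
    fillable: FillableGeneList,
    contig_table: GeneStatusTable,
    contigs: Sequence[SequenceRecord],
    contig_to_chrom: Sequence[AlignmentRecord],
    min_anchor_matches: int = DEFAULT_MIN_ANCHOR_MATCHES,
) -> list[MissingRegion]:
    """One region per host contig, genes grouped, anchors attached.

    Unanchored regions (no alignment clearing the match floor) are
    retained; downstream phases recall reads from the contig alone and a
    replacement is only attempted if the assembled candidate later aligns
    confidently on its own.
    """
    contig_len = {rec.id: len(rec.bases) for rec in contigs}
    grouped: dict[str, dict[str, tuple[int, int]]] = {}
    for gene_id in fillable:
        host, interval = locate_gene_in_contigs(gene_id, contig_table)
        if host not in contig_len:
            raise ValueError(
                f"gene {gene_id} locates to contig {host}, absent from the contig set"
            )
        grouped.setdefault(host, {})[gene_id] = interval

    regions = []
    for host in sorted(grouped):
        anchor = select_anchor_alignment(host, contig_to_chrom, min_anchor_matches)
        if anchor is None:
            logger.warning("region %s is unanchored", host)
        regions.append(
            MissingRegion(
                contig_id=host,
                contig_len=contig_len[host],
                gene_ids=sorted(grouped[host]),
                gene_intervals=dict(grouped[host]),
                anchor=anchor,
            )
        )
    return regions


# ---------------------------------------------------------------------------
# serialization of the region report


def regions_to_bed(regions: Sequence[MissingRegion]) -> str:
    """Anchored regions as BED lines, name = contig_id:gene_ids."""
    lines = []
    for r in regions:
        if r.anchor is None:
            continue
        name = f"{r.contig_id}:{','.join(r.gene_ids)}"
        lines.append(
            f"{r.anchor.chrom_id}\t{r.anchor.start}\t{r.anchor.end}\t{name}\t"
            f"{r.anchor.source_alignment.residue_matches}\t{r.anchor.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def regions_to_json(regions: Sequence[MissingRegion]) -> str:
    payload = []
    for r in regions:
        entry = {
            "contig_id": r.contig_id,
            "contig_len": r.contig_len,
            "gene_ids": r.gene_ids,
            "gene_intervals": {g: list(iv) for g, iv in r.gene_intervals.items()},
            "anchor": None,
        }
        if r.anchor is not None:
            entry["anchor"] = {
                "chrom_id": r.anchor.chrom_id,
                "start": r.anchor.start,
                "end": r.anchor.end,
                "strand": r.anchor.strand,
                "residue_matches": r.anchor.source_alignment.residue_matches,
            }
        payload.append(entry)
    return json.dumps(payload, indent=2)


def write_region_report(regions: Sequence[MissingRegion], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "regions.bed").write_text(regions_to_bed(regions))
    (out_dir / "regions.json").write_text(regions_to_json(regions))
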