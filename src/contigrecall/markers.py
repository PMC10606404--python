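"""Phase 1 — which single-copy marker genes can be used to fill the assembly.

A marker gene that a completeness assessor calls Missing on the
chromosome-level assembly but Complete (exactly one unambiguous locus) in
the merged contig set pinpoints a sequence lost during assembly or
scaffolding.  The set difference of the two assessor reports is the list
of fillable genes.

``toy_marker_scan`` is a deterministic, exact-substring stand-in for the
external assessor, adequate for noise-free fixtures where markers are
planted verbatim; real data goes through the assessor adapter instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io_formats import (
    GeneStatusTable,
    MarkerHit,
    SequenceRecord,
    read_fasta,
    reverse_complement,
    write_fasta,
)

logger = logging.getLogger(__name__)


@dataclass
class Marker:
    gene_id: str
    bases: str
    min_fragment_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"marker {self.gene_id} has an empty sequence")
        if not 0 < self.min_fragment_fraction <= 1:
            raise ValueError("min_fragment_fraction must lie in (0, 1]")


@dataclass
class MarkerCatalog:
    """The marker gene set playing the role of an ortholog lineage database."""

    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.gene_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker gene_ids must be unique")
        seqs = [m.bases for m in self.markers]
        if len(set(seqs)) != len(seqs):
            raise ValueError("marker sequences must be unique")

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def get(self, gene_id: str) -> Marker:
        for m in self.markers:
            if m.gene_id == gene_id:
                return m
        raise KeyError(gene_id)

    def subset(self, gene_ids: Sequence[str]) -> "MarkerCatalog":
        wanted = set(gene_ids)
        return MarkerCatalog([m for m in self.markers if m.gene_id in wanted])

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(
            [SequenceRecord(m.gene_id, m.bases) for m in self.markers], path
        )

    @classmethod
    def from_fasta(
        cls, path: str | Path, min_fragment_fraction: float = 0.5
    ) -> "MarkerCatalog":
        return cls(
            [
                Marker(rec.id, rec.bases, min_fragment_fraction)
                for rec in read_fasta(path)
            ]
        )


@dataclass
class FillableGeneList:
    """Ordered genes Missing on chromosomes but Complete in the contig set."""

    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("fillable gene list contains duplicates")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def missing_genes(table: GeneStatusTable) -> set[str]:
    """Genes whose status is Missing in the given assessor table."""
    return table.genes_with_status("Missing")


def fillable_genes(
    chrom_table: GeneStatusTable,
    contig_table: GeneStatusTable,
    include_fragmented: bool = False,
) -> FillableGeneList:
    """Set difference of Phase 1: lost on chromosomes, recoverable from contigs.

    A gene qualifies when it is Missing in ``chrom_table`` (optionally also
    Fragmented, with ``include_fragmented``) and exactly Complete — one
    unambiguous locus — in ``contig_table``.  Output order is
    lexicographic for determinism.  Mismatched gene universes trigger a
    warning and are intersected.
    """
    universe = chrom_table.gene_ids
    if universe != contig_table.gene_ids:
        logger.warning(
            "gene universes differ between tables (%d vs %d genes); using intersection",
            len(universe),
            len(contig_table.gene_ids),
        )
        universe = universe & contig_table.gene_ids

    lost = {"Missing", "Fragmented"} if include_fragmented else {"Missing"}
    genes = sorted(
        g
        for g in universe
        if chrom_table.status_of(g) in lost
        and contig_table.status_of(g) == "Complete"
        and len(contig_table.by_gene[g]) == 1
    )
    return FillableGeneList(genes)


# ---------------------------------------------------------------------------
# toy assessor


def _find_occurrences(
    assembly: Sequence[SequenceRecord], pattern: str
) -> list[tuple[str, int, int, str]]:
    """All (possibly overlapping) exact occurrences of pattern, both strands."""
    hits = []
    rc = reverse_complement(pattern)
    strands = [("+", pattern)] if rc == pattern else [("+", pattern), ("-", rc)]
    for rec in assembly:
        for strand, probe in strands:
            pos = rec.bases.find(probe)
            while pos != -1:
                hits.append((rec.id, pos, pos + len(probe), strand))
                pos = rec.bases.find(probe, pos + 1)
    return hits


def _longest_shared_fragment(
    assembly: Sequence[SequenceRecord], marker: str, min_len: int
) -> tuple[str, int, int, str] | None:
    """Longest contiguous marker substring (>= min_len) present in assembly.

    Binary search on fragment length; at each length every marker window is
    probed with C-speed substring search on both strands.  Returns the hit
    location of one longest fragment, or None when even min_len fails.
    """

    def best_at(length: int) -> tuple[str, int, int, str] | None:
        for offset in range(0, len(marker) - length + 1):
            window = marker[offset : offset + length]
            found = _find_occurrences(assembly, window)
            if found:
                return found[0]
        return None

    if min_len > len(marker) or best_at(min_len) is None:
        return None
    lo, hi = min_len, len(marker)  # invariant: a fragment of length lo exists
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if best_at(mid) is not None:
            lo = mid
        else:
            hi = mid - 1
    return best_at(lo)


def toy_marker_scan(
    assembly: Sequence[SequenceRecord], catalog: MarkerCatalog
) -> GeneStatusTable:
    """Deterministic exact-match completeness scan.

    Per marker: Complete when its full sequence (either strand) occurs
    exactly once across the assembly, Duplicated when more often,
    Fragmented when a contiguous substring of at least
    ``min_fragment_fraction x marker length`` occurs, otherwise Missing.
    """
    hits: list[MarkerHit] = []
    for marker in catalog:
        occ = _find_occurrences(assembly, marker.bases)
        if len(occ) == 1:
            seq_id, start, end, strand = occ[0]
            hits.append(
                MarkerHit(
                    marker.gene_id, "Complete", seq_id, start, end, strand,
                    score=float(len(marker.bases)), length=len(marker.bases),
                )
            )
        elif len(occ) > 1:
            for seq_id, start, end, strand in occ:
                hits.append(
                    MarkerHit(
                        marker.gene_id, "Duplicated", seq_id, start, end, strand,
                        score=float(len(marker.bases)), length=len(marker.bases),
                    )
                )
        else:
            min_len = max(1, int(marker.min_fragment_fraction * len(marker.bases)))
            frag = _longest_shared_fragment(assembly, marker.bases, min_len)
            if frag is not None:
                seq_id, start, end, strand = frag
                hits.append(
                    MarkerHit(
                        marker.gene_id, "Fragmented", seq_id, start, end, strand,
                        score=float(end - start), length=end - start,
                    )
                )
            else:
                hits.append(MarkerHit(marker.gene_id, "Missing"))
    return GeneStatusTable.from_hits(hits)
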