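"""Readers and writers for the plain-text formats the pipeline touches.

FASTA and FASTQ go through Biopython's :mod:`Bio.SeqIO`; PAF (minimap2
dialect, optional SAM-style tags) and the completeness assessor's
``full_table`` TSV are parsed here because no pre-packaged parser exists
for them.

Coordinate convention
---------------------
Everything held in memory is 0-based half-open.  The only places where
1-based inclusive coordinates appear are the full_table parse/serialize
boundary; PAF is already 0-based half-open on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO


class FormatError(ValueError):
    """An input file violates its format contract."""


VALID_STATUSES = ("Complete", "Duplicated", "Fragmented", "Missing")

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")
_WHITESPACE = (" ", "\t", "\n", "\r")


def reverse_complement(bases: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet.

    An involution: ``reverse_complement(reverse_complement(x)) == x``;
    ``N`` maps to ``N``.  Any other character raises :class:`ValueError`.
    """
    invalid = set(bases) - set("ACGTN")
    if invalid:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(invalid)}")
    return bases.translate(_RC_TABLE)[::-1]


@dataclass
class SequenceRecord:
    """One named sequence: an assembly chromosome, a contig, or a read."""

    id: str
    bases: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        for ws in _WHITESPACE:
            if ws in self.bases:
                raise ValueError(f"whitespace in bases of record {self.id!r}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignmentRecord:
    """One PAF row, 0-based half-open on both query and target.

    For ``strand == '-'`` the query interval is still given on the
    forward query sequence; its reverse complement aligns to the
    forward target interval (minimap2 convention).
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    residue_matches: int
    block_len: int
    mapq: int
    tags: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(
                f"query interval [{self.query_start},{self.query_end}) "
                f"invalid for length {self.query_len}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(
                f"target interval [{self.target_start},{self.target_end}) "
                f"invalid for length {self.target_len}"
            )
        if self.residue_matches > self.block_len:
            raise ValueError("residue_matches exceeds block_len")
        if not (0 <= self.mapq <= 255):
            raise ValueError(f"mapq {self.mapq} outside [0,255]")

    def is_primary(self) -> bool:
        """True unless explicitly tagged as a secondary alignment."""
        return self.tags.get("tp", "P") == "P"


@dataclass
class MarkerHit:
    """One completeness-assessor row for a single-copy marker gene."""

    gene_id: str
    status: str
    sequence_id: str | None = None
    start: int | None = None  # 0-based half-open once in memory
    end: int | None = None
    strand: str | None = None
    score: float | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "Missing":
            if self.sequence_id is not None or self.start is not None:
                raise ValueError(f"Missing hit for {self.gene_id} carries a location")
        else:
            if self.sequence_id is None or self.start is None or self.end is None:
                raise ValueError(f"{self.status} hit for {self.gene_id} lacks a location")
            if not self.start < self.end:
                raise ValueError(f"empty interval for {self.gene_id}")

    @property
    def interval(self) -> tuple[int, int]:
        if self.start is None or self.end is None:
            raise ValueError(f"hit for {self.gene_id} has no interval")
        return (self.start, self.end)


class GeneStatusTable:
    """All marker hits of one assembly, indexed by gene.

    A gene reported Complete more than once is reclassified Duplicated at
    construction time so that "Complete" always means "exactly one
    unambiguous locus".
    """

    def __init__(self, hits: Sequence[MarkerHit]):
        self.hits: list[MarkerHit] = list(hits)
        self.by_gene: dict[str, list[MarkerHit]] = {}
        for hit in self.hits:
            self.by_gene.setdefault(hit.gene_id, []).append(hit)
        self._validate()

    @classmethod
    def from_hits(cls, hits: Sequence[MarkerHit]) -> "GeneStatusTable":
        """Build a table, demoting multi-hit Complete genes to Duplicated."""
        by_gene: dict[str, list[MarkerHit]] = {}
        for hit in hits:
            by_gene.setdefault(hit.gene_id, []).append(hit)
        fixed: list[MarkerHit] = []
        for hit in hits:
            group = by_gene[hit.gene_id]
            if len(group) > 1 and hit.status == "Complete":
                hit = MarkerHit(
                    hit.gene_id, "Duplicated", hit.sequence_id, hit.start,
                    hit.end, hit.strand, hit.score, hit.length,
                )
            fixed.append(hit)
        return cls(fixed)

    def _validate(self) -> None:
        for gene, group in self.by_gene.items():
            statuses = {h.status for h in group}
            if len(group) > 1:
                if statuses != {"Duplicated"}:
                    raise ValueError(
                        f"gene {gene} has {len(group)} hits with statuses {sorted(statuses)}"
                    )
            elif group[0].status == "Duplicated":
                # tolerated: a Duplicated call whose extra loci were not reported
                pass

    def status_of(self, gene_id: str) -> str:
        return self.by_gene[gene_id][0].status

    def genes_with_status(self, status: str) -> set[str]:
        return {g for g, group in self.by_gene.items() if group[0].status == status}

    @property
    def gene_ids(self) -> set[str]:
        return set(self.by_gene)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneStatusTable):
            return NotImplemented
        return self.hits == other.hits

    def __repr__(self) -> str:
        counts = {s: len(self.genes_with_status(s)) for s in VALID_STATUSES}
        return f"GeneStatusTable({counts})"


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; bases are uppercased, header order preserved."""
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}: sequence data before first '>' header")
                break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                bases=str(rec.seq).upper(),
                description=_strip_id(rec.description, rec.id),
            )
        )
    return records


def _strip_id(description: str, rec_id: str) -> str:
    if description == rec_id:
        return ""
    if description.startswith(rec_id + " "):
        return description[len(rec_id) + 1 :]
    return description


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write FASTA with deterministic byte output at the given wrap width."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}" if rec.description else f">{rec.id}"
            fh.write(header + "\n")
            for i in range(0, len(rec.bases), line_width):
                fh.write(rec.bases[i : i + line_width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ, discarding quality strings (no phase consumes them)."""
    try:
        return [
            SequenceRecord(id=rec.id, bases=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")
        ]
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write FASTQ with uniform placeholder qualities ('I')."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.bases}\n+\n{'I' * len(rec.bases)}\n")


# ---------------------------------------------------------------------------
# PAF

_TAG_TYPES = {"i": int, "f": float, "A": str, "Z": str, "H": str, "B": str}


def parse_paf(path: str | Path) -> list[AlignmentRecord]:
    """Parse a PAF file, enforcing every AlignmentRecord invariant.

    Rows with fewer than 12 columns, non-integer coordinates, or
    invariant-violating intervals are rejected with their line number.
    Extra columns matching ``TAG:TYPE:VALUE`` become typed tags; other
    extras are ignored.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: PAF row has {len(fields)} columns, need >= 12"
                )
            try:
                rec = AlignmentRecord(
                    query_id=fields[0],
                    query_len=int(fields[1]),
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    strand=fields[4],
                    target_id=fields[5],
                    target_len=int(fields[6]),
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    residue_matches=int(fields[9]),
                    block_len=int(fields[10]),
                    mapq=int(fields[11]),
                    tags=_parse_tags(fields[12:]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                rec.validate()
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def _parse_tags(extras: Sequence[str]) -> dict:
    tags = {}
    for extra in extras:
        parts = extra.split(":", 2)
        if len(parts) == 3 and len(parts[0]) == 2 and parts[1] in _TAG_TYPES:
            try:
                tags[parts[0]] = _TAG_TYPES[parts[1]](parts[2])
            except ValueError:
                continue
    return tags


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [
                r.query_id, r.query_len, r.query_start, r.query_end, r.strand,
                r.target_id, r.target_len, r.target_start, r.target_end,
                r.residue_matches, r.block_len, r.mapq,
            ]
            for tag, value in sorted(r.tags.items()):
                type_code = "i" if isinstance(value, int) else (
                    "f" if isinstance(value, float) else
                    ("A" if len(str(value)) == 1 else "Z"))
                cols.append(f"{tag}:{type_code}:{value}")
            fh.write("\t".join(str(c) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# full_table TSV (completeness assessor)


def parse_busco_full_table(path: str | Path) -> GeneStatusTable:
    """Parse an assessor full_table TSV into a :class:`GeneStatusTable`.

    The 8-column dialect is read positionally (gene id, status, sequence,
    gene start, gene end, strand, score, length); '#' comment lines are
    skipped, trailing extra columns tolerated, and Missing rows may carry
    only the first two columns.  On-disk coordinates are 1-based
    inclusive and converted to 0-based half-open here.
    """
    path = Path(path)
    hits: list[MarkerHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: row needs gene id and status")
            gene_id, status = fields[0], fields[1]
            if status not in VALID_STATUSES:
                raise FormatError(f"{path}:{lineno}: unknown status word {status!r}")
            try:
                if status == "Missing":
                    hits.append(MarkerHit(gene_id, "Missing"))
                    continue
                if len(fields) < 5 or not fields[2] or not fields[3] or not fields[4]:
                    raise FormatError(
                        f"{path}:{lineno}: {status} row lacking coordinates"
                    )
                start = int(fields[3]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(fields[4])
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
                score = float(fields[6]) if len(fields) > 6 and fields[6] else None
                length = int(fields[7]) if len(fields) > 7 and fields[7] else None
                hits.append(
                    MarkerHit(gene_id, status, fields[2], start, end, strand, score, length)
                )
            except FormatError:
                raise
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return GeneStatusTable.from_hits(hits)


def write_busco_full_table(table: GeneStatusTable, path: str | Path) -> None:
    """Serialize a table back to the 8-column full_table dialect."""
    with open(path, "w") as fh:
        fh.write("# gene_id\tstatus\tsequence\tgene_start\tgene_end\tstrand\tscore\tlength\n")
        for hit in table.hits:
            if hit.status == "Missing":
                fh.write(f"{hit.gene_id}\tMissing\n")
                continue
            cols = [
                hit.gene_id,
                hit.status,
                hit.sequence_id,
                str(hit.start + 1),  # back to 1-based inclusive
                str(hit.end),
                hit.strand if hit.strand else "",
                f"{hit.score:g}" if hit.score is not None else "",
                str(hit.length) if hit.length is not None else "",
            ]
            fh.write("\t".join(cols) + "\n")
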