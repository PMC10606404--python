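"""Truth-tracked synthetic fixtures and a desk-scale k-mer aligner.

The generator emulates the study conditions the pipeline targets: a
truth genome carrying uniquely identifiable single-copy marker genes, a
chromosome-level assembly degraded by excising marker loci, the excised
segments surviving as small "lost" contigs distributed over two or more
contig sets (as if produced by different assemblers), HiFi-like long
reads at depth ~20 with recorded origins, and optionally a second
haplotype mutated at given SNP/indel rates (defaults: substitution,
insertion and deletion each at 0.02 per base, indel length 12 bp).

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import AlignmentRecord, SequenceRecord, reverse_complement
from .markers import Marker, MarkerCatalog

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _random_bases(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length, dtype=np.uint8)].tobytes().decode()


@dataclass
class Deletion:
    chrom_id: str
    start: int
    end: int
    gene_ids: list[str]


@dataclass
class FixtureTruth:
    """Full provenance of a synthetic fixture."""

    truth_genome: list[SequenceRecord]
    catalog: MarkerCatalog
    marker_loci: dict[str, tuple[str, int, int, str]]  # gene -> chrom, start, end, strand
    seed: int
    deletions: list[Deletion] = field(default_factory=list)
    lost_contigs: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    read_origins: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)

    def chrom(self, chrom_id: str) -> SequenceRecord:
        for rec in self.truth_genome:
            if rec.id == chrom_id:
                return rec
        raise KeyError(chrom_id)


@dataclass
class DiploidParams:
    """Per-base mutation rates for building a second haplotype."""

    snp_rate: float = 0.02
    ins_rate: float = 0.02
    del_rate: float = 0.02
    indel_len: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.snp_rate, self.ins_rate, self.del_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")
        if self.snp_rate + self.ins_rate + self.del_rate >= 1:
            raise ValueError("combined event probability must stay below 1")
        if self.indel_len < 1:
            raise ValueError("indel_len must be >= 1")


def generate_genome(
    n_chrom: int,
    chrom_len: int,
    n_markers: int,
    marker_len: int,
    seed: int,
    min_separation_bp: int = 12_000,
    end_margin_bp: int = 12_000,
) -> FixtureTruth:
    """Random genome with unique marker genes planted at interior loci.

    Markers are random sequences planted forward at non-overlapping loci
    kept ``min_separation_bp`` apart and ``end_margin_bp`` away from
    chromosome ends (so later deletions with margins stay interior), each
    verified to occur exactly once genome-wide on either strand
    (regenerated on collision).  Deterministic given the seed.
    """
    if n_markers * marker_len >= n_chrom * chrom_len // 4:
        raise ValueError("markers would occupy too much of the genome")
    rng = np.random.default_rng(seed)
    chroms = [
        SequenceRecord(f"chr{i + 1}", _random_bases(rng, chrom_len))
        for i in range(n_chrom)
    ]

    # pick loci: round-robin over chromosomes, rejection-sample positions
    loci: dict[str, list[tuple[int, int]]] = {c.id: [] for c in chroms}
    placements: list[tuple[str, int]] = []
    for i in range(n_markers):
        chrom = chroms[i % n_chrom]
        lo, hi = end_margin_bp, chrom_len - end_margin_bp - marker_len
        if hi <= lo:
            raise ValueError("chromosome too short for the requested margins")
        for _ in range(1000):
            pos = int(rng.integers(lo, hi))
            if all(
                abs(pos - other) >= min_separation_bp + marker_len
                for other, _ in loci[chrom.id]
            ):
                break
        else:
            raise ValueError("cannot place markers without overlap; reduce n_markers")
        loci[chrom.id].append((pos, pos + marker_len))
        placements.append((chrom.id, pos))

    markers: list[Marker] = []
    marker_loci: dict[str, tuple[str, int, int, str]] = {}
    bases_by_id = {c.id: c.bases for c in chroms}
    for i, (chrom_id, pos) in enumerate(placements):
        gene_id = f"gene{i + 1:03d}"
        for _ in range(10):
            seq = _random_bases(rng, marker_len)
            planted = bases_by_id[chrom_id][:pos] + seq + bases_by_id[chrom_id][pos + marker_len:]
            trial = dict(bases_by_id)
            trial[chrom_id] = planted
            total = sum(
                b.count(seq) + b.count(reverse_complement(seq))
                for b in trial.values()
            )
            if seq == reverse_complement(seq):
                total //= 2
            if total == 1 and all(seq != m.bases for m in markers):
                bases_by_id = trial
                break
        else:
            raise ValueError(f"could not plant a unique sequence for {gene_id}")
        markers.append(Marker(gene_id, seq))
        marker_loci[gene_id] = (chrom_id, pos, pos + marker_len, "+")

    genome = [SequenceRecord(c.id, bases_by_id[c.id]) for c in chroms]
    return FixtureTruth(
        truth_genome=genome,
        catalog=MarkerCatalog(markers),
        marker_loci=marker_loci,
        seed=seed,
    )


def degrade_assembly(
    truth: FixtureTruth,
    genes_to_drop: Sequence[str],
    gap_char_policy: str = "excise",
    contig_margin_bp: int = 2_000,
    n_sets: int = 2,
    jitter_bp: int = 300,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], list[list[SequenceRecord]]]:
    """Delete marker loci from the truth genome and keep them as lost contigs.

    Each dropped gene's locus padded by ``contig_margin_bp`` is removed
    from the chromosome (``excise``) or masked with N's (``n_fill``).
    The corresponding lost contig spans the removed segment padded by the
    margin again (plus a random jitter), so it shares flanking sequence
    with the surviving chromosome and can be anchored back.  Contigs are
    distributed round-robin over ``n_sets`` contig sets with jittered
    boundaries, mimicking assemblies from different tools while keeping
    each marker Complete exactly once in the merged set.  Deletions and
    lost-contig source intervals are recorded in ``truth``.
    """
    if gap_char_policy not in ("excise", "n_fill"):
        raise ValueError("gap_char_policy must be 'excise' or 'n_fill'")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)

    plans: dict[str, list[tuple[int, int, int, int, str]]] = {}
    for gene_id in sorted(genes_to_drop):
        if gene_id not in truth.marker_loci:
            raise ValueError(f"gene {gene_id} was never planted in the truth genome")
        chrom_id, m_start, m_end, _ = truth.marker_loci[gene_id]
        chrom_len = len(truth.chrom(chrom_id).bases)
        removed = (max(0, m_start - contig_margin_bp), min(chrom_len, m_end + contig_margin_bp))
        contig_span = (
            max(0, removed[0] - contig_margin_bp - int(rng.integers(0, jitter_bp + 1))),
            min(chrom_len, removed[1] + contig_margin_bp + int(rng.integers(0, jitter_bp + 1))),
        )
        plans.setdefault(chrom_id, []).append(
            (removed[0], removed[1], contig_span[0], contig_span[1], gene_id)
        )

    for chrom_id, chrom_plans in plans.items():
        chrom_plans.sort()
        for (_, r_end, _, c_end, g1), (r_start, _, c_start, _, g2) in zip(
            chrom_plans, chrom_plans[1:]
        ):
            if r_start < r_end or c_start < c_end:
                raise ValueError(f"drop loci of {g1} and {g2} overlap on {chrom_id}")

    contig_sets: list[list[SequenceRecord]] = [[] for _ in range(n_sets)]
    degraded: list[SequenceRecord] = []
    set_idx = 0
    for rec in truth.truth_genome:
        chrom_plans = plans.get(rec.id, [])
        parts: list[str] = []
        cursor = 0
        for r_start, r_end, c_start, c_end, gene_id in chrom_plans:
            parts.append(rec.bases[cursor:r_start])
            if gap_char_policy == "n_fill":
                parts.append("N" * (r_end - r_start))
            cursor = r_end
            contig_id = f"ctg_{gene_id}"
            contig_sets[set_idx % n_sets].append(
                SequenceRecord(contig_id, rec.bases[c_start:c_end])
            )
            truth.lost_contigs[contig_id] = (rec.id, c_start, c_end)
            truth.deletions.append(Deletion(rec.id, r_start, r_end, [gene_id]))
            set_idx += 1
        parts.append(rec.bases[cursor:])
        degraded.append(SequenceRecord(rec.id, "".join(parts), rec.description))
    return degraded, contig_sets


def simulate_reads(
    genome: Sequence[SequenceRecord],
    depth: float = 20.0,
    read_len_mean: int = 15_000,
    read_len_sd: int = 1_500,
    min_read_len: int = 1_000,
    error_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str = "read",
) -> tuple[list[SequenceRecord], dict[str, tuple[str, int, int, str]]]:
    """HiFi-like reads sampled uniformly from the genome, origins recorded.

    Read count is ``depth x genome length / read_len_mean``; lengths are
    normal (clamped to ``min_read_len`` and the chromosome), starts
    uniform, strands random, with independent per-base substitution
    errors at ``error_rate``.  Expected total bases equal depth times
    genome length up to sampling noise.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(r.bases) for r in genome], dtype=float)
    total = lengths.sum()
    n_reads = int(round(depth * total / read_len_mean))
    probs = lengths / total

    reads: list[SequenceRecord] = []
    origins: dict[str, tuple[str, int, int, str]] = {}
    for i in range(n_reads):
        ci = int(rng.choice(len(genome), p=probs))
        chrom = genome[ci]
        length = int(np.clip(round(rng.normal(read_len_mean, read_len_sd)),
                             min_read_len, len(chrom.bases)))
        start = int(rng.integers(0, len(chrom.bases) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        bases = chrom.bases[start : start + length]
        if strand == "-":
            bases = reverse_complement(bases)
        if error_rate > 0:
            arr = list(bases)
            for pos in np.flatnonzero(rng.random(length) < error_rate):
                arr[pos] = _OTHER[arr[pos]][int(rng.integers(0, 3))]
            bases = "".join(arr)
        rid = f"{id_prefix}{i + 1:05d}"
        reads.append(SequenceRecord(rid, bases))
        origins[rid] = (chrom.id, start, start + length, strand)
    return reads, origins


def make_diploid(
    hap1: Sequence[SequenceRecord], params: DiploidParams
) -> list[SequenceRecord]:
    """Second haplotype by per-base substitution/insertion/deletion.

    Scanning each position at most one event fires: a deletion removes
    ``indel_len`` bases (and consumes them), an insertion adds
    ``indel_len`` random bases after the copied base, a substitution
    swaps the base.  Deterministic given ``params.seed``; chromosome ids
    gain a ``_hap2`` suffix.
    """
    rng = np.random.default_rng(params.seed)
    d, i_rate, s = params.del_rate, params.ins_rate, params.snp_rate
    out: list[SequenceRecord] = []
    for rec in hap1:
        bases = rec.bases
        u = rng.random(len(bases))
        parts: list[str] = []
        pos = 0
        while pos < len(bases):
            roll = u[pos]
            if roll < d:
                pos += params.indel_len
                continue
            if roll < d + i_rate:
                parts.append(bases[pos])
                parts.append(_random_bases(rng, params.indel_len))
            elif roll < d + i_rate + s:
                parts.append(_OTHER[bases[pos]][int(rng.integers(0, 3))])
            else:
                parts.append(bases[pos])
            pos += 1
        out.append(SequenceRecord(rec.id + "_hap2", "".join(parts)))
    return out


# ---------------------------------------------------------------------------
# toy aligner


def toy_align(
    queries: Sequence[SequenceRecord],
    targets: Sequence[SequenceRecord],
    k: int = 31,
    min_chain_bp: int = 500,
    max_gap: int = 20_000,
    max_occ: int = 50,
) -> list[AlignmentRecord]:
    """Exact k-mer anchor chaining, both strands, PAF-style output.

    Anchors are exact k-mer matches grouped per diagonal into maximal
    colinear segments; segments are chained when both query and target
    advance with gaps at most ``max_gap`` (so a chain can jump an
    excised region).  Chains whose query span reaches ``min_chain_bp``
    become alignment records with ``residue_matches`` equal to the
    anchor-covered query bases; the best chain per query is tagged
    ``tp:A:P``, the rest ``tp:A:S``.  Deterministic.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    index: dict[str, list[tuple[int, int]]] = {}
    for ti, t in enumerate(targets):
        bases = t.bases
        for p in range(len(bases) - k + 1):
            index.setdefault(bases[p : p + k], []).append((ti, p))

    records: list[AlignmentRecord] = []
    for q in queries:
        qlen = len(q.bases)
        per_query: list[AlignmentRecord] = []
        for strand in "+-":
            seq = q.bases if strand == "+" else reverse_complement(q.bases)
            segs: dict[tuple[int, int], list[int]] = {}
            for p in range(len(seq) - k + 1):
                hits = index.get(seq[p : p + k])
                if not hits or len(hits) > max_occ:
                    continue
                for ti, tp in hits:
                    key = (ti, tp - p)
                    s = segs.get(key)
                    if s is None:
                        segs[key] = [p, p + k, k]  # q_start, q_end, covered
                    else:
                        s[2] += k if p >= s[1] else p + k - s[1]
                        s[1] = p + k
            by_target: dict[int, list[tuple[int, int, int, int, int]]] = {}
            for (ti, diag), (qs, qe, cov) in segs.items():
                by_target.setdefault(ti, []).append((qs, qe, qs + diag, qe + diag, cov))
            for ti, seg_list in by_target.items():
                for chain in _extract_chains(seg_list, k, max_gap, min_chain_bp):
                    qs, qe, ts, te, cov = chain
                    if strand == "-":
                        qs, qe = qlen - qe, qlen - qs
                    span = max(qe - qs, te - ts)
                    per_query.append(
                        AlignmentRecord(
                            query_id=q.id,
                            query_len=qlen,
                            query_start=qs,
                            query_end=qe,
                            strand=strand,
                            target_id=targets[ti].id,
                            target_len=len(targets[ti].bases),
                            target_start=ts,
                            target_end=te,
                            residue_matches=min(cov, span),
                            block_len=span,
                            mapq=60,
                            tags={},
                        )
                    )
        if not per_query:
            continue
        per_query.sort(
            key=lambda a: (-a.residue_matches, a.target_id, a.target_start, a.strand)
        )
        for rank, rec in enumerate(per_query):
            rec.tags["tp"] = "P" if rank == 0 else "S"
            if rank > 0:
                rec.mapq = 0
            rec.validate()
        records.extend(per_query)
    return records


def _extract_chains(
    segs: list[tuple[int, int, int, int, int]],
    k: int,
    max_gap: int,
    min_chain_bp: int,
    max_chains: int = 50,
) -> list[tuple[int, int, int, int, int]]:
    """Repeatedly extract the best-scoring colinear chain of segments.

    Returns (q_start, q_end, t_start, t_end, covered) per chain with
    query span >= min_chain_bp.  Segments may overlap by up to k-1 bases
    at a junction (anchors straddling an indel)."""
    segs = sorted(segs)
    available = [True] * len(segs)
    chains: list[tuple[int, int, int, int, int]] = []
    slack = k - 1
    for _ in range(max_chains):
        order = [i for i in range(len(segs)) if available[i]]
        if not order:
            break
        score = {}
        prev = {}
        best_i, best_score = -1, -1
        for pos, i in enumerate(order):
            qs, qe, ts, te, cov = segs[i]
            score[i], prev[i] = cov, -1
            for j in order[:pos]:
                qs2, qe2, ts2, te2, cov2 = segs[j]
                if (
                    qs >= qe2 - slack
                    and ts >= te2 - slack
                    and qe > qe2
                    and te > te2
                    and qs - qe2 <= max_gap
                    and ts - te2 <= max_gap
                    and score[j] + cov > score[i]
                ):
                    score[i], prev[i] = score[j] + cov, j
            if score[i] > best_score:
                best_i, best_score = i, score[i]
        chain_idx = []
        i = best_i
        while i != -1:
            chain_idx.append(i)
            available[i] = False
            i = prev[i]
        chain_idx.reverse()
        first, last = segs[chain_idx[0]], segs[chain_idx[-1]]
        q_span = last[1] - first[0]
        if q_span >= min_chain_bp:
            cov = sum(segs[i][4] for i in chain_idx)
            chains.append((first[0], last[1], first[2], last[3], cov))
    return chains


# ---------------------------------------------------------------------------
# one-call fixture builder


@dataclass
class Fixture:
    """Everything the pipeline needs, plus the truth to judge it by."""

    truth: FixtureTruth
    chrom_assembly: list[SequenceRecord]
    contig_sets: list[list[SequenceRecord]]
    reads: list[SequenceRecord]
    dropped_genes: list[str]
    unsupported_genes: list[str] = field(default_factory=list)
    hap2: list[SequenceRecord] | None = None

    @property
    def catalog(self) -> MarkerCatalog:
        return self.truth.catalog


def make_fixture(
    seed: int,
    n_chrom: int = 2,
    chrom_len: int = 100_000,
    n_markers: int = 6,
    marker_len: int = 1_000,
    n_drop: int = 3,
    contig_margin_bp: int = 2_000,
    depth: float = 20.0,
    read_len_mean: int = 15_000,
    error_rate: float = 0.0,
    remove_support: bool = False,
    diploid: bool = False,
    diploid_params: DiploidParams | None = None,
) -> Fixture:
    """Standard planted-deletion scenario in one call.

    Drops ``n_drop`` randomly chosen markers.  With ``remove_support``
    the first dropped gene (lexicographically) loses its lost contig and
    every read overlapping its deletion — an unrecoverable gap, for
    partial-recovery accounting.  With ``diploid`` a mutated second
    haplotype is built and reads are drawn from both haplotypes at half
    depth each.
    """
    truth = generate_genome(n_chrom, chrom_len, n_markers, marker_len, seed)
    rng = np.random.default_rng(seed + 101)
    all_genes = sorted(truth.marker_loci)
    drop = sorted(rng.choice(all_genes, size=n_drop, replace=False).tolist())
    chrom_asm, contig_sets = degrade_assembly(
        truth, drop, contig_margin_bp=contig_margin_bp, seed=seed + 202
    )

    unsupported: list[str] = []
    if remove_support:
        unsupported = [drop[0]]
        contig_id = f"ctg_{drop[0]}"
        contig_sets = [
            [c for c in cs if c.id != contig_id] for cs in contig_sets
        ]

    if diploid:
        params = diploid_params or DiploidParams(seed=seed + 303)
        hap2 = make_diploid(truth.truth_genome, params)
        reads1, origins1 = simulate_reads(
            truth.truth_genome, depth=depth / 2, read_len_mean=read_len_mean,
            error_rate=error_rate, seed=seed + 404, id_prefix="h1read",
        )
        reads2, origins2 = simulate_reads(
            hap2, depth=depth / 2, read_len_mean=read_len_mean,
            error_rate=error_rate, seed=seed + 505, id_prefix="h2read",
        )
        reads = reads1 + reads2
        truth.read_origins = {**origins1, **origins2}
    else:
        hap2 = None
        reads, origins = simulate_reads(
            truth.truth_genome, depth=depth, read_len_mean=read_len_mean,
            error_rate=error_rate, seed=seed + 404,
        )
        truth.read_origins = origins

    if unsupported:
        removed = {
            d.chrom_id: (d.start, d.end)
            for d in truth.deletions
            if d.gene_ids == [unsupported[0]]
        }

        def touches_gap(rid: str) -> bool:
            chrom_id, start, end, _ = truth.read_origins[rid]
            base_chrom = chrom_id.removesuffix("_hap2")
            if base_chrom not in removed:
                return False
            g_start, g_end = removed[base_chrom]
            return min(end, g_end) > max(start, g_start)

        reads = [r for r in reads if not touches_gap(r.id)]
        truth.read_origins = {
            rid: o for rid, o in truth.read_origins.items()
            if rid in {r.id for r in reads}
        }

    return Fixture(
        truth=truth,
        chrom_assembly=chrom_asm,
        contig_sets=contig_sets,
        reads=reads,
        dropped_genes=drop,
        unsupported_genes=unsupported,
        hap2=hap2,
    )
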