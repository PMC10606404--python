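"""Phase 3: read recruitment, greedy overlap assembly, candidate selection."""

import numpy as np
import pytest

from contigrecall.io_formats import AlignmentRecord, SequenceRecord, reverse_complement
from contigrecall.locate import ChromosomeAnchor, MissingRegion
from contigrecall.markers import Marker, MarkerCatalog
from contigrecall.recall import (
    reads_overlapping_interval,
    recall_reads,
    select_candidate,
    toy_assemble,
)

from conftest import random_alignments


def _aln(query_id, t_start, t_end, target_id="ctg", target_len=10_000):
    return AlignmentRecord(
        query_id, 5_000, 0, min(5_000, t_end - t_start), "+", target_id,
        target_len, t_start, t_end, t_end - t_start, t_end - t_start, 60,
    )


class TestReadsOverlappingInterval:
    def test_partial_overlap_included(self):
        assert reads_overlapping_interval([_aln("r1", 0, 100)], "ctg", (50, 150)) == {"r1"}

    def test_touching_half_open_boundary_excluded(self):
        assert reads_overlapping_interval([_aln("r1", 0, 50)], "ctg", (50, 150)) == set()

    def test_min_overlap_threshold(self):
        alns = [_aln("r1", 0, 100)]
        assert reads_overlapping_interval(alns, "ctg", (50, 150), min_overlap_bp=50) == {"r1"}
        assert reads_overlapping_interval(alns, "ctg", (51, 150), min_overlap_bp=50) == set()

    def test_other_targets_ignored(self):
        assert (
            reads_overlapping_interval([_aln("r1", 0, 100, target_id="x")], "ctg", (0, 100))
            == set()
        )

    def test_matches_brute_force_overlap_scan(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            alns = random_alignments(rng, 200, [f"r{i}" for i in range(60)], ["t1", "t2"])
            start = int(rng.integers(0, 9_000))
            end = int(rng.integers(start + 1, 10_001))
            min_ov = int(rng.integers(1, 200))
            brute = {
                a.query_id
                for a in alns
                if a.target_id == "t1"
                and min(a.target_end, end) - max(a.target_start, start) >= min_ov
            }
            assert reads_overlapping_interval(alns, "t1", (start, end), min_ov) == brute


def _region(anchor=None, contig_len=1_000):
    return MissingRegion("ctg", contig_len, ["g1"], {"g1": (100, 300)}, anchor)


def _anchor(start=4_000, end=5_000, chrom_len=50_000):
    source = AlignmentRecord(
        "ctg", 1_000, 0, 1_000, "+", "chr1", chrom_len, start, end,
        end - start, end - start, 60,
    )
    return ChromosomeAnchor("chr1", start, end, "+", source)


def _reads(ids):
    return [SequenceRecord(rid, "ACGT") for rid in ids]


class TestRecallReads:
    def test_unanchored_region_uses_contig_source_only(self):
        to_contigs = [_aln(f"c{i}", 0, 500) for i in range(5)]
        to_chrom = [_aln(f"n{i}", 0, 500, target_id="chr1", target_len=50_000) for i in range(4)]
        reads = _reads([a.query_id for a in to_contigs + to_chrom])
        rset = recall_reads(_region(), to_contigs, to_chrom, reads)
        assert rset.read_ids == {f"c{i}" for i in range(5)}
        assert set(rset.provenance.values()) == {"contig"}

    def test_disjoint_sources_union(self):
        to_contigs = [_aln(f"c{i}", 0, 500) for i in range(5)]
        to_chrom = [_aln(f"n{i}", 4_000, 5_000, target_id="chr1", target_len=50_000) for i in range(7)]
        reads = _reads([a.query_id for a in to_contigs + to_chrom])
        rset = recall_reads(_region(anchor=_anchor()), to_contigs, to_chrom, reads)
        assert len(rset) == 12
        assert rset.provenance["c0"] == "contig"
        assert rset.provenance["n0"] == "chromosome_neighborhood"

    def test_read_in_both_sources_gets_both_provenance(self):
        to_contigs = [_aln("r1", 0, 500)]
        to_chrom = [_aln("r1", 4_000, 5_000, target_id="chr1", target_len=50_000)]
        rset = recall_reads(_region(anchor=_anchor()), to_contigs, to_chrom, _reads(["r1"]))
        assert rset.provenance == {"r1": "both"}

    def test_recalled_id_absent_from_read_set_is_an_error(self):
        with pytest.raises(ValueError, match="ghost"):
            recall_reads(_region(), [_aln("ghost", 0, 500)], [], [])

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(13)
        to_contigs = [_aln(f"c{i}", int(rng.integers(0, 900)), 1_000) for i in range(20)]
        to_chrom = [
            _aln(f"n{i}", int(rng.integers(0, 40_000)), 41_000, target_id="chr1",
                 target_len=50_000)
            for i in range(20)
        ]
        reads = _reads([a.query_id for a in to_contigs + to_chrom])
        base = recall_reads(_region(anchor=_anchor()), to_contigs, to_chrom, reads)
        shuffled = recall_reads(
            _region(anchor=_anchor()), to_contigs[::-1], to_chrom[::-1], reads[::-1]
        )
        assert [r.id for r in base.reads] == [r.id for r in shuffled.reads]
        assert base.provenance == shuffled.provenance

    def test_flank_growth_never_shrinks_the_set(self):
        rng = np.random.default_rng(17)
        to_chrom = [
            _aln(f"n{i}", int(rng.integers(0, 49_000)), int(rng.integers(49_000, 50_000)),
                 target_id="chr1", target_len=50_000)
            for i in range(30)
        ]
        reads = _reads([a.query_id for a in to_chrom])
        previous: set = set()
        for flank in (0, 1_000, 10_000, 60_000):
            rset = recall_reads(_region(anchor=_anchor()), [], to_chrom, reads, flank_bp=flank)
            assert previous <= rset.read_ids
            previous = rset.read_ids

    def test_all_reads_from_inside_a_deletion_are_recalled(
        self, haploid_fixture, haploid_result
    ):
        fx = haploid_fixture
        recalled_any = set()
        from contigrecall.recall import recall_reads as rr

        for region in haploid_result.regions:
            rset = rr(
                region,
                haploid_result.alignments["reads_to_contigs"],
                haploid_result.alignments["reads_to_chrom"],
                fx.reads,
            )
            recalled_any |= rset.read_ids
        for deletion in fx.truth.deletions:
            inside = {
                rid
                for rid, (chrom, start, end, _) in fx.truth.read_origins.items()
                if chrom == deletion.chrom_id
                and start >= deletion.start
                and end <= deletion.end
            }
            assert inside <= recalled_any


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestToyAssembler:
    def test_exact_overlap_merge_arithmetic(self):
        rng = np.random.default_rng(21)
        truth = _random_seq(rng, 3_000)
        r1, r2 = truth[:1_800], truth[1_200:]  # 600 bp overlap
        (merged,) = toy_assemble(
            [SequenceRecord("a", r1), SequenceRecord("b", r2)], min_olap=500
        )
        assert len(merged.bases) == len(r1) + len(r2) - 600
        assert merged.bases == truth

    def test_single_read_is_a_fixed_point(self):
        read = SequenceRecord("only", "ACGT" * 300)
        assert toy_assemble([read]) == [read]

    def test_reverse_strand_partner_is_merged(self):
        rng = np.random.default_rng(22)
        truth = _random_seq(rng, 3_000)
        r1 = truth[:1_800]
        r2 = reverse_complement(truth[1_200:])
        (merged,) = toy_assemble(
            [SequenceRecord("a", r1), SequenceRecord("b", r2)], min_olap=500
        )
        assert truth in merged.bases or reverse_complement(truth) in merged.bases

    def test_below_min_overlap_stays_unmerged(self):
        rng = np.random.default_rng(23)
        truth = _random_seq(rng, 2_000)
        # 200 bp shared, below the 500 bp floor: both reads survive
        reads = [SequenceRecord("a", truth[:1_100]), SequenceRecord("b", truth[900:])]
        assert len(toy_assemble(reads, min_olap=500)) == 2

    def test_contained_read_is_absorbed(self):
        rng = np.random.default_rng(24)
        truth = _random_seq(rng, 3_000)
        reads = [SequenceRecord("big", truth), SequenceRecord("small", truth[800:1_600])]
        (merged,) = toy_assemble(reads, min_olap=500)
        assert merged.bases == truth

    def test_tiling_reads_reconstruct_the_truth_segment(self):
        rng = np.random.default_rng(25)
        truth = _random_seq(rng, 20_000)
        reads = []
        starts = list(range(0, 20_000 - 1_500, 250))  # ~6x coverage, 1.25 kb overlaps
        for i, start in enumerate(starts):
            end = min(start + 1_500, 20_000)
            bases = truth[start:end]
            if i % 3 == 2:
                bases = reverse_complement(bases)
            reads.append(SequenceRecord(f"r{i:03d}", bases))
        reads.append(SequenceRecord("last", truth[18_600:]))
        candidates = toy_assemble(reads, min_olap=500)
        assert any(
            truth in c.bases or reverse_complement(truth) in c.bases
            for c in candidates
        )

    def test_deterministic_output(self):
        rng = np.random.default_rng(26)
        truth = _random_seq(rng, 10_000)
        reads = [
            SequenceRecord(f"r{i}", truth[s : s + 2_000])
            for i, s in enumerate(range(0, 8_200, 400))
        ]
        first = toy_assemble(reads)
        second = toy_assemble(list(reversed(reads)))
        assert [(c.bases) for c in first] == [(c.bases) for c in second]


class TestSelectCandidate:
    @pytest.fixture()
    def catalog(self):
        rng = np.random.default_rng(31)
        return MarkerCatalog([Marker("g1", _random_seq(rng, 300))])

    def test_candidate_with_intact_gene_selected_with_interval(self, catalog):
        rng = np.random.default_rng(32)
        marker = catalog.get("g1").bases
        cand = SequenceRecord("c1", _random_seq(rng, 500) + marker + _random_seq(rng, 500))
        chosen = select_candidate([cand], "g1", catalog)
        assert chosen is not None
        assert chosen.record.id == "c1"
        assert chosen.gene_interval == (500, 800)

    def test_no_candidate_with_gene_means_failed_recall(self, catalog):
        rng = np.random.default_rng(33)
        assert (
            select_candidate([SequenceRecord("c1", _random_seq(rng, 1_000))], "g1", catalog)
            is None
        )

    def test_longest_qualifying_candidate_wins(self, catalog):
        rng = np.random.default_rng(34)
        marker = catalog.get("g1").bases
        with_gene_short = SequenceRecord("a", marker + _random_seq(rng, 100))
        with_gene_long = SequenceRecord("b", _random_seq(rng, 400) + marker)
        without = SequenceRecord("c", _random_seq(rng, 5_000))
        chosen = select_candidate([with_gene_short, with_gene_long, without], "g1", catalog)
        assert chosen.record.id == "b"

    def test_matches_brute_force_filter_and_argmax(self, catalog):
        rng = np.random.default_rng(35)
        marker = catalog.get("g1").bases
        for _ in range(10):
            candidates = []
            for i in range(5):
                bases = _random_seq(rng, int(rng.integers(400, 2_000)))
                if rng.random() < 0.5:
                    pos = int(rng.integers(0, len(bases)))
                    bases = bases[:pos] + marker + bases[pos:]
                candidates.append(SequenceRecord(f"c{i}", bases))
            brute_pool = [c for c in candidates if marker in c.bases]
            # exclude accidental duplicates of the marker (scan requires exactly one)
            brute_pool = [c for c in brute_pool if c.bases.count(marker) == 1]
            expected = (
                sorted(brute_pool, key=lambda c: (-len(c.bases), c.id))[0]
                if brute_pool
                else None
            )
            chosen = select_candidate(candidates, "g1", catalog)
            if expected is None:
                assert chosen is None
            else:
                assert chosen.record.id == expected.id

    def test_never_returns_non_complete_candidate(self, catalog):
        rng = np.random.default_rng(36)
        marker = catalog.get("g1").bases
        fragment = marker[: len(marker) // 2]  # Fragmented, not Complete
        cand = SequenceRecord("c1", _random_seq(rng, 200) + fragment + _random_seq(rng, 200))
        assert select_candidate([cand], "g1", catalog) is None
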