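"""Generators and the k-mer chain aligner: determinism, statistics, oracles."""

import math

import numpy as np
import pytest

from contigrecall.io_formats import SequenceRecord, reverse_complement, parse_paf, write_paf
from contigrecall.markers import toy_marker_scan
from contigrecall.synthetic import (
    DiploidParams,
    degrade_assembly,
    generate_genome,
    make_diploid,
    simulate_reads,
    toy_align,
)


class TestGenerateGenome:
    def test_all_planted_markers_scan_complete(self):
        truth = generate_genome(2, 100_000, 6, 1_000, seed=1)
        table = toy_marker_scan(truth.truth_genome, truth.catalog)
        assert all(table.status_of(m.gene_id) == "Complete" for m in truth.catalog)
        for gene, (chrom, start, end, strand) in truth.marker_loci.items():
            hit = table.by_gene[gene][0]
            assert (hit.sequence_id, hit.start, hit.end) == (chrom, start, end)

    def test_no_markers_gives_plain_random_genome(self):
        truth = generate_genome(1, 50_000, 0, 1_000, seed=2)
        assert len(truth.catalog) == 0
        assert len(truth.truth_genome[0].bases) == 50_000

    def test_same_seed_is_byte_identical(self):
        a = generate_genome(2, 60_000, 4, 500, seed=3)
        b = generate_genome(2, 60_000, 4, 500, seed=3)
        assert [r.bases for r in a.truth_genome] == [r.bases for r in b.truth_genome]
        assert [m.bases for m in a.catalog] == [m.bases for m in b.catalog]

    def test_impossible_placement_errors(self):
        with pytest.raises(ValueError):
            generate_genome(1, 30_000, 10, 1_000, seed=4)


class TestDegradeAssembly:
    @pytest.fixture()
    def truth(self):
        return generate_genome(2, 100_000, 6, 1_000, seed=5)

    def test_excision_shortens_by_marker_plus_margins(self, truth):
        gene = sorted(truth.marker_loci)[0]
        chrom_id = truth.marker_loci[gene][0]
        before = len(truth.chrom(chrom_id).bases)
        degraded, _ = degrade_assembly(truth, [gene], contig_margin_bp=2_000)
        after = len(next(r for r in degraded if r.id == chrom_id).bases)
        assert before - after == 1_000 + 2 * 2_000

    def test_scan_statuses_flip_as_expected(self, truth):
        gene = sorted(truth.marker_loci)[0]
        degraded, contig_sets = degrade_assembly(truth, [gene])
        merged = [c for cs in contig_sets for c in cs]
        assert toy_marker_scan(degraded, truth.catalog).status_of(gene) == "Missing"
        assert toy_marker_scan(merged, truth.catalog).status_of(gene) == "Complete"

    def test_n_fill_preserves_length_and_loses_the_marker(self, truth):
        gene = sorted(truth.marker_loci)[0]
        chrom_id = truth.marker_loci[gene][0]
        degraded, _ = degrade_assembly(truth, [gene], gap_char_policy="n_fill")
        chrom = next(r for r in degraded if r.id == chrom_id)
        assert len(chrom.bases) == len(truth.chrom(chrom_id).bases)
        assert toy_marker_scan(degraded, truth.catalog).status_of(gene) == "Missing"

    def test_empty_drop_list_is_identity(self, truth):
        degraded, contig_sets = degrade_assembly(truth, [])
        assert [r.bases for r in degraded] == [r.bases for r in truth.truth_genome]
        assert all(len(cs) == 0 for cs in contig_sets)

    def test_lost_contigs_are_true_source_segments(self, truth):
        genes = sorted(truth.marker_loci)[:3]
        _, contig_sets = degrade_assembly(truth, genes)
        merged = {c.id: c for cs in contig_sets for c in cs}
        for contig_id, (chrom_id, start, end) in truth.lost_contigs.items():
            assert merged[contig_id].bases == truth.chrom(chrom_id).bases[start:end]

    def test_unknown_gene_errors(self, truth):
        with pytest.raises(ValueError):
            degrade_assembly(truth, ["nonexistent"])


class TestSimulateReads:
    def test_total_bases_near_depth_times_genome_length(self):
        truth = generate_genome(1, 200_000, 0, 1_000, seed=6)
        reads, _ = simulate_reads(truth.truth_genome, depth=20, seed=6)
        total = sum(len(r.bases) for r in reads)
        n = len(reads)
        # lengths are Normal(15000, 1500) clamped; 3 standard errors
        se = 1_500 * math.sqrt(n)
        assert abs(total - 20 * 200_000) <= 3 * se + 15_000

    def test_error_free_reads_are_exact_substrings(self):
        truth = generate_genome(1, 50_000, 0, 1_000, seed=7)
        reads, origins = simulate_reads(truth.truth_genome, depth=5, seed=7)
        genome = truth.truth_genome[0].bases
        for read in reads:
            chrom, start, end, strand = origins[read.id]
            expected = genome[start:end]
            if strand == "-":
                expected = reverse_complement(expected)
            assert read.bases == expected

    def test_error_rate_perturbs_reads(self):
        truth = generate_genome(1, 50_000, 0, 1_000, seed=8)
        clean, _ = simulate_reads(truth.truth_genome, depth=2, error_rate=0.0, seed=8)
        noisy, origins = simulate_reads(truth.truth_genome, depth=2, error_rate=0.01, seed=8)
        genome = truth.truth_genome[0].bases
        mismatches = 0
        for read in noisy:
            chrom, start, end, strand = origins[read.id]
            ref = genome[start:end]
            if strand == "-":
                ref = reverse_complement(ref)
            mismatches += sum(a != b for a, b in zip(read.bases, ref))
        total = sum(len(r.bases) for r in noisy)
        assert 0.005 < mismatches / total < 0.02

    def test_same_seed_identical_reads(self):
        truth = generate_genome(1, 50_000, 0, 1_000, seed=9)
        a, _ = simulate_reads(truth.truth_genome, depth=3, seed=11)
        b, _ = simulate_reads(truth.truth_genome, depth=3, seed=11)
        assert [r.bases for r in a] == [r.bases for r in b]


class TestMakeDiploid:
    @pytest.fixture()
    def hap1(self):
        return generate_genome(1, 100_000, 0, 1_000, seed=10).truth_genome

    def test_zero_rates_are_identity(self, hap1):
        params = DiploidParams(snp_rate=0, ins_rate=0, del_rate=0, seed=1)
        hap2 = make_diploid(hap1, params)
        assert hap2[0].bases == hap1[0].bases
        assert hap2[0].id == hap1[0].id + "_hap2"

    def test_substitution_count_is_binomial(self, hap1):
        params = DiploidParams(snp_rate=0.02, ins_rate=0, del_rate=0, seed=2)
        hap2 = make_diploid(hap1, params)
        assert len(hap2[0].bases) == len(hap1[0].bases)
        subs = sum(a != b for a, b in zip(hap1[0].bases, hap2[0].bases))
        n, p = len(hap1[0].bases), 0.02
        se = math.sqrt(n * p * (1 - p))
        assert abs(subs - n * p) <= 3 * se

    def test_length_matches_expectation_at_standard_rates(self, hap1):
        # substitution, insertion and deletion each at 0.02, indel length 12
        params = DiploidParams(seed=3)
        hap2 = make_diploid(hap1, params)
        length = len(hap1[0].bases)
        # positions are consumed by deletions, so ins and del events each
        # realize at rate r * scanned, scanned = L / (1 + (indel_len-1)*d)
        scanned = length / (1 + (params.indel_len - 1) * params.del_rate)
        expected = length + params.indel_len * scanned * (params.ins_rate - params.del_rate)
        n_events = scanned * (params.ins_rate + params.del_rate)
        se = params.indel_len * math.sqrt(n_events)
        assert abs(len(hap2[0].bases) - expected) <= 3 * se

    def test_same_seed_identical_haplotype(self, hap1):
        params = DiploidParams(seed=4)
        assert make_diploid(hap1, params)[0].bases == make_diploid(hap1, params)[0].bases


class TestToyAlign:
    def _seq(self, rng, n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    def test_exact_containment_fully_recovered(self):
        rng = np.random.default_rng(70)
        target = SequenceRecord("t", self._seq(rng, 30_000))
        query = SequenceRecord("q", target.bases[5_000:10_000])
        records = toy_align([query], [target])
        assert len(records) == 1
        rec = records[0]
        assert (rec.target_start, rec.target_end) == (5_000, 10_000)
        assert (rec.query_start, rec.query_end) == (0, 5_000)
        assert rec.residue_matches == 5_000
        assert rec.strand == "+" and rec.tags["tp"] == "P"

    def test_reverse_complement_query_maps_minus_strand(self):
        rng = np.random.default_rng(71)
        target = SequenceRecord("t", self._seq(rng, 20_000))
        query = SequenceRecord("q", reverse_complement(target.bases[4_000:9_000]))
        (rec,) = toy_align([query], [target])
        assert rec.strand == "-"
        assert (rec.target_start, rec.target_end) == (4_000, 9_000)

    def test_no_shared_kmer_no_record(self):
        rng = np.random.default_rng(72)
        target = SequenceRecord("t", self._seq(rng, 10_000))
        query = SequenceRecord("q", self._seq(rng, 2_000))
        assert toy_align([query], [target]) == []

    def test_chain_jumps_an_excised_gap(self):
        rng = np.random.default_rng(73)
        full = self._seq(rng, 20_000)
        # target lacks the middle 5 kb, as after an excision
        target = SequenceRecord("t", full[:7_500] + full[12_500:])
        query = SequenceRecord("q", full)
        recs = toy_align([query], [target])
        primary = next(r for r in recs if r.tags["tp"] == "P")
        assert primary.query_start < 100 and primary.query_end > 19_900
        assert primary.target_end - primary.target_start == pytest.approx(15_000, abs=100)

    def test_planted_queries_match_substring_oracle(self):
        rng = np.random.default_rng(74)
        target = SequenceRecord("t", self._seq(rng, 50_000))
        queries, expected = [], {}
        for i in range(20):
            start = int(rng.integers(0, 48_000))
            length = int(rng.integers(600, 2_000))
            end = min(50_000, start + length)
            qid = f"q{i:02d}"
            queries.append(SequenceRecord(qid, target.bases[start:end]))
            expected[qid] = (target.bases.find(target.bases[start:end]), end - start)
        records = toy_align(queries, [target])
        primaries = {r.query_id: r for r in records if r.tags["tp"] == "P"}
        for qid, (found_at, length) in expected.items():
            rec = primaries[qid]
            assert rec.target_start == found_at
            assert rec.target_end - rec.target_start == length

    def test_output_round_trips_through_paf(self, tmp_path):
        rng = np.random.default_rng(75)
        target = SequenceRecord("t", self._seq(rng, 20_000))
        queries = [
            SequenceRecord("a", target.bases[1_000:4_000]),
            SequenceRecord("b", reverse_complement(target.bases[9_000:12_000])),
        ]
        records = toy_align(queries, [target])
        for rec in records:
            rec.validate()
        p = tmp_path / "toy.paf"
        write_paf(records, p)
        assert parse_paf(p) == records

    def test_deterministic(self):
        rng = np.random.default_rng(76)
        target = SequenceRecord("t", self._seq(rng, 20_000))
        queries = [SequenceRecord("a", target.bases[2_000:8_000])]
        assert toy_align(queries, [target]) == toy_align(queries, [target])
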