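"""What the synthetic-data generator produces, piece by piece.

Generates a truth genome with planted markers, degrades it, simulates
reads, and builds a mutated second haplotype, printing the realized
statistics next to their expectations.
"""

from contigrecall.markers import toy_marker_scan
from contigrecall.synthetic import (
    DiploidParams,
    degrade_assembly,
    generate_genome,
    make_diploid,
    simulate_reads,
)

truth = generate_genome(n_chrom=2, chrom_len=100_000, n_markers=6, marker_len=1_000, seed=7)
table = toy_marker_scan(truth.truth_genome, truth.catalog)
print("markers complete on truth genome:",
      sum(table.status_of(m.gene_id) == "Complete" for m in truth.catalog), "/ 6")

genes = sorted(truth.marker_loci)[:3]
degraded, contig_sets = degrade_assembly(truth, genes)
chrom_table = toy_marker_scan(degraded, truth.catalog)
print("after excising", genes, "->",
      sorted(g for g in truth.marker_loci if chrom_table.status_of(g) == "Missing"),
      "are missing on chromosomes")
print("lost contigs per set:", [len(cs) for cs in contig_sets],
      "(distributed so each marker stays single-copy in the merged set)")

reads, origins = simulate_reads(truth.truth_genome, depth=20, seed=7)
total = sum(len(r.bases) for r in reads)
print(f"reads: {len(reads)}, total bases {total} "
      f"(expected {20 * 200_000} at depth 20 on 200 kb)")

hap2 = make_diploid(truth.truth_genome, DiploidParams(seed=7))
print("hap2 lengths:", [len(r.bases) for r in hap2],
      "(substitution/insertion/deletion each at 0.02 per base, 12 bp indels;"
      " insertions and deletions balance in expectation)")
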