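"""End-to-end gap filling on a synthetic planted-deletion fixture.

Builds a two-chromosome truth genome with six unique 1 kb marker genes,
excises three of them (with 2 kb margins) from the chromosome assembly
while keeping the excised segments as lost contigs, simulates depth-20
error-free long reads, and runs all four pipeline phases with the
built-in toy adapters.
"""

from contigrecall import fill_assembly, make_fixture, merge_contig_sets

fixture = make_fixture(seed=1)
print(f"dropped genes: {fixture.dropped_genes}")
print(f"reads simulated: {len(fixture.reads)}")

result = fill_assembly(
    fixture.chrom_assembly,
    merge_contig_sets(fixture.contig_sets),
    fixture.reads,
    fixture.catalog,
)

s = result.summary
print(f"\nfillable genes found: {s['fillable_genes']}")
print(f"missing single-copy genes: {s['missing_before']} -> {s['missing_after']}")
print(f"replacements: {s['replacements']}")
print(f"no-regression check passed: {s['regression_ok']}")

# compare every filled interval against the truth genome
truth = {r.id: r.bases for r in fixture.truth.truth_genome}
final = {r.id: r.bases for r in result.assembly}
for deletion in fixture.truth.deletions:
    segment = truth[deletion.chrom_id][deletion.start - 1000 : deletion.end + 1000]
    ok = segment in final[deletion.chrom_id]
    print(f"  {deletion.gene_ids} on {deletion.chrom_id}: restored exactly = {ok}")

# A drop from 3 to 0 missing genes with every interval restored verbatim
# means the recall-and-splice cycle reproduced the lost sequence, not
# merely something marker-bearing.
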