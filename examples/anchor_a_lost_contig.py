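"""How a lost contig is anchored back onto a chromosome.

Excises one marker locus from a chromosome, aligns the lost contig
(which retains flanking sequence on both sides of the cut) against the
degraded chromosome with the k-mer chain aligner, and shows the chosen
anchor interval bracketing the excision point.
"""

from contigrecall.locate import select_anchor_alignment
from contigrecall.synthetic import degrade_assembly, generate_genome, toy_align

truth = generate_genome(n_chrom=1, chrom_len=100_000, n_markers=2, marker_len=1_000, seed=11)
gene = sorted(truth.marker_loci)[0]
degraded, contig_sets = degrade_assembly(truth, [gene])
contig = [c for cs in contig_sets for c in cs][0]
print(f"lost contig {contig.id}: {len(contig.bases)} bp "
      f"(the excised locus plus retained flanks)")

alignments = toy_align([contig], degraded)
for a in alignments:
    print(f"  chain {a.query_start}-{a.query_end} -> {a.target_id}:"
          f"{a.target_start}-{a.target_end} ({a.strand}), "
          f"{a.residue_matches} matched bases, tp:{a.tags['tp']}")

anchor = select_anchor_alignment(contig.id, alignments)
deletion = truth.deletions[0]
shift = 0  # single deletion: degraded coordinate of the cut equals its start
cut = deletion.start - shift
print(f"\nanchor: {anchor.chrom_id}:{anchor.start}-{anchor.end} ({anchor.strand})")
print(f"true excision point in degraded coordinates: {cut}")
print(f"anchor brackets the cut: {anchor.start <= cut <= anchor.end}")
# The chain jumps the excised gap: the contig's two flanks are adjacent on
# the degraded chromosome, so one colinear chain covers both.
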