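# Methods

## Problem and model

A chromosome-level assembly `C` and a merged contig set `K` (contigs
from one or more assemblers, possibly overlapping) are assessed with a
single-copy ortholog catalog. Writing `M(X)` for the genes Missing on
`X` and `C1(X)` for the genes Complete with exactly one locus, the
fillable set is

```
F = M(C) ∩ C1(K)
```

Each `g ∈ F` identifies one lost contig (its host in `K`); the whole
contig — not just the gene interval — is treated as the missing region,
because the point of the subsequent read recall is to recover the
complete neighborhood, including flanks needed for anchoring and
junction-spanning reads. Requiring status *exactly Complete* in `K`
(not Duplicated, not Fragmented) keeps the gene's location unambiguous;
genes Fragmented on the chromosomes are not fillable by default
(`include_fragmented` widens this) since a fragmented locus is a
different repair problem than an absent one.

The repair per region is: recall reads from two sources (the lost
contig; the anchor neighborhood on the chromosome, padded by `flank_bp`
per side), assemble the union, select per gene the longest candidate on
which the gene is intact, align that candidate back to the chromosomes,
and splice it in if the alignment is trustworthy. A final assessor pass
enforces monotonicity: no gene's status may move down the
Complete > Duplicated > Fragmented > Missing lattice, and the Missing
count may not increase; otherwise the edited assembly is withheld.

## Tunable parameters

| parameter | default | meaning and rationale |
| --- | --- | --- |
| `flank_bp` | 50 000 bp | chromosome neighborhood padded around the anchor during read recall. Must exceed a read length so junction-spanning reads are captured; recall is monotone in this value. |
| `min_anchor_matches` | 500 bp | residue-match floor for accepting a contig-to-chromosome anchor. A floor prevents spurious placements; contigs below it are processed unanchored (contig-side recall only). |
| `min_overlap_bp` | 1 bp | minimum alignment overlap for recalling a read. Permissive on purpose — recall should be complete; the assembler resolves noise. |
| `min_query_coverage` | 0.8 | fraction of the candidate that its chromosome alignment must span before splicing. Guards against splicing in a candidate that aligns only by a repeat arm. |
| `assembler_min_olap` | 500 bp | minimum exact suffix–prefix overlap for the built-in greedy assembler. |

Replacement span is the chosen alignment's **target interval**, not the
whole anchor: the local alignment defines the corresponding sequence,
and over-replacement would risk deleting correct flanking bases.
Candidate re-alignment is restricted to the anchor neighborhood when an
anchor exists and falls back to genome-wide otherwise.

## Processing order and conflicts

Genes are processed in ascending (chromosome id, anchor start) order,
unanchored genes last, lexicographic ids as the final tie-break — a
positional order that makes conflict handling deterministic. When two
applied splices on one chromosome overlap, the later one (in that
order) is demoted to `skipped_overlap` rather than aborting the run:
gene-by-gene partial success, with the demotion logged and the final
assessment deciding whether the gene was nevertheless recovered (it
usually is, because the earlier splice covered both loci). Offsets are
tracked in an edit ledger so that any untouched pre-edit locus maps to
its post-edit coordinate; `EditLedger.map_position` returns `None`
inside a replaced interval.

All failure modes of replacement planning are statuses, not exceptions:
`skipped_no_alignment`, `skipped_low_coverage`, and
`skipped_gene_outside_alignment` — the last being the known failure
mode where the gene falls outside the aligned region and the gap
remains unfilled.

## Built-in desk-scale adapters

* **Marker scanner** — exact substring search, both strands. Complete =
  exactly one occurrence genome-wide; Duplicated = more; Fragmented = a
  contiguous marker substring of ≥ `min_fragment_fraction` (default
  0.5) of the marker length occurs (longest such fragment found by
  binary search over window lengths); else Missing. Exact matching is
  correct on the noise-free fixtures; real data goes through the
  assessor adapter.
* **Aligner** — exact k-mer anchors (k = 31) on both strands, grouped
  per diagonal into maximal segments, segments chained colinearly with
  per-gap ceiling `max_gap` (20 kb), so one chain jumps an excised
  region and the anchor interval brackets the cut. `residue_matches` is
  the anchor-covered query length; best chain per query is tagged
  `tp:A:P`. K-mers occurring more than 50 times in the target are
  ignored (repeat guard).
* **Assembler** — greedy merging by maximal exact suffix–prefix
  overlap, both strands, deterministic seed order (longest sequence,
  then lexicographic id); contained sequences are absorbed. On
  error-free reads with contiguous coverage and true overlaps above the
  floor it reconstructs the source segment exactly; it is intentionally
  unusable for real error profiles, for which the external assembler
  adapter exists.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* of the evaluation scenario:
uniform-random chromosomes with unique random marker sequences planted
at interior, well-separated loci (verified single-copy genome-wide);
degradation by excising each dropped marker locus ± 2 kb; the excised
segment ± another margin (plus boundary jitter) surviving as a lost
contig so that it shares anchorable flanks with the chromosome; long
reads at depth 20 with Normal(15 kb, 1.5 kb) lengths, random strand,
optional per-base substitution errors, and recorded origins; and a
second haplotype mutated per base at substitution/insertion/deletion
rates of 0.02 each with 12 bp indels. Lost contigs are distributed
round-robin across the ≥ 2 contig sets (boundaries jittered per
contig): emitting every contig into every set would make each dropped
marker Duplicated in the merged set and thus ineligible under the
exact-Complete rule, which is not the situation the method addresses.

Deliberately **not** emulated: realistic repeat landscapes and
centromere/telomere structure, base-quality emission, the multi-pass
CLR→CCS consensus process behind real HiFi reads (only the depth
parameter is matched), and real ortholog models (markers are random
sequences, which is what makes the exact scanner a valid oracle).
Passing tests therefore demonstrate the correctness of the pipeline's
logic — set difference, anchoring, recall completeness, splice
coordinate handling, regression guarding — on clean signals; they say
nothing about assembler robustness to sequencing error or about
HMM-based ortholog detection, which are delegated to external tools.

In the diploid scenario the chromosome assembly and contigs derive from
haplotype 1; haplotype 2 reads mostly fail the 31-mer chain threshold
against hap1 sequence (mutations every ~17 bp on average break most
k-mers), so they contribute little to recall and never win candidate
selection — the run must simply complete without regression.

## Numerical and degenerate-input choices

* All in-memory coordinates are 0-based half-open; conversion to the
  1-based inclusive table dialect happens only at the full_table
  parse/serialize boundary. PAF is 0-based half-open on disk already.
* A gene listed Complete more than once in an assessor table is
  reclassified Duplicated at parse time, making "Complete" synonymous
  with "unambiguous locus" everywhere downstream.
* Anchor/candidate/alignment argmax ties break by (block length,
  lexicographic target id, leftmost target start), making every
  selection a pure function of its inputs.
* Zero fillable genes short-circuits the pipeline into a byte-identical
  no-op (and makes a rerun on its own output idempotent).
* Reads recalled by id, not by sequence: simulated and real read ids
  are unique, and sequence-level deduplication would merge legitimate
  twins.
* Fixture scale (2 × 100 kb chromosomes, six 1 kb markers, three
  deletions, depth 20) was chosen as the smallest configuration in
  which every moving part is exercised — multiple regions per
  chromosome, anchored and unanchored paths, overlap demotion — while a
  full pipeline run stays in the tens of seconds.

## Known limitations

* Regions without a single-copy marker are invisible to the method by
  construction.
* One anchor per contig: chimeric (split-aligning) contigs are anchored
  to their single best placement only, with the event logged.
* The whole-contig region definition plus a large default flank means
  recall windows on small test genomes can span most of a chromosome;
  on real genomes (Mb-scale chromosomes, kb-scale contigs) the windows
  are local.
* Spliced junctions are not polished; the final no-regression check is
  the only post-edit validation.
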