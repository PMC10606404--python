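# contig-recall

Chromosome-level genome assemblies routinely lose sequence: scaffolding
keeps the long contigs and silently drops small ones, so the final
chromosomes miss regions that the underlying read data actually covers.
`contig-recall` finds and repairs such gaps by using **single-copy marker
genes** (BUSCO-style orthologs, expected exactly once per haploid genome)
as anchors: a gene that is *Missing* on the chromosomes but *Complete* in
a merged contig set pinpoints a lost contig, and the sequence around it
can be rebuilt from the raw long reads and spliced back in.

The tool is aimed at people finishing plant or animal genome assemblies
from PacBio HiFi-class reads who want to squeeze the last few missing
single-copy genes out of an otherwise complete chromosome build.

## The algorithm

Four phases, each with a clean library surface:

1. **Prepare** — run a completeness assessor on the chromosome assembly
   and on the merged contig set (contigs from several assemblers are
   merged; colliding ids get set prefixes). The fillable gene list is the
   set difference: genes Missing on chromosomes ∩ Complete (exactly one
   locus) in contigs.
2. **Locate** — each fillable gene maps to its host contig; the *whole
   contig* is the missing region. The contig is anchored to a chromosome
   interval by its best contig-to-chromosome alignment (argmax of residue
   matches among primary alignments, with a 500 bp match floor).
3. **Recall** — reads aligning to the lost contig and reads aligning to
   the anchor's chromosome neighborhood (± `flank_bp`, default 50 kb) are
   merged and reassembled. Among the assembled candidates, the one where
   the target gene is intact (and longest) is selected per gene.
4. **Replace** — the candidate is aligned back to the chromosomes; the
   splice happens only when the alignment covers ≥ 80 % of the candidate
   and the gene lies inside the aligned span. An edit ledger tracks every
   coordinate shift, and a final assessor run verifies that **no gene's
   status regresses** — otherwise the edited assembly is withheld.

External tools (minimap2-style aligner, hifiasm/hiCanu-style assembler,
BUSCO-style assessor) plug in through command-template adapters.
Deterministic built-in "toy" equivalents — an exact-substring marker
scanner, an exact k-mer chain aligner, and a greedy maximal
suffix–prefix overlap assembler — make the whole pipeline runnable and
testable at desk scale on the synthetic fixtures, with no downloads.

## Worked example

`examples/fill_synthetic_assembly.py` builds a truth-tracked fixture
(2 × 100 kb chromosomes, six planted 1 kb markers, three excised with
2 kb margins, error-free depth-20 reads) and runs all four phases:

```
dropped genes: ['gene001', 'gene002', 'gene004']
reads simulated: 267

fillable genes found: ['gene001', 'gene002', 'gene004']
missing single-copy genes: 3 -> 0
replacements: {'applied': 2, 'skipped_no_alignment': 0, 'skipped_gene_outside_alignment': 0, 'skipped_low_coverage': 0, 'skipped_overlap': 1}
no-regression check passed: True
  ['gene001'] on chr1: restored exactly = True
  ['gene002'] on chr2: restored exactly = True
  ['gene004'] on chr2: restored exactly = True
```

All three planted deletions are recovered and each filled interval is
byte-identical to the truth genome. (The `skipped_overlap` entry is the
bookkeeping for two genes on the same chromosome whose recall windows
overlap: the first splice already restored both, so the second is
demoted rather than applied twice — and the final assessment confirms
both genes present.) The other examples walk the generator
(`simulate_fixture.py`) and the anchoring step
(`anchor_a_lost_contig.py`).

From a shell, the same run is:

```bash
contig-recall simulate --out fx --seed 1
contig-recall run --chrom-asm fx/chrom_asm.fasta \
    --contigs fx/contigs_set1.fasta --contigs fx/contigs_set2.fasta \
    --reads fx/reads.fastq --catalog fx/catalog.fasta --out filled
```

which writes `filled/filled_assembly.fasta`, a `summary.json`, the edit
ledger (TSV + JSON), region reports (BED + JSON) and all intermediate
alignments (PAF). `prepare`, `locate`, `recall` and `replace` expose the
phases individually.

## Layout

```
src/contigrecall/   io_formats, markers, locate, recall, replace,
                    synthetic, pipeline, adapters, config, cli
tests/              unit, property and end-to-end suites
examples/           narrative scripts, one per capability
docs/methods.md     models, parameters, design choices, limitations
```
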