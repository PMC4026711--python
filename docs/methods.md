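# Methods

This note documents the models, conventions and numerical choices behind
`rrbsim`, and what the synthetic data can and cannot say about real
experiments.

## Genome and feature model

Chromosome sequence is i.i.d. over {A, C, G, T} with P(C) = P(G) = gc/2
(default `background_gc` = 0.42), which gives a background CpG rate of
(gc/2)² per dinucleotide (~4.4 per 100 bp at the default). Three feature
classes are layered on top:

* **Genes** (default 20 × 2 kb) are annotation only; their sequence is
  whatever lies under them. Promoters are never stored: they are derived
  at analysis time as the `promoter_length_bp` (default 2,000) interval
  immediately upstream of the TSS on the gene's strand, clipped at
  chromosome ends. A minus-strand gene at [a, b) has promoter
  [b, b + 2000).
* **CpG islands** (default 20 × 600 bp) overwrite the background. The
  island backbone is generated at `island_gc` (default 0.60) with every
  C→G adjacency broken, then exactly `round(length × density / 100)` CpGs
  are planted at even offsets (so plants never overlap). The configured
  `island_cpg_density` (default 10 per 100 bp) is therefore the realised
  density up to at most two boundary CpGs per island — which is what lets
  a test compare a dinucleotide scan of the emitted FASTA against the
  configuration exactly. A configurable fraction of islands (default 0.8
  of genes) is anchored at gene promoters, adjacent to the TSS; the rest
  are placed uniformly.
* **Tandem repeats** (default 3 loci × 5 copies × 400 bp) overwrite the
  background with byte-identical copies of a per-locus unit. Their only
  purpose is to defeat unique mapping, the mechanism by which repeat
  content depresses mapping efficiency in real data.

Placement draws uniformly over every start position that fits in a free
gap (islands and repeats never overlap each other; genes never overlap
genes), so placement cannot fail by bad luck — a `PlacementError` naming
the chromosome means the request genuinely does not fit.

No attempt is made to model real repeat families, CpG-island shores,
chromatin state, SNPs or sex chromosomes.

## Methylome model

Each CpG dinucleotide draws one probability from the Beta distribution of
its compartment and both strand cytosines share it (symmetric CpG
methylation; strand asymmetry is not modelled):

| compartment | default | mean |
|---|---|---|
| island | Beta(1, 9) | 0.10 |
| background | Beta(6, 2) | 0.75 |
| repeat | Beta(9, 1) | 0.90 |

Compartment precedence where features overlap is island > repeat >
background, a deterministic tie-break. A `*_fixed` level replaces the Beta
draw by a point mass (used for degenerate truth in tests). Non-CpG
cytosines get the constant `non_cpg_methylation` (default 0.005; real
mammalian somatic non-CpG methylation is of this order). With the default
compartment sizes the genome-wide mean CpG methylation lands around
0.65–0.75, with islands hypomethylated and repeats hypermethylated — the
structure needed to make RRBS-vs-WGBS comparisons meaningful.

## Digestion, fill-in and size selection

`find_sites` reports every occurrence (including overlapping ones) of the
recognition sequence; the cut coordinate is occurrence start + cut offset
(MspI: C^CGG, offset 1). The pieces between consecutive cuts partition the
chromosome exactly.

The *sequenced insert* of an internal fragment is the end-repaired
molecule: MspI leaves two-base 5' CG overhangs, and filling them
regenerates the two bases past the downstream cut on both strands, so the
insert is `[cut_i, cut_{i+1} + 2)`. This convention is what makes both
strands of every fragment begin at a restriction site (read 1 starts
CGG/TGG depending on the methylation of the terminal CpG, read 2 starts
CAA after conversion) and it pins down the fill-in artifact precisely: the
regenerated cytosines are the bottom-strand C at `insert_start + 1` and
the top-strand C at `insert_end - 2`, each the partner of a real
fragment-end CpG, and each unmethylated in every molecule regardless of
the methylome. `Fragment.end_extension` records the two extension bases so
the exact cut-to-cut partition remains recoverable. Terminal chromosome
pieces have one ligatable end only and are excluded from libraries.

Size selection keeps inserts with min ≤ length ≤ max, both bounds
inclusive — adjacent published windows (50–150 / 150–250 / 250–350) share
their endpoints, so inclusivity is stated rather than guessed; tests use
interior lengths where it matters. Digestion is complete (no partial
digests); sonication uses a truncated-Normal length model (mean 350,
sd 50, window 300–400) since only the selected window of a sheared library
is ever observable anyway.

## Read simulation

Directional protocol only: read 1 is always the first `read_length` bases
of the bisulfite-converted original strand (top or bottom, p = 0.5 per
molecule), read 2 the first `read_length` bases of its complement from the
other insert end. Molecules pick fragments uniformly (no PCR duplication
model). Conversion is per molecule and per cytosine: unmethylated C → T
with `conversion_rate` (default 0.995), methylated C → T with
`inappropriate_conversion_rate` (default 0). Inserts shorter than the read
run through into a fixed TruSeq-style adapter prefix (configurable;
anything past the adapter is padded with A). Qualities are constant Q40 by
default with an optional logistic 3' decay to exercise quality trimming.
Sequencing errors are uniform substitutions at `sequencing_error_rate`
(default 0.001); indels are not modelled.

## Trimming

Per read: (1) the trailing run of bases below the Phred cutoff (default
20) is removed; (2) the leftmost suffix matching the adapter prefix with
≥ 1 base overlap and ≤ 10 % mismatches is removed; (3) in RRBS mode, two
further bases come off the 3' end of any adapter-trimmed read, and the
first two bases of read 2 are always clipped. The read-2 5' clip is the
standard paired-end RRBS practice and is essential here: for inserts
longer than the read, the filled-in cytosine at the fragment-start CpG is
sequenced exclusively at the 5' end of read 2, which a 3'-only rule would
never touch; with both rules active, no fill-in evidence survives into the
call table at any insert length (a property the tests assert exactly, on a
fully methylated truth where any surviving artifact shows up as an
unmethylated call). Pairs with either mate shorter than
`min_length_after_trim` (default 20) are rejected.

## Alignment

Scoring happens entirely in converted space: the reference is converted
C→T (for original-top candidates) and G→A (original-bottom), reads
likewise, so bisulfite conversion can never count as a mismatch —
including, deliberately, a read C over a reference T, which a
fully-asymmetric scorer would penalise. Candidates come from the 5'-most
`seed_length_bp` (default 50) of each mate: one exact hash lookup plus all
3 × 50 single-substitution variants, which guarantees that every full-read
placement within the one-mismatch budget is enumerated (a ≤ 1-mismatch
alignment has ≤ 1 mismatch inside the seed). Both mates are seeded
genome-wide; concordant candidates pair a read-1 locus with a read-2 locus
on the same chromosome, opposite insert ends, insert length within
[insert_min, insert_max] (by default the library's size window ± 20 bp,
since trimming shifts inferred insert ends by up to 2 bp). Exactly one
concordant candidate ⇒ `unique` (the only status used downstream); more
than one — including top/bottom ties at the same locus — ⇒ `ambiguous`;
none, but both mates had placements ⇒ `discordant`; otherwise `unmapped`
(also the status for mates shorter than the seed, which is how very short
size windows lose mapping efficiency). The test suite holds the seed
mapper to exact agreement (status and locus) with a brute-force
all-positions aligner on planted libraries.

## Calling and coverage

Evidence is strand-aware: a top-strand molecule reports forward-strand
cytosines (read base C methylated / T unmethylated), a bottom-strand
molecule reports reverse-strand cytosines (G / A in forward orientation).
Context (CpG vs non-CpG) comes from the reference, never the read; CHG/CHH
are not distinguished. Where mates overlap, read 1 wins and read 2
contributes only its non-overlapping part. Calls are kept per strand, with
a merged view per CpG dinucleotide (forward-position-keyed, strands
summed) used for every coverage statistic.

Conversion QC: non-CpG methylation % = 100 × Σ methylated / Σ depth over
non-CpG rows; implied efficiency is its complement. With zero true non-CpG
methylation this estimates 1 − conversion_rate in closed form. Mean CpG
methylation is depth-weighted (global count ratio over merged sites at
`min_depth`, default 1), reported to one decimal; the unweighted per-site
mean is exposed as an option.

Saturation: subsampling is exact-count, without replacement, implemented
as a prefix of one seed-keyed permutation so decreasing fractions under
one seed are nested (which also makes count monotonicity exact rather than
statistical). By default each subsample is re-mapped; a
`reuse_alignments` flag subsamples the full-data alignments instead —
mapping is per-pair, so the two modes agree (asserted by a test). GB
equivalents are a reporting convenience: fraction × `full_gb` (default
30, one lane). Percentages relative to the full dataset use
round-half-even to one decimal everywhere; if the full dataset has zero
qualifying sites the percentage is reported as NaN rather than an error.

## Determinism and seeds

Every stochastic stage takes an explicit integer seed. The pipeline
derives per-stage seeds from one global seed as
`crc32("stage:seed") mod 2^31`, so a config plus seed reproduces
byte-identical outputs end to end while stages stay independently
re-runnable.

## Problem sizes

Unit tests run on 10–100 kb genomes with hundreds of read pairs. The
heavier end-to-end properties use: 120 kb / 2,000 pairs for the
mapper-vs-brute-force parity check, 100 kb / 10,000 WGBS pairs at ~20×
for compartment-mean recovery (background and island means within 3 SE
through the real pipeline; the repeat compartment — unmappable by design —
via the truth-tracked alignment route), and 50 kb / 3,000-pair paired
RRBS/WGBS libraries for the depth-collapse comparison. The acceptance
script uses a 200 kb genome at ~20× CpG depth. These sizes were chosen so
the statistical assertions (3 SE bands, strict orderings) are comfortably
powered on a single CPU.

## What passing tests do and do not show

The generator reproduces the *mechanisms* the assessment relies on — CpG
enrichment by MspI + size selection, island hypomethylation at promoters,
repeat-driven mapping loss, the fill-in trimming artifact, depth
saturation — under idealised conditions: i.i.d. background sequence,
complete digestion, uniform molecule sampling without PCR bias, mostly
constant base quality, substitution-only errors. Passing tests therefore
validate the pipeline's logic and the direction and rough magnitude of
design effects, not absolute values for any real genome: real mapping
efficiencies, CpG totals and methylation means depend on repeat content,
assembly quality and library chemistry that are outside this model.
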