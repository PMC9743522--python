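# fusion4c

Detection and characterization of low-frequency gene fusions from Hi-C
contact maps and multi-caller structural-variant call sets.

Kinase fusions such as the KIAA1549-BRAF fusion of juvenile pilocytic
astrocytoma are created by genomic rearrangements — tandem
duplications, deletions, interchromosomal insertions — that are easy to
miss with any single RNA fusion caller or short-read SV caller,
especially at low tumor purity. A rearrangement, however, permanently
changes the three-dimensional contact structure of the locus: the
fusion partner becomes an unusually strong interactor of the retained
gene terminal in a genome-wide Hi-C map. `fusion4c` turns that
observation into a reusable pipeline for people analyzing binned Hi-C
maps and heterogeneous caller outputs in tumor genomics.

## What it computes

**Virtual-4C with anchor-partition normalization.** The viewpoint gene
is split at its recurrent breakpoint into the fusion-retained
C-terminal anchor and the fusion-lost N-terminal anchor (defaults ship
for BRAF, hg38: chr7:140,710,000–140,790,000 and
chr7:140,790,000–140,930,000). For every 50 kb bin *b* (edges phased at
the breakpoint),

```
norm_c(b) = Σ contacts(b, C-terminal) / Σ contacts(b, full gene)
```

The full-gene background is the exact union of the two terminals, so
`norm_c + norm_n = 1` and the ratio cancels the distance decay and
per-bin coverage bias that dominate raw profiles. Fusion partner loci
are called per sample as *exclusive peaks*: bins where exactly one
cohort sample exceeds a leave-one-out z-score threshold (default
z = 4, with binomial and absolute noise floors on the denominator).

**A/B compartments.** Per-chromosome compartment scores as the leading
eigenvector of the Pearson correlation of the balanced
observed/expected map (positive = A, open; negative = B, compact),
sign-oriented by a user-supplied reference track, plus cross-sample
correlation matrices and average-linkage dendrograms.

**Multi-caller SV consensus.** Calls from heterogeneous SV callers are
merged when both paired breakpoints agree within ±1000 bp (single
linkage; SV type not required to match), filtered to > 10 kb and ≥ 2
callers, flagged somatic/germline by matched-normal subtraction, and
annotated against gene models (gene, intron in transcript numbering,
predicted 5′→3′ fusion orientation). RNA fusion calls are unioned by
gene pair with a priority-gene review list, so a single-caller BRAF
fusion among hundreds of raw calls is retained rather than
intersected away.

**Synthetic data with ground truth.** A first-class simulator builds
rearranged genomes from an event grammar, samples Hi-C maps with
power-law cis decay, trans background, planted A/B checkerboards and
Poisson depth, maps them back to reference coordinates through the
rearrangement, and emulates jittered, dropout-prone caller panels —
so every stage is testable without controlled-access patient data.

## Worked example

The shipped demo simulates a 6-sample cohort on a two-chromosome toy
genome; `sample1` carries a tandem duplication joining the 5′ end of a
partner gene (breakpoint chr7:2,000,000) to the retained C-terminal of
the viewpoint gene, and four simulated SV callers report the event with
300 bp breakpoint jitter plus false positives.

```
$ fusion4c run --config examples/demo.yaml --outdir demo_run
run 23c6fdebde29d44a seed 7: ok
fusion sample sample1 recovered at partner breakpoint ['chr7', 2000000]
samples with exclusive loci: sample1
```

The run directory contains the simulated matrices (`matrices/*.coo`),
balancing weights, compartment tracks and dendrogram
(`compartments/`), virtual-4C profiles and candidate partner loci
(`virtual4c/`), the consensus SVs (`sv/`) and a `report.json` stamped
with the config hash and seed (reruns are byte-identical). The
top-ranked exclusive locus:

```
$ head -1 demo_run/virtual4c/candidate_loci.bed
chr7	1980000	2880000	sample1	13.55
```

— only the fusion sample has an exclusive peak, its locus covers the
true partner breakpoint at chr7:2,000,000, and the peak leave-one-out
z-score is 13.55. The consensus SV output recovers the planted
junction from the jittered caller panel:

```
$ cat demo_run/sv/sample1.consensus.bedpe
chr7	1999952	1999953	chr7	3979959	3979960	caller1,caller2,caller3,caller4	.	.	.	DUP	sample1	somatic
```

with the medoid representative ~50 bp from the true breakpoints, all
four callers agreeing, and the report annotating the pair as
PARTNER → GENE (5′ → 3′). Each stage is also available as a
subcommand (`fusion4c simulate | balance | coarsen | compartments |
virtual4c | sv-consensus | fusions`) for file-driven use on real data.

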