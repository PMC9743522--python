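# Methods

`fusion4c` detects and characterizes gene fusions from binned Hi-C
contact maps and multi-caller structural-variant (SV) call sets. The
motivating application is the BRAF fusion spectrum of juvenile
pilocytic astrocytoma, where fusions are often present at low allelic
or cellular fraction and missed by any single RNA or DNA caller. This
note describes the models, the tunable parameters, the synthetic-data
generator that underwrites the test suite, and the numerical and design
choices that were genuinely open.

## Virtual-4C profiles with anchor-partition normalization

A virtual-4C profile summarizes a genome-wide contact map against a
fixed viewpoint. The viewpoint here is a gene region split into two
terminal anchors at the recurrent fusion breakpoint: the *C-terminal*
region retained by oncogenic fusions and the *N-terminal* region lost
by them. The shipped default is the human BRAF locus (hg38):
C-terminal chr7:140,710,000–140,790,000, N-terminal
chr7:140,790,000–140,930,000, with the full gene region
(chr7:140,710,000–140,930,000) as the normalization background. The two
terminals partition the background exactly; all coordinates are 0-based
half-open and 10 kb-aligned.

Contacts are read at a fine resolution (default 10 kb) and summed to a
coarse resolution (default 50 kb) whose bin edges are *phased at the
breakpoint*: one coarse-bin boundary coincides exactly with the
terminal boundary, so the retained and lost terminals never share a
coarse bin. For each coarse bin `b`,

    raw_c(b) = Σ contacts(b, C-terminal)
    raw_n(b) = Σ contacts(b, N-terminal)
    raw_bg(b) = raw_c(b) + raw_n(b)            (exact, by the partition)
    norm_c(b) = raw_c(b) / raw_bg(b)

`norm_c` is the fraction of a bin's gene-directed contacts that go to
the retained terminal. Because both numerator and denominator decay
identically with genomic distance, the ratio removes the distance bias
that dominates raw viewpoint profiles; it equally cancels per-bin
coverage bias, which is why raw (unbalanced) counts are the default
input (balanced counts are available behind a flag, and behave
equivalently under the ratio). Bins with `raw_bg = 0` are flagged
missing, never 0/0. The same formula applies verbatim on trans
chromosomes, where it still cancels anchor-coverage effects.

### Exclusive-peak calling

A fusion partner locus appears as a peak in `norm_c` present in exactly
one sample of a cohort. The detector z-scores each sample's `norm_c`
at every bin against the leave-one-out mean and standard deviation of
the other samples, excluding the viewpoint itself plus a configurable
flank (default 1 Mb). A candidate bin is one where exactly the tested
sample exceeds the threshold (default z = 4); adjacent candidates
(gap ≤ 1 bin) merge into loci ranked by peak z.

With a handful of samples the empirical leave-one-out standard
deviation is heavy-tailed (the statistic is approximately a scaled t
with n−2 degrees of freedom), and at low-coverage bins `norm_c` is a
binomial fraction estimated from few counts; either effect alone
manufactures spurious "exclusive" peaks. The z denominator is
therefore floored twice:

* by the binomial sampling noise of the tested fraction,
  `sqrt(p(1−p)/raw_bg)` with `p` the leave-one-out mean; and
* by an absolute `min_sd` (default 0.02 on the [0, 1] fraction scale).

In event-free 6-sample cohorts at the default simulation depth this
reduces spurious exclusive bins from ~10 per cohort to ~1 per 50,000
bin tests while leaving planted-fusion recovery at 100%. Both floors
are parameters; setting them to 0 recovers the bare z rule.

## A/B compartment scores

Per chromosome, the balanced contact map is transformed to
observed/expected (O/E) by dividing each cis entry by the mean balanced
count at its diagonal separation; the compartment score is the leading
eigenvector of the Pearson correlation matrix of the O/E map, scaled by
the square root of its eigenvalue. Positive score = open A compartment,
negative = compact B.

The eigenvector sign is arbitrary, so orientation is an explicit input:
a per-bin reference track (the planted A-density on simulations; gene
density or GC content on real data) with which the returned score must
correlate non-negatively. Because the leading eigenvector can track
karyotype rather than compartments on aneuploid genomes, the top three
eigenvectors are computed and the one best correlated (in absolute
value) with the orientation track is selected, with a warning whenever
it is not the first. Bins masked by balancing, and bins whose O/E row
is constant (no correlation signal, typically ultra-sparse), are
flagged missing.

Samples are compared by pairwise Pearson correlation of their scores
over jointly unmasked bins (pairwise-complete; default comparison
resolution 50 kb) followed by average-linkage hierarchical clustering
on 1 − r distance. Pairs sharing fewer than two bins get an undefined
correlation and enter the linkage at the maximum distance of 2, with a
warning.

## Matrix model, balancing and coarsening

Contact maps are symmetric sparse matrices over a genome-wide bin
table, stored as the upper triangle with the diagonal counted once.
The text format is a plain COO dialect (`#bin_size`, `#chrom`,
optional `#anchor`/`#meta` headers, then `i j count`); the writer is
canonical (sorted, stable number formatting) so round trips are
byte-identical.

Balancing is iterative correction: per-bin multiplicative weights `w`
such that the row sums of `w_i c_ij w_j` are uniform, iterated until
the relative variance of the unmasked row sums falls below `tol`
(default 1e-6) or `max_iter` (200) is reached — non-convergence is
reported, never silent. Bins in the lowest coverage quantile (default
2%) and zero-coverage bins are masked to NaN; weights are normalized to
unit mean over unmasked bins. The weight contract (per-bin
multiplicative factors attached to the matrix) is deliberately the same
as that of external karyotype-aware normalizers, so externally computed
weights can be substituted without touching downstream code.

Anchored coarsening sums fine bins into coarse bins whose edges on the
anchor chromosome are phased at a breakpoint (first coarse bin may be
short); totals are conserved exactly, and short terminal bins are
retained rather than dropped for the same reason.

## The synthetic-data generator

The simulator is the package's ground-truth factory; every recovery
claim in the test suite is a claim about data it generated.

*Rearranged genomes.* An event grammar — tandem duplication, deletion,
insertion-translocation (a segment lost and replaced by a segment from
another chromosome, the TOP2B-BRAF-type mechanism), balanced
translocation — rewrites the reference into per-chromosome walks of
(interval, orientation) segments, with a derived-bin → reference-bin
lift-over. Breakpoints are bin-aligned: downstream analysis is binned,
so sub-bin breakpoints carry no information here. Insertions are
copy-forward by default (the source chromosome keeps its copy),
matching the observed chr3 duplication flanking the characterized
insertion event; inverted orientation is supported in the grammar.

*Contact maps.* Expected counts are computed in derived coordinates:
cis pairs at separation `d` bins get weight `(d+1)^−α` (default
α = 1.0, the canonical Hi-C cis decay slope), trans pairs a flat
relative rate (default 0.01), and pairs sharing a planted A/B label a
multiplicative boost (default 1.5 where compartments are planted;
checkerboard blocks of 10 bins). Weights are rescaled to a configured
total depth (default 1e6 read pairs) and Poisson-sampled — the standard
shot-noise model, seed-reproducible — then mapped through the lift-over
back to reference coordinates, where bins covered by several derived
copies accumulate all contributions, exactly as a reference-aligned map
of a duplicated region does. A rearrangement therefore leaves its
characteristic ectopic footprint (e.g. elevated contact between
duplication flanks) without being painted in by hand.

*Call sets.* A panel of simulated SV callers reports each true
junction with probability 1 − dropout, with independent rounded
Gaussian jitter (default σ = 300 bp) on both breakpoints, plus
unrelated false-positive calls per caller; truth labels are carried on
every true call.

*What the simulator does not emulate* — and hence what passing tests do
not show about real data: the genome is haploid and clonal (no tumor
purity, no heterozygous alleles; an N-terminal-deleting fusion
therefore depresses `raw_n` genome-wide and makes exclusivity easier
than in a heterozygous tumor), there is no restriction-fragment
structure, no mappability or GC bias beyond what balancing would
remove, no copy-number-driven coverage variation, and caller errors
are independent across callers, which real callers' shared alignment
artifacts are not. Default problem sizes (toy genomes of 4–10 Mb, 6
samples per cohort, 20 seeds per claim) were chosen to give stable
recovery statistics at interactive runtimes.

## SV consensus and fusion aggregation

Two SV calls match when their chromosome pairs agree and both paired
breakpoints lie within ±1000 bp (boundary inclusive) of each other; SV
type is *not* required to agree, because heterogeneous callers label
one junction DUP, TRA or BND. Consensus groups are the connected
components of this relation (single-linkage — the simplest pairwise
reading of the rule, pinned by an independent O(n²) oracle in the
tests), summarized by the medoid member (ties broken by canonical
order). Filters keep groups supported by ≥ 2 callers and strictly
larger than 10 kb; trans calls have no size and pass by default.
Matched-normal subtraction flags a tumor group germline when any
normal call matches its representative under the same rule — an
automated stand-in for manual curation of somatic status, with no
claim of replicating it.

RNA fusion calls are unioned across callers by unordered gene pair
(union-then-targeted-review, not intersection): a priority-gene list
subsets the union, so a fusion seen by a single caller among hundreds
of raw calls survives review — the regime in which low-expressed
kinase fusions are actually found. Breakpoints are annotated against
BED6/BED12 gene models; with exon structure, the containing intron is
numbered in transcript orientation, and the predicted 5′/3′ fusion
partners follow from each gene's strand and the flank retained by the
junction geometry.

## Numerical choices and degenerate inputs

* Counts fold to the upper triangle on read; duplicates sum; negative
  counts are rejected.
* Zero-expected O/E diagonals yield flagged-missing values, never
  division errors; missing propagates as NaN, never as zero.
* Eigendecomposition uses dense symmetric `eigh` per chromosome
  (chromosome-scale blocks at 50 kb are small); eigenvalues clipped at
  zero before the square-root scaling.
* Balancing on an already-balanced matrix converges in one iteration
  to unit weights; an empty matrix is rejected.
* `compartment_at` ties (equal A and B bin counts) fall back to the
  sign of the mean score.
* Pipeline runs are pure functions of (config, seed): reports and
  matrices are byte-identical across reruns, and every output carries
  the config hash and seed.

## Known limitations

Exclusivity is a cohort notion: with fewer than ~4 comparison samples
the leave-one-out statistics are weak, and a fusion shared by several
samples (a recurrent fusion in a homogeneous cohort) is by design not
"exclusive" and will be missed. Compartment scores on real aneuploid
tumors may require the non-leading eigenvector (the selection flag
exists for this). The consensus rule inherits single-linkage
chaining: dense call clusters can merge distinct events closer than
the tolerance. None of the recovery rates measured on simulations
transfer quantitatively to patient data; they validate the machinery,
not the biology.
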