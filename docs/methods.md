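# Methods

## Scope and data model

`gbmeth` analyses WGBS data after read mapping and methylation
extraction: its inputs are per-cytosine count tables (extended
Bismark-style coverage files with strand and context columns), feature
annotations, FPKM expression matrices, gene sequences, ortholog hit
tables, and externally computed substitution rates. Read-level
processing (trimming, mapping, M-bias handling) and annotation building
(gene prediction, repeat masking) are out of scope; the package treats
their outputs as given.

All intervals are held internally as 0-based half-open `[start, end)`.
Bismark coverage (1-based) and GFF3 (1-based inclusive) are converted at
the I/O boundary only; BED passes through. Cytosine records are kept
per strand: a CpG is represented by two site records, one per strand,
and tallies count per-strand sites. The percent-methylation column of
coverage files is advisory; methylated/unmethylated read counts are the
source of truth.

## Site calling

The conversion-failure rate ε is the pooled ratio Σm/Σ(m+u) over
spike-in control sites — a single genome-wide scalar, with no
per-context or per-strand variants. Sites are depth-filtered to the
inclusive band [5, 30]: below 5 reads a proportion is too noisy, above
30 the depth distribution flags collapsed repeats. The methylation test
is the one-sided upper binomial tail P(X ≥ m) with X ~ Binomial(n, ε):
the alternative is "more methylated reads than conversion error alone
explains". m = 0 gives p = 1 exactly; ε = 0 with m > 0 gives p = 0 and
a logged warning. BH correction runs jointly over all retained sites in
one family (all contexts and chromosomes together), as a single
genome-wide procedure; a per-context option exists but is off by
default. Calls use a strict q < 0.01.

## Feature aggregation

W = Σm/Σ(m+u) is computed from raw counts over all retained CpG sites
in a feature, regardless of call status; calls feed only the fraction
of sites called methylated. Both metrics are emitted side by side
because downstream analyses of expression stability can plausibly be
read against either. The gene filter "more than 10 covered CpG sites"
is strict: a gene is kept iff it has ≥ 11. Gene body means exons plus
introns; any UTR inside the gene span counts as gene body. A TE is
genic when fully contained in a gene span (TEs nested in introns are
genic), intergenic when it overlaps no gene, boundary otherwise.

Site-to-feature assignment uses a searchsorted fast path when a feature
set is non-overlapping (the common case for gene spans) and an interval
tree for nested/overlapping sets; both paths are checked against a
brute-force linear scan in the tests.

## Expression analyses

Replicates are merged by the arithmetic mean of FPKM per group. Fold
changes are log2((A + c)/(B + c)) with pseudocount c = 0.01 FPKM; the
pseudocount is needed because zero means occur, and a small constant
preserves ordering. Methylation classes are low [0, 0.2], medium
(0.2, 0.7], high (0.7, 1]; the published bin edges overlap at 0.2 and
0.7, and boundaries are assigned to the lower class — a deterministic,
documented rule whose sensitivity is testable. Rank-sum tests are
exact by enumeration when both groups have ≤ 8 observations and use the
tie-corrected normal approximation otherwise. Spearman's rho uses
average ranks; its p-value is exact by full permutation enumeration for
n ≤ 9 and the t-approximation above. ΔW is population A minus B (the
CLI prints the convention); the top-5% flag covers ⌈0.05·n⌉ genes with
all cutoff ties kept. Expression stability is the sample SD (n−1) of
log2 FPKM across a designated individual set, by default restricted to
genes expressed in all individuals (log2 on raw FPKM); the permissive
mode admits genes expressed in at least one individual using the
pseudocount.

## CpG O/E and mixture decomposition

Dinucleotides are counted with overlap at step 1; positions with
non-ACGT symbols are excluded from base counts and any pair touching
one is skipped. O/E is undefined (missing, logged) when a sequence has
no C or no G. Genome scans tile each contig from position 0 with
non-overlapping fragments (default 1000 bp) and drop the trailing
partial fragment so L is constant and values comparable. Zero O/E
values are removed before KDE and before mixture fitting: they arise
from sequences too short to contain a CpG, not from true total
depletion. KDE uses a Gaussian kernel with Silverman's rule-of-thumb
bandwidth and a grid spanning the data ± 3h.

The EM fitter runs `n_starts` initialisations (k-quantile means, the
first unjittered, the rest jittered with SD 0.25·sample-SD; all σ start
at the sample SD, weights uniform), keeps the best final log-likelihood,
and declares convergence when the relative log-likelihood change falls
below 1e-8 (cap 2000 iterations). σ is floored at 1e-4·sample-SD to
prevent collapse onto single points. Log-likelihood monotonicity is
asserted on every run (tolerance 1e-9 relative, for floating-point
noise). Components are reported sorted by ascending mean. k is a user
choice; BIC is available as a report, not an automatic selector. The
implementation is cross-checked in the tests against scikit-learn's
`GaussianMixture` on the same data.

## Comparative analyses

Reciprocal best hits require a unique top score in both directions; a
tie for best disqualifies the query, and the pair set is symmetric in
its inputs. The codon-alignment filter slides 60-bp windows in 3-bp
steps (the kept unit is the codon, so windows respect frame); a codon
is kept iff fully inside at least one window with ≤ 10 non-identical
positions (SNPs and gaps both count), kept codons are concatenated, and
the result is retained only if strictly longer than 180 bp measured
after filtering. Overlapping sliding windows are the more permissive
reading of a window rule that could also be tiled; sliding was chosen
and is documented here. Pearson correlations carry Fisher-z 95%
intervals; "average CpG O/E of the two species" is the per-gene mean of
the two species' values.

## The synthetic-data generator

The generator reproduces the distributional structure the analyses
assume, with explicit ground truth:

- **Annotation.** Non-overlapping genes packed left to right with
  random gaps (multinomial slack over a 100-bp minimum); 2–4 exons of
  150–400 bp separated by introns of 100–400 bp, so every gene has at
  least one intron. TEs (alternating DNA/RNA class) cycle through
  intergenic, boundary-spanning and genic placements. Background
  sequence is i.i.d. with GC content 0.33, typical of the AT-rich
  invertebrate genomes this pipeline targets.
- **Methylome.** 45% of genes are methylated — together with a
  within-gene methylated-site fraction of 0.8 this puts about a third
  of genic CpG sites in the methylated state, matching the gene-body
  pattern the pipeline is designed to detect; intergenic CpG sites are
  methylated with probability 0.05. CHG/CHH sites are never truly
  methylated and appear methylated only through conversion failure
  (ε = 0.01, i.e. a 99% conversion rate). Read depth is negative
  binomial (mean 15, dispersion 5) truncated to ≥ 1, so the [5, 30]
  retention band produces realistic attrition. A truly methylated site
  yields methylated reads with probability 1 − ε, an unmethylated site
  with probability ε. The per-site true methylation probabilities
  within methylated genes are calibration choices of this generator,
  not measured quantities.
- **Expression.** Log-normal FPKM with a stable per-gene baseline
  offset (SD 1 log2 unit); methylated genes have 4× the mean and 0.5×
  the coefficient of variation of unmethylated genes. An optional
  coupling shifts the two groups' log2 means by ±coupling·ΔW/2,
  linking between-population methylation differences to expression
  differences with the positive sign (more methylation, more
  expression).
- **Sequences with target CpG O/E.** Targets are drawn from a chosen
  normal mixture truncated to > 0. A first-order Markov chain tunes
  only the C→G transition rate to the target, with the freed
  probability mass routed to A/T and the non-C rows solved from
  stationarity so the base composition stays at the background — this
  keeps the GpC O/E control unbiased at 1. Residual deviation is then
  removed by composition-preserving swap moves until the realized O/E
  is within ±0.03 of the target; an unattainable target (≤ 0, or more
  CpGs than the composition permits) raises an error.

Fixing the seed fixes every byte of output. What the generator does
*not* emulate: read-level artifacts (M-bias, mapping bias, PCR
duplicates), linkage between neighbouring sites, overdispersed
(beta-binomial) methylation counts, partially methylated domains, and
annotation error. Tests passing on this generator therefore validate
the statistical machinery and its calibration under the stated model,
not robustness to those real-data features.

## Problem sizes and test design

The test suite validates each primitive against an independent
brute-force oracle (BH step-up, exact rank tests, RBH, interval
assignment, the codon window filter) on hundreds of randomized small
instances, and checks calibration properties on simulated studies:
mixture-parameter recovery at n = 20,000 draws, false-call control on
20 replicate null methylomes of 10⁵ sites, and the
methylation–expression triad on 20 replicate studies of 2,000 genes
each — sizes chosen to make Monte-Carlo error small relative to the
tested tolerances while keeping the full suite around a minute. The
KDE mode-location check uses a ±0.3 tolerance at n = 10⁴: the mode of
a kernel density estimate converges slowly, and repeated simulation
shows excursions up to ~0.25 at this sample size, so the sharper check
is placed on the peak height instead.

## Known limitations

- ε is genome-wide; context- or fragment-specific conversion bias is
  not modelled.
- The binomial site test ignores overdispersion across reads; a
  beta-binomial extension is a natural next step and deliberately out
  of scope.
- Single-site differential methylation and smoothing-based region
  callers are out of scope; differential analysis operates on gene-level
  W only.
- The mixture fitter assumes Gaussian components on the O/E scale;
  heavy-tailed or skewed components will be approximated, not detected.
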