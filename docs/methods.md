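# Methods

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED-native), including internally;
GTF input (1-based inclusive) is converted on read. The gap between two
intervals on one chromosome is 0 when they touch or overlap and
`later.start − earlier.end` otherwise, so "within max_gap" at `max_gap = 0`
includes abutting intervals. Strand is carried but ignored by every overlap
operation — histone-mark peaks are unstranded — and used only for promoter
windows. Overlap checks *within* one mark use `max_gap = 0`; checks
*between* two marks (enhancer classification) default to `max_gap = 1000`
bp. Chromosome-name dialects ("chr1" vs "1") are never silently reconciled:
an optional alias map can rename at read time, and the pipeline fails fast
when input files disagree, because the alternative failure mode is a
silently empty intersection.

## Consensus peaksets

The consensus of n replicate peaksets at support k is the set of maximal
runs of bases covered by peaks from ≥ k distinct replicates (peaks are
merged within a replicate first so each replicate contributes at most 1 per
base). Base-level support is the strictest reading of a k-of-n rule; it is
order-independent, anti-monotone in k, and directly checkable against a
per-base counting oracle. The wider convention used by some tools — extend
each supported seed to the merged span of every replicate peak touching
it — is available as `extent="span"`. Defaults: k = 2, n = 3. Consensus
regions carry no summit; the testing window falls back to the region
midpoint, the only symmetric choice when replicate summits conflict.

## Testing windows and counting

Per mark, the WT and KO consensus sets are merged (gap 0) into one joint
testing peakset: regions present in only one genotype must still be
testable, otherwise condition-specific gains are invisible by construction.
Each region becomes the window `[summit − h, summit + h)` with h = 500 bp
(300 bp-wide H3K4me3 peaks use h = 150 bp), clamped to chromosome bounds.
Windows from nearby summits may overlap; they are tested as-is. A fragment
is counted into a window when its midpoint lies in the window — midpoints
keep counts disjoint across abutting windows. Library size is the total
fragment count of the sample.

## Statistical model

Counts follow NB(μ, φ) with Var = μ + φμ².

* **Normalization** — trimmed mean of M-values: the reference sample is the
  column whose 75th-percentile count rate is closest to the mean; per
  sample, log-ratios against the reference are doubly trimmed (30 % on each
  M tail, 5 % on each A tail) and averaged with inverse asymptotic-variance
  weights; factors are rescaled to geometric mean 1. Effective library size
  = library size × factor.
* **Dispersion** — per region, a method-of-moments estimate
  φ̂ = (s² − m)/m² from within-group sample variances on counts scaled to
  the geometric-mean effective library size, pooled across groups by
  residual df, clamped at 1e-8, then shrunk toward the all-region median
  φ₀ with weight n₀/(n₀ + df), prior df n₀ = 10. With 3 + 3 replicates
  (df = 4) the estimate is noisy per region; shrinkage trades per-region
  variance for stability, which simulation shows keeps the exact test's
  type-I error near nominal. Fewer than 2 replicates per group is an error
  (a fixed dispersion must then be supplied).
* **Exact test** — counts are scaled to the common (geometric-mean)
  effective library size and the rounded group sums are compared
  conditionally on their total: under the null both groups share a
  per-sample mean μ̂ = t/(n_A + n_B); the sum of n i.i.d. NB(μ̂, φ)
  variables is NB with size n/φ and success probability 1/(1 + φμ̂), so the
  conditional distribution of the group-A sum is an explicit ratio
  distribution over 0..t. The two-sided p-value sums the probability of
  every split at most as probable as the observed one (ties included on
  both sides, within a 1e-9 log-tolerance), so a perfectly balanced split
  gives p = 1 exactly, and φ → 0 with equal library sizes reduces to the
  conditional binomial test. Totals of 0 give p = 1.
* **Effect size** — log₂FC = log₂((mean scaled KO + c)/(mean scaled WT + c))
  with prior count c = 0.125 to keep zero groups finite.
* **Multiplicity** — Benjamini–Hochberg step-up,
  q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j capped at 1. DBRs require *strictly* q < α
  (default α = 0.05) and a strictly signed log₂FC; consequently even α = 1
  leaves perfectly balanced windows (p = q = 1) uncalled.

All constants (trim fractions, prior df, prior count, α) are arguments.

## Enhancer-state classification

Baseline (WT): poised = H3K4me1 consensus peaks with no H3K27ac peak within
1000 bp; active = H3K27ac consensus peaks, partitioned by H3K4me1
co-occurrence. Differential (KO vs WT): H3K4me1 DBRs with no KO H3K27ac
consensus peak within the gap are poised gained/lost; H3K27ac DBRs split
exhaustively into active with/without H3K4me1 (gained/lost) by KO H3K4me1
consensus presence. H3K4me1 DBRs that fail the poised criterion have no
defined state; they are emitted in a side table
(`k4me1_k27ac_cooccurring`) rather than forced into a class. Every record
carries the evidence mark, direction, and the distance to the nearest
partner-mark consensus peak.

## Gene annotation and the overlap test

Each gene is one TSS: the 5′-most transcript start (+ strand) or 3′-most
transcript end (− strand). Promoter windows span TSS −5000/+100 bp,
strand-reflected on the − strand so the construction is mirror-symmetric.
A region overlapping ≥ 1 promoter window is assigned to the overlapped gene
with the smallest |TSS distance| (ties: lexicographic gene id); other
regions fall back to the nearest TSS with `in_promoter = False`, so every
region gets exactly one assignment, matching the behaviour of standard
nearest-feature annotators. Signed TSS distance is measured from the region
midpoint, negative upstream.

The bivalency-resolution test intersects the genes hit by H3K4me3-gained
DBRs with those hit by H3K27me3-lost DBRs. The universe is the set of genes
assigned to any *tested* window of either mark — conditioning on
testability avoids inflating significance with genes that could never have
entered either set. The 2×2 membership table is tested with Pearson
chi-squared, 1 df, no continuity correction (Yates available by flag),
upper-tail p.

## Synthetic experiment

The generator lays out non-overlapping loci (≥ 5 kb apart, interleaved
across ≥ 2 chromosomes) of four classes: promoters (bivalent: H3K4me3 +
H3K27me3, one gene per promoter with alternating strand and TSS at the
locus center), poised enhancers (H3K4me1 only), and active enhancers with
and without H3K4me1 (H3K27ac ± H3K4me1). Defaults: 300 loci per class on
two 10-Mb chromosomes; 100 gained + 100 lost loci per mark at |log₂FC| = 2
(the two genotypes receive 2^(±log₂FC/2) mean multipliers, so the planted
contrast equals the nominal effect); 40 promoters carry both an H3K4me3
gain and an H3K27me3 loss, the planted bivalency-resolution set — note that
against margins of 100 gained/100 lost among 300 testable promoters this
overlap is only mildly above the independence expectation (≈ 33), so the
reported chi-squared is small by design; the pipeline's job is to recover
the planted count, not to manufacture significance.

Per replicate, each present mark emits a peak at the locus (800 bp for
H3K4me3, 1500 bp otherwise) with independent Gaussian boundary jitter
(sd 50 bp) and dropout probability 0.05; per sample, the fragment count per
locus is NB(mean 100 × genotype multiplier, φ = 0.1) with midpoints uniform
over a central span narrower than the testing window, plus 100 uniform
background fragments per Mb; fragments are 200 bp. A fixed seed gives a
byte-identical bundle. The `noise_free()` preset (jitter 0, dropout 0,
φ = 0, mean 300) defines the zero-noise condition under which the pipeline
is expected to be lossless: consensus reproduces planted peaks exactly and
every planted state label is recovered — "zero noise" includes zero count
overdispersion, since NB counts at φ = 0.1 leave a nonzero chance of
missing a planted region no matter how good the test.

Scoring matches calls to planted loci by ≥ 1 bp overlap, direction- and
state-aware: DBR sensitivity = recovered planted loci / planted; empirical
FDR = calls overlapping no matching planted locus / calls; state accuracy =
planted state loci recovered with the exact label / planted state loci.
Empty call sets report precision/FDR as NaN.

What the generator does **not** model — read-level sequence, mappability or
GC bias, peak-caller boundary artefacts, correlated background, copy-number
structure — bounds what passing tests show: they validate the statistics
and the bookkeeping under the model's own assumptions, not performance on
real libraries.

## Problem sizes

The test suite exercises oracle comparisons on ~100 random instances per
interval operation (coordinates ≤ 5 kb so per-base oracles stay cheap),
statistical calibration on 2000–5000 simulated regions, and pipeline-level
properties on a 160-locus experiment; the full default 1200-locus
experiment is run once for planted-truth recovery and once noise-free. The
acceptance script runs the default experiment plus a 5000-region null
simulation per invocation.

## Known limitations

* The exact test rounds scaled group sums to integers rather than
  interpolating the quantile adjustment; with the moderate normalization
  factors typical of this design the rounding error is far below the
  test's granularity.
* Dispersion shrinkage toward the global median assumes exchangeable
  regions; marks with strongly bimodal dispersion would be better served by
  trended shrinkage, which is not implemented.
* The annotator implements promoter-window + nearest-TSS assignment only;
  no exon/intron/UTR taxonomy.
* `consensus(extent="span")` can chain regions through replicates and is
  provided for compatibility, not as the default.
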