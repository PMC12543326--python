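# enhancerstate

Differential histone-mark ChIP-seq analysis for a replicated two-condition
design: replicate-consensus peaksets, summit-window negative-binomial count
testing, six-way poised/active enhancer-state classification, promoter-window
gene annotation, and a gene-set overlap test for bivalency resolution — plus
a synthetic-data generator with planted ground truth so the whole chain can
be validated end to end.

The package is aimed at epigenomics analysts comparing histone-modification
profiles (H3K4me3, H3K27me3, H3K4me1, H3K27ac) between a knockout and a
wild-type condition with a small number of biological replicates (the
canonical design is 3 clones per genotype), starting from called peaks
(BED/narrowPeak) and fragment intervals (BED) rather than raw reads.

## What it computes

**Consensus peaks.** For each mark and condition, the consensus peakset is
the set of maximal regions where peaks from at least *k* of *n* replicates
overlap (default 2 of 3), computed by per-base support counting.

**Differential binding.** Each consensus region (WT and KO consensus merged)
is reduced to a fixed window around its summit — ±500 bp, or ±150 bp for the
narrower H3K4me3 mark — and per-sample fragment midpoints are counted per
window. Counts y~rs~ are modelled as negative binomial with
Var = μ + φμ²; samples are normalized by trimmed-mean-of-M-values (TMM)
factors, per-region dispersions are method-of-moments estimates shrunk
toward the common value, and each window is tested with the conditional NB
exact test on group sums (two-sided, minimum-likelihood tail). P-values are
Benjamini–Hochberg adjusted; windows with q < 0.05 are differentially bound
regions (DBRs), gained (log₂FC > 0) or lost (log₂FC < 0) in KO.

**Enhancer states.** A poised enhancer carries H3K4me1 without H3K27ac; an
active enhancer carries H3K27ac with or without H3K4me1. Each H3K4me1 or
H3K27ac DBR is assigned one of six differential states
(poised / active-without-H3K4me1 / active-with-H3K4me1, each gained or
lost), with partner-mark presence judged against the KO consensus peakset
allowing a maximum 1000 bp gap for cross-mark overlap.

**Gene annotation and bivalency resolution.** Regions are assigned to genes
via strand-aware promoter windows (TSS −5000/+100 bp by default; nearest-TSS
fallback), and the overlap between genes gaining H3K4me3 and genes losing
H3K27me3 — loss of bivalency toward activation — is tested with a Pearson
chi-squared on the 2×2 gene-membership table.

## Worked example

Run the default synthetic experiment (two 10-Mb chromosomes, 1200 planted
loci, 200 differential loci per mark at |log₂FC| = 2, NB dispersion 0.1,
3 replicates per genotype) through the whole pipeline:

```python
from enhancerstate import run_pipeline

report = run_pipeline({"output_dir": "out", "simulation": {"seed": 1}})
ev = report["evaluation"]
print({m: round(d["sensitivity"], 3) for m, d in ev["dbr"].items()})
print(round(ev["enhancer_states"]["accuracy"], 4))
print(report["stages"]["bivalency"]["overlap"])
```

prints

```
{'H3K27ac': 1.0, 'H3K27me3': 1.0, 'H3K4me1': 0.99, 'H3K4me3': 1.0}
0.9925
40
```

i.e. essentially every planted differential region is recovered per mark,
99.25 % of the 400 planted enhancer-state labels are reproduced exactly
(sensitivity per mark ≥ 0.99 at an empirical FDR below the nominal 0.05),
and the 40-gene planted overlap between H3K4me3-gained and H3K27me3-lost
promoters is recovered in full. `out/` holds per-stage BED/TSV artifacts,
`report.json` and a log.

The same run is available from the shell:

```sh
enhancerstate run --config run.yaml          # full pipeline
enhancerstate simulate --seed 1 --out sim/   # just the synthetic bundle
enhancerstate consensus --peaks r1.narrowPeak --peaks r2.narrowPeak \
    --peaks r3.narrowPeak --min-support 2 --out consensus.bed
```

## Scope

The package starts from called peaks and fragment intervals. Read trimming,
alignment, peak calling, spike-in handling, blacklist filtering and signal
track generation are upstream concerns; RNA-seq and DNA-methylation
analysis, gene-set enrichment against external databases, and
chromatin-state HMMs are out of scope.
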