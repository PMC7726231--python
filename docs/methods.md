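# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Data model and preprocessing

The central object is a gene × sample matrix of bead-array intensities with
an optional parallel matrix of detection/quality scores in [0, 1]. Gene
symbols are uppercased before any matching because gene-set catalogs and
journal tables mix cases freely; duplicate symbols after uppercasing are an
error at parse time, and probe-level matrices are collapsed to one probe per
gene by the max-mean convention. Missing values are rejected rather than
imputed.

**Quality filtering** keeps a gene only if its score is strictly greater
than the threshold (default 0.95) in *every* sample. The all-sample rule is
the stringent reading of a per-value detection score on a
one-probe-one-gene platform, and it makes the enrichment background
well-defined: the retained gene count *is* the "total number of genes
measured" N.

**Normalization** is log2 followed by subtraction of each sample's median
log2 value, after which every sample's median is exactly 0 (the classical
QC criterion for this pipeline; box-plot five-number summaries are provided
for inspection). Scaling each sample by its median in raw space and then
taking log2 is algebraically identical. Centering per sample implies
centering per group a fortiori. Non-positive intensities are an error —
background-corrected arrays can go negative, but silently offsetting data
would fabricate values, so the caller must resolve them explicitly.

*Assumption worth noting:* median centering presumes most genes are
unchanged between groups. If a large fraction of the transcriptome moves in
one direction, the median moves with it and apparent directions are
distorted. At the emulated study scale (739 DEGs among 20,000 genes, ~2.4%
down) the distortion is negligible; simulations that plant DEGs into most
of a small gene panel must skip centering, and the test suite does exactly
that where relevant.

## Differential expression

Two-sided Student t-test with pooled variance per gene, on the
log2-centered values. Pooled rather than Welch because with n = 4 per group
on a shared platform the classical equal-variance test is what the legacy
array suites computed; Welch is available via `variant="welch"`. Genes with
p < α (default 0.05, raw) are partitioned by the sign of
Δ = mean(treatment) − mean(control). No fold-change threshold is applied
and no multiple-testing correction enters the call; a Benjamini–Hochberg
q-value column is attached for information only. Results are ordered by
ascending p with lexicographic gene-ID tie-break, so output is fully
deterministic.

Degenerate inputs are handled explicitly rather than through NaN: two
constant groups with equal means give t = 0, p = 1; with unequal means they
give a flagged ±inf t sentinel with p = 0.

Selecting at raw p < 0.05 has an unavoidable consequence that matters for
interpreting the partition: about 5% of the null genes enter it as false
positives, split evenly between directions. With 20,000 measured genes and
739 true DEGs, the partition's down-fraction is therefore pulled from the
true 66% toward ~53–57%. Scoring against the simulator's ground truth
separates the two effects: the direction split *among recovered planted
DEGs* stays at 66%, and both numbers are reported by the evaluation
routines.

## Directional enrichment z-score

For one set and one direction: N = measured genes (the post-filter
universe), R = size of the directional DEG list, n = measured genes
annotated to the set, r = DEGs annotated to the set, and

z = (r − nR/N) / sqrt( n (R/N)(1 − R/N)(1 − (n−1)/(N−1)) ),

i.e. the exact hypergeometric mean/variance standardization of r. The
implementation is cross-validated against `hypergeom_moments`, which sums
the pmf explicitly over the feasible support (no closed forms); for N ≤
1000 the pmf uses exact integer binomial coefficients converted once to
float64, which keeps the summed moments accurate to a few ulps even on
two-point supports (a log-gamma formulation would lose ~1e-10 in z there);
above that a log-gamma path takes over. Calls use |z| ≥ 2 two-sided:
over-representation above +2, depletion below −2.

Set membership is intersected with the measured universe to define n; the
full catalog size is reported alongside for transparency, because printed
tables of this era sometimes used catalog sizes. Sets with no measured
members, and degenerate queries (R = 0, n = N), are skipped with a logged
notice rather than returning infinities.

At small n the statistic is coarse: for n ≈ 5 and R/N ≈ 0.025 a single
overlapping gene already gives z ≈ 2.5, and the two-sided |z| ≥ 2 event has
probability ≈ 0.12 under the null — a property of applying a normal-scale
cutoff to a discrete count, not of the implementation. The simulator's
default *null* sets therefore span 10–500 genes (typical pathway-catalog
sizes); tiny sets remain fully supported.

## Background calibration

Published per-pathway tables print (r, n, z) but not N. Since z is smooth
and monotone in N at fixed counts, an integer grid search minimizing
Σ(z(N) − z_printed)² over N recovers the background a table used; ties
break toward the smaller N so results are deterministic, and at least two
rows are required because one row is solved by a whole curve of N values.

Applied to the embedded published tables (17 down-regulated pathways with
R = 487; 15 up-regulated with R = 252): the down table calibrates to
N̂ = 19,826 with max |residual| 0.22 and median 0.03 z units; the up table
to N̂ = 32,291 with max |residual| 0.04. No single N reconciles the two
directions — the inconsistency is in the published tables themselves, and
both fits are reported without guessing intent. The default search ranges
are [15,000, 30,000] (down) and [15,000, 50,000] (up); the analysis-time
default for fresh data is N = genes surviving the quality filter, with a
fixed-N option for reproducing printed tables.

## Clustering

Gene and sample ordering for heatmaps uses agglomerative clustering on
correlation distance d = 1 − Pearson (range [0, 2]) with size-weighted
average linkage, the defaults of array-era heatmap tools; Euclidean
distance and complete linkage are available as options. The agglomeration
is implemented in-package because the ordering contract is fully pinned
down: among equidistant pairs the one containing the lowest original row
index merges first, and at each merge the subtree with the smaller minimal
original index becomes the left child. This yields a deterministic leaf
order without optimal-leaf-ordering, a permutation-invariant tree, and
non-decreasing merge heights (average linkage admits no inversions on these
inputs; any inversion would be an error). Trees export as Newick with
branch lengths equal to merge-height differences, so root-to-leaf distances
are ultrametric. Rendering is out of scope; the ordered matrix TSV is the
deliverable.

## Densitometry and correlation

Band densities are divided by a loading reference (β-actin or a
total-protein stain — a column, not a constant) and then by the
control-group mean of that ratio per target, making the control mean
exactly 1 and the output invariant to global rescaling. Group comparison is
the same pooled t-test as the expression stage; correlations are Pearson
with the two-sided p from t = r·sqrt((n−2)/(1−r²)) on n − 2 df, computed on
the pooled cohort (both groups share one axis in the emulated figures),
with per-group subsets available by filtering. Protein and transport tables
are paired by subject-ID inner join, dropping and counting unmatched
subjects. Fisher-z intervals (atanh r ± z₀.₉₇₅/√(n−3)) quantify estimation
uncertainty.

## Simulator

Per-gene log2 baselines ~ Normal(8.0, 1.5), typical of bead-array
intensities; planted DEGs add ±2.0 log2 units to the treatment group (66%
down by default); i.i.d. Normal(0, 0.5) noise per value; exponentiation to
the raw scale so the pipeline's own log2 recovers the construction. Default
design: 4 + 4 samples, 20,000 genes, 739 DEGs. Gene sets receive a
specified number of true down-DEGs plus random non-DEG fillers (default
planted set: 88 genes with 18 true down-DEGs); null sets draw only non-DEG
genes. The densitometry cohort is 19 + 25 subjects with a bivariate normal
(ρ = 0.6 by default) on the natural-log scale, exponentiated for positive
support, with an optional downward IUGR mean shift (−0.4 log units)
emulating reduced ribosomal-protein expression.

One integer seed drives everything; per-stage substreams are derived by
fixed offsets so each stage can be regenerated independently, and identical
seeds give bitwise-identical outputs.

What the simulator does *not* emulate: probe-level bead noise, batch and
dye effects, correlated gene co-expression (genes are independent given
group), detection-score structure (scores are 1.0 unless degraded by flag),
and heavy-tailed intensity distributions. Passing tests therefore
demonstrate that the statistics behave as designed under their own
assumptions — correct type-I control, recovery of planted structure,
exact agreement with the hypergeometric oracle — not that real arrays meet
those assumptions.

Two evaluation choices are deliberate. First, the exponentiation step
slightly attenuates the measured-scale Pearson correlation relative to the
latent ρ (≈ 0.586 measured for ρ = 0.6 at SD 0.35), so Fisher-interval
coverage of ρ sits a shade under nominal; coverage is assessed with the
group shift disabled, because a group mean shift adds a between-group
correlation component that is a separate emulation feature. Second,
recovery of the planted direction split is scored against ground truth for
the reason given in the differential-expression section.

## Problem sizes and determinism of the evaluation suite

The heavy evaluations use 100 replicate simulations each: null runs at
10,000 genes (type-I error and null-set flag rate), planted runs at the
default 20,000-gene study scale, and cohort-size correlation runs; the
exhaustive z-statistic verification sweeps every (N, R, n, r) with
N ≤ 200. These sizes make the full evaluation complete in about a minute on
one CPU while keeping binomial noise on the reported rates small (SD ≈ 2
percentage points on a 95% rate over 100 runs). All of it is seed-driven
and reproducible.

## Known limitations

* Raw p < 0.05 selection is faithful to the emulated workflow but is not a
  defensible modern error-control strategy; the BH column exists for users
  who want one.
* The enrichment z treats genes as exchangeable; correlated genes inflate
  |z| in real data.
* Calibration recovers N only up to the information in the printed rows;
  tables with few rows or heavily rounded z values yield flat objectives.
* The clustering stage is O(k²) memory and O(k³)-ish time in DEG count via
  dense distance matrices — fine for hundreds to a few thousand DEGs, not
  for whole transcriptomes.
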