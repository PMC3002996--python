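# Methods

This note documents the statistical models and procedures implemented in
`acetdyn`, the defaults they use, and the choices made where the design was
genuinely open.

## Data model

All analyses operate on two long-format tables. The **probe table** holds
background-subtracted log-scale ChIP-chip intensities per
(probe, day, replicate), with each probe either assigned to a gene at a
signed base-pair offset from its TSS (5'→3' in gene orientation, 0 = TSS)
or flagged as a control probe. The **expression table** holds log-scale
expression per (gene, day, replicate). Day 0 is the undifferentiated
baseline; all "changes" are differences against it, so they accumulate over
the course rather than being step-to-step increments. A gene-level quality
filter retains genes with strictly more than `min_probes` (default 10)
distinct probes within ±`window_bp` (default 3500) of the TSS.

## Island calling

Control probes are designed to be un-acetylated and give an empirical null
for each array day. The null is moment-based and robust: per-day median
location and MAD-derived scale (×1.4826), with the day scale shrunk toward
the pooled cross-day scale by λ_day = n_day/(n_day + 50). The prior count
50 equals the minimum number of controls accepted per day; a day with few
controls borrows most of its scale from the pool, while the thousands of
controls on a typical array keep λ ≈ 1 and the day's own estimate. All
signals — control and gene-assigned — are replicate-averaged before testing
so both live on the same scale.

Acetylation is signal **above** background, so tests are one-sided
upper-tail Gaussian p-values, corrected by Benjamini–Hochberg within each
day (the null is day-specific, so pooling days would mix nulls). The FDR
cutoff defaults to 0.10 and is configuration-exposed. Under pure-null
simulation the realized call rate stays at or below the nominal level
(verified over 20 seeds in the test suite). A degenerate zero-variance null
(noise-free simulation) is floored at scale 1e-12, which makes calls reduce
to "strictly above the median".

Per-gene transition summaries report, for a day pair (a, b), the fraction
of probes staying acetylated (#ac at both / #ac at a) and staying
un-acetylated; genes with fewer than `min_state_count` (default 3) probes
in either state at day a are flagged discarded, since a proportion
estimated from one or two probes is meaningless. The pooled summary sums
the numerators and denominators over all consecutive day pairs, which
assumes the change distribution is time-homogeneous.

## Binned profiles and peaks

Profiles are mapped to 14 bins of 0.5 kb spanning −3.5..+3.5 kb (half-open
bins, 0-based internally, 1-based in outputs; the closed right edge folds
into bin 14). Every probe contributes max(signal − day null location, 0)
and the bin value is the mean contribution over the probes in the bin;
empty bins are zero. Binning therefore depends only on the null *location*,
not the FDR cutoff. Binning is computed on probe values, and peaks on the
binned vectors: "smallest region" searches could equally be run on raw
probes, but binned peaks are what make genes with different probe layouts
comparable, so that is the implemented (and documented) choice.

A **peak** is the smallest contiguous bin interval that contains the
profile argmax and carries at least `coverage` (default 0.30) of the total
binned signal. The search is greedy from the argmax: at each step the
neighbouring bin with the larger signal is appended; ties are broken toward
the TSS, then leftward, and the same rule picks among tied argmax bins.
This is deterministic and O(bins), always satisfies the coverage contract,
and shrinking the coverage never widens the interval. Peak agreement
between days is categorized as identical / contained / overlapping /
disjoint, with a mismatch tolerance t letting each endpoint differ by up to
t bins before a category degrades.

## Correlation, permutation significance, CCA

Per-gene changes versus day 0 are summarized by the mean (robustness check:
median) of the 14-bin change profile and correlated with expression change
for all pairings of post-baseline days (Pearson; robustness check:
Spearman). Analytic p-values come from the standard nulls, but those assume
independent genes; the permutation scheme instead applies one random gene
relabelling to the *whole* expression-change matrix per permutation, so
inter-day correlation within each layer and inter-gene correlation
structure are preserved, and reports the add-one empirical p-value
(1 + #{|r_perm| ≥ |r_obs|})/(1 + n_perm).

With a one-dimensional expression block, canonical correlation reduces to
the multiple correlation: the weight vector solves the least-squares
regression of expression change on the 14 bins (ridge-regularized by
1e-8 × mean diagonal if the Gram matrix is rank-deficient), ρ² equals the
regression R², and ρ is never below the |correlation| achieved by the
uniform (mean-summary) weighting.

## Shrinkage partial correlations

The 42 variables (14 bins × days 1, 3, 5) of the stacked change profiles
are modelled as a Gaussian graphical model. The sample correlation matrix R
is shrunk toward the identity, R* = (1 − λ)R + λI, with the analytic
Schäfer–Strimmer intensity λ* = Σ var̂(r_ij)/Σ r_ij² over off-diagonal
entries (clipped to [0, 1]); partial correlations are read off the inverse
Ω = R*⁻¹ as r_ij·rest = −ω_ij/√(ω_ii ω_jj). With λ pinned to 0 and n ≫ p
this reproduces direct covariance inversion to 1e-6 (oracle test), and on
AR(1) chains the significant-edge graph recovers the generating chain with
precision and recall ≥ 0.9 at n = 5000.

Edge significance uses the Fisher z-transform with effective degrees of
freedom n − p − 1 (each coefficient conditions on the remaining p − 2
variables), two-sided normal p-values and BH correction over the upper
triangle; an edge is kept at q ≤ 0.05 by default. This replaces the
local-FDR mixture fit of the GeneNet tradition with a deterministic
closed-form criterion; the cutoff is configuration-exposed.

## Balanced classification benchmark

Labels come from the simulation truth, or — for real data — from a
moderated two-sample t-test of a day's expression replicates against day 0
(residual variance shrunk toward the mean gene variance with 4 prior
degrees of freedom, BH at q ≤ 0.05, sign of the change giving up/down).
Four binary problems are built from the three classes; "differential vs
stable" pools up and down as the positive class.

With ~5% differential genes, a constant "unchanged" predictor reaches ~95%
accuracy, so each problem is balanced: the minority class is kept whole and
the majority class subsampled without replacement to the same size, 20
times. Every balanced resample is evaluated by stratified 10-fold CV
(stratification keeps the 50/50 ratio inside folds; the accuracy is the
pooled fraction correct over held-out folds, with a fresh classifier per
fold). Reported accuracy vectors therefore mix resampling and fold-split
variance, exactly as the evaluation design intends. The registry holds 18
classifiers with fixed, documented default hyperparameters (no tuning);
distance- and margin-based methods are wrapped in a standardizing pipeline.
The "stabilized" (left-spherical) discriminant variant is approximated by
shrinkage-regularized LDA; the shared-diagonal-covariance discriminant is a
small in-package estimator since scikit-learn has no direct equivalent.

## GSEA

Genes are ranked by a phenotype score (descending, ties broken by gene id
for determinism). The enrichment score is the signed extremum of the
weighted Kolmogorov–Smirnov running sum: hits add |score|^α normalized over
hits (α = 1 by default; α = 0 gives the classic unweighted statistic,
invariant under monotone score transforms), misses subtract 1/(N − N_hit).
Because the running sum is linear between hits, its extrema occur
immediately before or after hits; the implementation evaluates those
candidates in closed form, which makes large permutation ensembles cheap,
and ties in magnitude favour the positive extremum. Significance is the
add-one two-sided empirical p-value over random same-size gene sets —
equivalent to gene-label permutation when each gene carries one score —
with 10 000 permutations by default. The standard panel (3 phenotype
orderings × 5 gene sets = 15 tests) is reported without multiple-testing
correction: with so few tests even Bonferroni would not change conclusions,
and raw empirical p-values are the more informative output.

## Synthetic-data generator

The generator is a first-class module that emulates the study conditions:
17 268 genes (default), 28 probes per gene on a jittered even grid at
248 bp spacing within ±3.5 kb (jitter is uniform ±half-spacing; probes
jittered outside the window are dropped, producing realistic variable
per-gene counts), 5000 control probes, days (0, 1, 3, 5), 2 ChIP and 3
expression replicates, 2.5% up- and 2.5% down-regulated genes, and a 2%
ESC-like subset drawn from the stable class.

Each gene owns a contiguous island (half the probes by default; ~85% for
down genes so their loss is broad) whose location is fixed for the whole
course; the island plateau is 2.0 in units where the control null is
N(0, 0.5). Down genes lose the island multiplicatively, completely by the
last day; up genes gain at most 0.6 within ±1.5 kb of the TSS — much weaker
and narrower than the loss, which is what makes up-vs-stable genuinely
harder than down-vs-stable for the classifiers; ESC genes get a +1.0
window-wide elevation and an exponential retention exp(−1.9·t/t_max). A
per-gene effect-size factor Uniform(0.4, 1.0) spreads differential effect
magnitudes so the classes overlap realistically. Noise is Gaussian on the
log-scale signal in both layers (sd 0.5 for acetylation, 0.25 for
expression), matching standard two-colour array practice.

Expression change for gene g on day t is
coupling_by_day[t] × z_g(t) + noise, where z is the standardized *true*
mean acetylation change and coupling defaults to (0, 0.1, 0.3, 0.35) —
increasing, so genome-wide coordination strengthens over days. ESC genes'
coupling is damped ×0.25, emulating strong de-acetylation that is not
mirrored transcriptionally. The coupling direction
(acetylation → expression) is a simulation convenience only; the analyses
themselves are correlational and make no causal claim. A single
`numpy.random.default_rng(seed)` stream drives all draws, so outputs are
byte-identical for a given seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: probe-level spatial autocorrelation beyond the
island structure, dye-bias and normalization artifacts, heavy-tailed or
heteroskedastic noise, genomic coordinates/sequence, and biologically
realistic correlation magnitudes — with a single expression-noise parameter
serving both biological and replicate variation, the day-5 genome-wide
correlation (~0.6–0.7) is stronger than is typical of real
chromatin–expression data; that parameter was set so that roughly 5% of
genes pass a replicate-level differential call, which the balanced
evaluation depends on.

## Problem sizes and numerical conventions

The test suite runs the full pipeline at reduced sizes (hundreds to a few
thousand genes, 5–20 permutation/resample counts) chosen to keep the suite
fast while leaving each statistical check well-powered; the acceptance
script uses 2000 genes with the full registry and the study's 20 × 10-fold
design. Degenerate inputs are handled explicitly: all-zero profiles yield a
no-peak sentinel; zero-variance columns yield flagged NaN correlations;
empty gene-set intersections, under-determined unshrunk precision
estimates, invalid FDR/permutation counts and malformed input files raise
informative errors. Stage sub-seeds in the CLI are derived by hashing the
stage name into the global seed, so re-ordering or skipping stages never
shifts another stage's random stream.
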