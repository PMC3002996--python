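# acetdyn

Statistical pipeline for mapping **dynamic promoter histone-acetylation
profiles to gene-expression change** over a differentiation time course.

The setting: a ChIP-chip promoter-tiling study measures H3K9,14 acetylation
at ~28 probes per gene within ±3.5 kb of each TSS, on days 0, 1, 3 and 5 of
stem-cell differentiation (2 ChIP replicates), alongside expression
microarrays (3 replicates). The questions the pipeline answers:

1. **Does the *location* of acetylation signal move over time?** Probes are
   called "acetylated" against the empirical null given by un-acetylated
   control probes (one-sided test, per-day Benjamini–Hochberg control);
   per-gene fractions of probes staying acetylated / un-acetylated between
   days, and the stability of profile *peaks* (the smallest bin interval
   containing the profile maximum and ≥30% of total signal), quantify
   positional stability.
2. **How coordinated are acetylation and expression changes?** Profiles are
   binned into 14 × 0.5 kb bins around the TSS; per-gene mean (or median)
   acetylation change versus day 0 is correlated with expression change for
   all day pairings (Pearson/Spearman), with significance from both analytic
   nulls and a permutation scheme that relabels whole genes so inter-gene and
   inter-day correlation structure is preserved. One-dimensional canonical
   correlation (ρ = the multiple correlation of expression change on the 14
   bins) bounds what any linear profile summary can achieve, and a shrinkage
   Gaussian graphical model (Schäfer–Strimmer shrinkage of the correlation
   matrix toward the identity; partial correlations
   r_ij = −ω_ij/√(ω_ii ω_jj) from the inverse Ω) maps the direct
   spatio-temporal dependencies among the 42 bin×day variables.
3. **How predictive is the full change profile?** A suite of 18 classifiers
   (SVMs with four kernels, four discriminant-analysis variants, trees,
   bagging, random forest, k-NN with k ∈ {1,5,10,15}, naive Bayes, a small
   neural network, logistic regression) is benchmarked on four binary
   problems (up vs down, down vs stable, up vs stable, differential vs
   stable) with **balanced evaluation**: because only ~5% of genes are
   differential, the majority class is subsampled to the minority size 20
   times and stratified 10-fold CV accuracy is reported per resample, so
   chance is 50% rather than 95%.
4. **Do stem-cell-network genes behave distinctly?** Permutation GSEA (a
   weighted Kolmogorov–Smirnov running sum over ranked gene lists) tests
   whether ESC gene sets concentrate at the extremes of three orderings:
   mean day-0 acetylation, day-5 acetylation change, day-5 expression change.

Because the original array data are not redistributable, the package ships a
first-class **synthetic-data generator** that emulates the study's structure
(jittered probe grids, fixed acetylation-island locations, broad
de-acetylation in down-regulated genes vs narrow TSS-proximal gain in
up-regulated ones, an ESC-like subset with elevated baseline and strong
monotone loss, and an acetylation→expression coupling that strengthens over
days) so every stage is testable end-to-end.

## Worked example

```bash
acetdyn run-all --out demo/ --seed 5 --config demo.yaml
```

with `demo.yaml` scaling the simulation down for a quick run:

```yaml
sim: {n_genes: 250, n_control_probes: 300, frac_up: 0.06, frac_down: 0.06, frac_esc: 0.04}
n_perm: 100
gsea_perm: 100
n_resamples: 3
problems: [i]
classifiers: [lda, knn_5]
```

This writes `demo/manifest.json` plus per-stage outputs. On this
configuration the day-pair Pearson correlation matrix between mean
acetylation change and expression change
(`demo/assoc/correlation_pearson_mean.tsv`) is

```
acet_day        1        3        5
1          0.0877   0.3278   0.3399
3          0.1334   0.4295   0.4566
5          0.1441   0.4631   0.4785
```

— the diagonal (0.09 → 0.43 → 0.48) shows acetylation↔expression
coordination increasing over the time course; the day-3 and day-5 entries
all reach the permutation floor p = 1/101 at 100 permutations while the
day-1 correlations are much weaker
(`demo/assoc/correlation_permutation_p.tsv`). The classification summary
(`demo/classify/cv_summary.tsv`) reports the balanced-CV accuracy of
distinguishing up- from down-regulated genes by their change profiles
(median 0.97 for LDA, 1.00 for 5-NN on this easy synthetic instance), and
`demo/gsea/gsea_results.tsv` shows all five ESC-like gene sets enriched at
the top of the day-0 acetylation ranking (ES 0.67–1.00, p = 1/101) and at
the bottom of the day-5 acetylation-change ranking (ES ≤ −0.95), while
their day-5 expression-change enrichment is far weaker (three of five sets
not significant) — the generator's emulation of strong de-acetylation that
is not mirrored transcriptionally.

Column contracts for the on-disk formats (TSV with `.` for missing values;
GMT for gene sets) are documented in `src/acetdyn/ioformats.py`.

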