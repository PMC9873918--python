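# Methods

`colitraj` implements a temporal transcriptomic analysis of experimental
colitis: two arms (disease vs. control) sampled at four sacrifice days
(default 5, 12, 17, 36), with gene-level and exon-counting-bin-level RNA-seq
counts, VDJ-mapped read tables, and per-animal histopathology scores. This
note records the statistical models, the choices made where the design was
genuinely open, and the limits of what the synthetic validation shows.

## Count models and testing

### Log-CPM with precision weights

Exon-level (and optionally gene-level) analyses transform counts to
`log2((y + 0.5) / (L + 1) * 1e6)` and attach observation weights from a
fitted mean–variance trend: per-feature square-root residual standard
deviations from a design fit are lowess-smoothed (span 0.5) against average
log2 count, the trend is evaluated at each observation's fitted log2 count,
and the weight is the predicted standard deviation to the power −4. Below 50
features there is too little data to fit a trend and unit weights are used
with a warning.

### Weighted least squares and empirical-Bayes moderation

Per-feature weighted least squares gives coefficients, unscaled standard
errors, residual standard deviation `s_g` and residual df `d_g`. The
variance prior (`d0`, `s0²`) is estimated by method of moments on
`log s_g²` with digamma/trigamma corrections (trigamma inverted by Newton
iteration); posterior variances are `(d0·s0² + d_g·s_g²)/(d0 + d_g)` and
moderated t statistics are referred to `t(d0 + d_g)`. When all residual
variances coincide the prior df is infinite and the posterior is exactly
`s0²`; as `d0 → 0` the moderated t reduces to the ordinary t. Both limits
are tested.

### Negative-binomial GLMs

Gene-level fixed-day tests (`engine="nbglm"`) and the interaction LRT fit
NB2 log-linear models (variance `μ + φμ²`, log link, log-library offsets)
by IRLS, batched over genes. The per-gene dispersion is a moment estimator
with residual-df correction — the root of
`Σ (y−μ)² / (μ(1+φμ)) = n − p` — solved by bisection on `log φ`
(floor 1e−8). For the fixed-day Wald test it is shrunk 50% toward an
`a + b/mean` trend; the Wald statistic is referred to `t(n − p)` rather
than the normal, because at ~10 animals per arm the normal reference is
visibly anticonservative in the far tail that drives step-up FDR decisions.

For the disease:time interaction, full (`~ group + day + group:day`) and
reduced (`~ group + day`) models share a per-gene dispersion so the
likelihood ratio is well-defined. Two numerical choices matter for
calibration and were fixed after null-simulation study:

* the shared dispersion is the **average** of the unshrunk df-corrected
  Pearson estimates under the full and reduced models — the full-model
  estimate is biased low under the null (the interaction fit absorbs noise
  into the eight cell means) and the reduced-model estimate is the
  null-constrained one, biased high under the alternative;
* the statistic over its df is referred to **F(df, n − p_full)** rather
  than the asymptotic χ²(df) — the standard small-sample scaling when the
  dispersion is estimated.

With these choices the complete-null simulation (2,000 genes, 10 per arm
per day) yields zero BH rejections in 20 replicates, an empirical rate of
0.047 at the 0.05 quantile, and per-replicate Kolmogorov–Smirnov statistics
that pass uniformity at α = 0.01 in 19–20 of 20 replicates; with the χ²
reference and full-model dispersion the same simulation rejects in ~20% of
replicates, which would overstate discovery.

### Multiplicity

Benjamini–Hochberg step-up q-values (NaN propagated, ties broken by stable
sort) within each analysis context; Simes combination
`min_i p_(i)·m/i` for within-gene aggregation. Both are checked against
independent oracles (statsmodels; brute-force definitions).

## Differential exon usage

A counting bin is differentially used when its coefficient departs from the
gene's precision-weighted average coefficient (weights `1/u²` from the
unscaled standard errors). The deviation variance accounts for the
subtracted mean (`u_e² − 1/Σw`). Gene-level evidence is aggregated two
ways — Simes over the exon deviation p-values, and a moderated F equal to
the sum of squared deviation t's over `k − 1` on `(k − 1, d0 + d_g)` df —
and a gene is called differentially spliced when the smaller of the two BH
q-values is below the context default (0.10 fixed-day, 0.05 trajectory).
Single-exon genes are untestable and excluded with a log entry.

For splicing *trajectories*, the exon model includes the interaction
columns; per-exon deviations across the three interaction coefficients are
whitened with the coefficient covariance before forming the per-exon F.
This matters: interaction estimates share the reference-day samples and are
positively correlated, and an unwhitened sum of squared t's inflates the
null rate at 0.05 from ~0.05 to ~0.11.

Prediction features at the exon level use **usage-relative expression**
(exon log2-CPM minus the gene's per-sample mean over its exons), so exon
features carry splicing signal rather than repeating gene-level expression.

## Trajectory clustering

Median disease log2-CPM trajectories of genes passing interaction FDR 0.05
are row-standardized (mean 0, sd 1; constant rows dropped) and soft-
clustered by fuzzy c-means: memberships `u_gc ∝ (1/‖t_g − c_c‖²)^{1/(m−1)}`
normalized per gene, centers are `u^m`-weighted means, iterated to a center
shift below 1e−6. Five seeded k-means++-style starts are run and the
lowest-objective solution kept; a point coinciding with a center gets full
membership there. The fuzzifier defaults to the published size/
dimensionality heuristic (≈3 at 200 genes × 4 days; fallback 1.25), which
in our recovery simulations is markedly more stable than small fuzzifiers.
Clusters are relabeled A–E by greedy maximal correlation of centers with
the canonical temporal shapes — A early (1,1,0,0), B late (0,⅓,⅔,1), C very
early (1,0,0,0), D day-12 up (0,1,0,0), E day-12 down (0,−1,0,0) — with
ties broken by cluster size.

## Adaptive (VDJ) scores

Burden is VDJ-mapped reads per million total library reads. Clonality is
the normalized Shannon-entropy concentration `1 − H/ln K` of the clone
frequency vector (`K` = clones with positive count; a single-clone sample
is 1 by convention). "Clonality" has no single agreed definition in the
repertoire literature; the evenness complement used here is the most
common one, and the choice is deliberately surfaced rather than buried.
Spearman correlations use exact permutation
p-values for n ≤ 9 and the normal approximation `z = ρ√(n−1)` otherwise.

## Histology prediction

Each signature yields ten features per sample: the first three principal
components of the signature-restricted gene matrix and of the
usage-relative exon matrix (loadings fitted on the training cohort only,
signs fixed so loading sums are positive), the median expression and median
usage over the signature, and the two VDJ scores. A 500-tree random forest
regresses the histology score on these features; feature retention is by
10-fold cross-validation, dropping features whose held-out permutation
importance is non-positive in a majority of folds (screening forests use
100 trees — importance ranks stabilize well before the final ensemble
size — and at least one feature is always kept). Validation cohorts are
projected with training loadings, never refit; performance is Spearman ρ
(with p), a Cohen's kappa on the status binarization (disease iff score
> 0 — the synthetic controls have zero expected histology; a real-data
user should supply their own rule), and top-3 permutation importances.

## Human translation

Mouse signatures map through a user-supplied ortholog table (policy `all`
expands one-to-many; `one_to_one` keeps only unique pairs). Histology
indices are regressed on the first five signature PCs with restricted cubic
splines (3 knots at the 0.1/0.5/0.9 quantiles; `k` knots give `k − 1`
columns with linear tails), selected by backward stepwise deletion of whole
per-PC column groups minimizing `AIC = n·ln(RSS/n) + 2k`. Collinear columns
are dropped by projection-residual screening before selection.
Optimism-corrected adjusted R² reruns the full selection inside each of 300
bootstrap resamples: optimism is the mean of (fit on the bootstrap sample −
fit of the same model on the original data), and corrected = apparent −
optimism; degenerate resamples are skipped and logged. With no candidate
columns the model is the intercept alone and apparent = corrected = 0
exactly. Network relevance is an upper-tail hypergeometric overlap; the
universe defaults to the network's node set, and reported logs are base 10.

## Synthetic data

The generator emulates a two-arm hit/rest colitis time course: 2 arms × 4
days × 10 animals
(configurable), NB2 counts with mean `L_s·p_g·2^(x_s·δ_g(day)·f_s)` where
`p_g` comes from a log2-normal baseline (mean 5, sd 2 → realistic bulk
abundance spread), per-gene dispersions are gamma (mean 0.1, shape 4,
typical of mouse bulk RNA-seq), and library sizes are lognormal around 10⁷
(gene) and 10⁶ (exon). Planted structure, disjoint by construction: 50
genes per day with ±2 log2 fixed effects; five trajectory classes of 40
genes each following the canonical A–E shapes at amplitude 2; 40 static
and 20 late-day isoform switches that shift half of a gene's Dirichlet
(α = 5) exon proportions by +1.5 log2 in disease with renormalization, so
the gene total — and hence gene-level DE — is untouched. A latent severity
(hit/rest day profile 1.0/0.6/1.2/0.8 × lognormal per-animal factor, sd
0.3) scales each disease animal's expression effects and drives VDJ burden
(≈500 clones and 500 base reads per sample, linear in severity, with
mean-preserving lognormal rate noise of sd 0.6 — repertoire capture from
bulk RNA-seq is sparse, so the adaptive scores are a noisy severity
readout and expression features carry most of the predictive signal) and
histology
(`max(0, 2·severity + N(0, 0.5))`). A separate `structure_seed` lets two
cohorts share the planted gene structure with independent sampling noise,
which is what the cross-cohort transfer experiment requires.

What the generator does **not** emulate: batch and site effects, gene–gene
correlation beyond the shared severity factor, overlapping planted
categories (real genes can be both DE and spliced), tissue differences,
human covariates (age, ancestry, RIN), or sequence-level artifacts.
Passing the recovery and calibration suite therefore demonstrates that the
estimators do what they claim under the assumed model, not that real
colitis data will reach the same sensitivities.

## Problem sizes used in validation

Null calibration uses 2,000 genes × 80 samples × 20 replicates (10 in the
acceptance script); recovery and orthogonality use 1,500–2,000 genes;
transfer cohorts are 40 + 40 animals with 1,000 genes; the optimism check
uses n = 40, k = 10, B = 300 over 20 seeds (10 in the script); the
end-to-end pipeline run uses 800 genes × 48 samples. All stages are
bit-reproducible from a single integer seed.

## Known limitations

* Equation-level details of the source design matrix (covariates beyond
  group and day) are not recoverable from the text; the minimal
  `~ group + day + group:day` model is used.
* The NB engine assumes a common dispersion across groups; no outlier
  handling (Cook's-style) is implemented, so single aberrant animals can
  drive calls at these group sizes.
* The AIC-penalized spline selection is greedy backward deletion, not
  exhaustive; with strongly correlated PCs the selected term set is not
  unique (the optimism correction accounts for the selection either way).
* Status binarization for kappa is a placeholder threshold for synthetic
  data; real cohorts need a clinically meaningful rule.
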