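# Methods

This note documents the statistical models and procedures implemented in
`dualomics`, the defaults and why they were chosen, what the synthetic
cohort generator does and does not emulate, and the known limitations.

## Study design being modeled

A cross-sectional case-control pregnancy cohort: women diagnosed with
gestational diabetes mellitus (GDM) by a 75-g OGTT in the second trimester
versus women with normal glucose tolerance (NGT), each profiled by shotgun
metagenomics (species-level relative abundances) and untargeted serum
metabolomics, with clinical glycemic and hematologic covariates. The default
cohort size is 50 + 54. All group tests are two-sided Wilcoxon rank-sum
(Mann–Whitney) with Benjamini–Hochberg adjustment; the discovery screens use
FDR < 0.2 and confirmatory comparisons FDR < 0.05, both as strict
inequalities.

## Rank tests and FDR families

`wilcoxon_bh` uses exact null enumeration when both groups have ≤ 12
observations and the pooled data are tie-free, otherwise the normal
approximation with tie and continuity correction (scipy's
`mannwhitneyu`). One BH family spans one analysis table (all metabolites;
all species; all genera; all pathway scores; the metrics of one network
comparison), matching how the FDR levels are quoted per analysis. Fold
changes are mean(case)/mean(control). Constant features are reported with
p = 1 and a flag rather than dropped, keeping family size stable.

## Diversity and community tests

Richness counts taxa above a detection threshold (default 0: any non-zero
abundance). The alpha-diversity index is the Shannon entropy in nats on the
composition re-closed over detected taxa; it is labeled as a surrogate since
no specific index is canonical for this design. ANOSIM uses Bray–Curtis
dissimilarities and the standard statistic
R = (mean between-group rank − mean within-group rank) / (n(n−1)/4),
with a seeded label-permutation p-value (1 + #{R\* ≥ R}) / (1 + B).

## Pathway activity ("PAPi-style") scores

Metabolite abundances are first divided by their across-sample mean, making
instrument response scales comparable. The activity score of pathway *p* in
sample *s* is the sum of the normalized abundances of the measured
metabolites mapped to *p*, divided by the pathway's total compound count
K_p. Dividing by K_p (not by the measured count) penalizes thinly covered
pathways; unmeasured compounds contribute zero and are not imputed. The
score is linear in abundances and monotone in coverage (removing an
unmeasured compound from K_p strictly raises the score). The sign
convention is "score ∝ abundance"; no flux interpretation is attached, and
group differences are reported directionally only. Pathway maps and sizes
are supplied as files; there is no online database access.

## Co-occurrence networks

Networks are built on the top-k (default 50) most abundant species by
pooled mean. All C(k,2) Spearman correlations are computed at once (midrank
ties; t-approximation p-values, identical to the per-pair reference
computation); an edge survives when |ρ| strictly exceeds 0.3 and its
p-value — BH-adjusted for full-cohort networks, raw inside bootstrap
replicates — falls below α. Negative correlations are retained as signed
attributes, but all metrics weight edges by |ρ| (path length 1 − |ρ|), since
standard centralities require non-negative weights. Isolated nodes stay in
the node set with metric value 0, keeping replicate distributions
comparable. Metrics: global transitivity (unweighted 3×triangles /
connected triples), strength (Σ|ρ|), weighted closeness (reachable count /
summed shortest-path length; an isolated node scores 0), and the
L2-normalized non-negative principal eigenvector of the |ρ| adjacency.

### Bootstrapped comparison and its calibration

The between-group comparison rebuilds networks on 30-sample subsamples per
group, 100 replicates, drawn **without** replacement — with-replacement
draws duplicate samples and invalidate rank-correlation p-values (a
with-replacement flag exists). Node metrics are aggregated per replicate
(mean over nodes) by default; pooling nodes × replicates is available but
compounds dependence.

Replicates of one cohort are mutually dependent, so the conventional
rank-sum test on replicate distributions treats what is essentially one
observation per group (the cohort) as 100, and under a true null it flags
differences at FDR < 0.05 in most cohorts — the difference it detects is
cohort-level sampling noise, not population structure. The package
therefore exposes three comparisons:

* `method="subsampling_z"` (default): extrapolates the replicate variance to
  cohort-level uncertainty with the m-out-of-n factor m/(n_g − m) before a
  two-sided z-test. Empirically calibrated (no false flags on null cohorts)
  but, with ~50 samples per group, it detects a planted correlation-module
  difference (within-block ρ 0.6 vs 0.2) only rarely — that weakness is a
  property of the data size, not of the test.
* `method="ranksum"`: the conventional descriptive statistic for bootstrap
  network comparisons. Reported because it is the field's display
  convention; its p-values should be read as effect-size summaries of the
  replicate distributions, not as calibrated inference.
* `permutation_metric_comparison`: an exactly calibrated label-permutation
  test on full-group network metrics, for confirmatory use.

The pipeline emits both the calibrated and the rank-sum comparison side by
side.

Focal-species edge analysis records, per partner and replicate, the signed
ρ of the surviving edge (0 when absent — a config switch can drop missing
instead), rank-sum tests the per-partner distributions between groups, BH
across partners, and reports the top-10 most significant partners with
group-wise median ρ and sign.

## Balance selection

For disjoint taxon sets (N, D), the balance score is the isometric
log-ratio contrast √(k₁k₂/(k₁+k₂)) · (mean ln x over N − mean ln x over D);
it is invariant to per-sample rescaling and closure. Zeros are first
replaced by half the smallest positive value in the table, rows re-closed.
The greedy search initializes with the exhaustive best pair and adds the
taxon/side with the largest criterion gain (tolerance 1e-4, name-ordered
tie-break) up to 8 taxa, the size range of balances displayed for this kind
of analysis. The binary criterion is the orientation-free rank-AUC of the
balance — equivalent to the AUC of a univariate logistic fit, since AUC is
invariant under the monotone link; a capped IRLS logistic supplies the
reported coefficients. The continuous criterion is R² (cross-validated MSE
is also recorded). Cross-validation is 5-fold × 10 repeats, stratified for
binary responses; the whole search re-runs per training fold, accumulating
per-taxon selection frequencies, and the cross-validated AUC is computed
within each test fold and averaged — fold-specific balances are not on a
common scale, so pooling raw scores across folds would be meaningless.

## Sparse PLS

Regression-mode sPLS with per-component retained-variable counts (the
keepX/keepY idiom), defaults 2 components, keepX = 10, keepY = 5. Each
component starts from the SVD of the current cross-covariance and is
refined by alternating multiplication with soft-thresholding to the
requested count, then both blocks are deflated on the X-score. The sign is
fixed (largest-magnitude X-loading positive) so fits are deterministic.
Blocks are column-standardized; zero-variance columns are an error naming
the column; missing clinical values are mean-imputed with a logged count.
The display surface is sim(i,j) = Σ_h corr(X_i, t_h)·corr(Y_j, t_h),
clipped to [−1, 1]. Spearman heatmaps report all coefficients unthresholded
with BH over the full matrix (pairs with < 3 complete observations are
flagged missing).

## Random forest and Shapley attribution

Each significantly altered pathway score is regressed on the top-50 species
with a standard random forest (500 trees, mtry = ⌊p/3⌋, min-leaf 5,
out-of-bag R² reported). Shapley values use the model-agnostic permutation
estimator: per explained sample and random feature ordering, one random
background row fills the not-yet-introduced features and the marginal
prediction changes along the ordering are averaged (default 200 orderings;
background = the training matrix, subsampling configurable). The estimator
was chosen over tree-specific recursions because it verifies directly
against exact subset enumeration at small p. After averaging, the residual
of the efficiency identity Σφ = f(x) − baseline is spread uniformly over
features so the identity holds exactly; the baseline is the mean prediction
over the full background set (a fixed interventional/background
convention). Species-level φ are compared between groups with the standard
rank-sum/BH machinery, restricted to the species already flagged as
differentially abundant.

## Synthetic cohorts

Latent species log-abundances are multivariate normal: a strictly
decreasing base-mean profile (so taxon index tracks abundance rank),
unit log-SD, and group-specific block-correlation structure (a Gaussian
copula over designated top taxa). Log-normal + copula was preferred over a
Dirichlet because group-specific correlation modules — what the network
stage must recover — are directly specifiable. Group mean shifts plant
differential taxa (default: ten taxa at |log2 FC| = 1.5 inside the top
stratum; one module with within-block ρ 0.6 in GDM vs 0.2 in NGT and one
shared module at 0.45). Abundances are exponentiated, zero-inflated with
probability 0.3 for taxa outside the top-50 stratum (keeping the network
universe dense, as real top-abundance species are), and closed to 100%.

Metabolites are noisy linear read-outs of latent log-abundances shifted to
positive instrument-style units; three planted pathways are measured by
three metabolites each, one of them coupled to differential driver species.
OGTT 1-h glucose is intercept + 12 mg/dL × planted balance score + N(0, 8²)
noise; fasting and 2-h glucose are group-shifted Gaussians chosen so that
the IADPSG diagnosis reproduces the designed group membership for ~95% of
samples — the remaining discordance is deliberate label noise of the kind a
threshold diagnosis produces. With these defaults the balance analysis
lands in a cross-validated AUC ≈ 0.85–0.93 regime. Clinical covariates are
group-conditional Gaussians with means/SDs typical of published GDM vs NGT
cohorts; HOMA-IR is computed from the generated fasting glucose and insulin
by the standard HOMA1-IR formula (glucose[mmol/L] × insulin[µIU/mL] /
22.5, an external convention since no formula is canonical to this
analysis).

What the generator does **not** emulate: sequencing and profiling error,
compositional count noise (abundances are exact closures of the latent
draws), covariate confounding (age, BMI are independent of the microbiome),
batch effects, metabolite missingness, and longitudinal structure. Passing
recovery tests therefore demonstrates the statistical machinery is correct
and powered under clean planted signals, not that real cohorts of this size
would yield the same power.

## Numerical choices and problem sizes

Spearman p-values use the t-approximation throughout (|ρ| = 1 mapped to
p = 0). Eigenvector centrality comes from a dense symmetric
eigendecomposition; sign fixed to the non-negative orientation. The IRLS
logistic caps coefficients at ±30 to keep criteria finite under
separation. All stochastic stages take explicit integer seeds and are
bit-reproducible; derived seeds stay below 2³¹. Validation experiments in
the test suite run cohorts at 60 species with 20–30-taxon network
universes and 20-seed Monte-Carlo batches, sizes at which every recovery
regime reported above is already stable; the acceptance script runs the
primary cohort at the full 300-species scale.

## Known limitations

* Spearman co-occurrence on compositions is not compositionality-aware
  (SparCC/SPIEC-EASI-style methods are out of scope); negative bias from
  closure is mitigated only by restricting to top-abundance taxa.
* The rank-sum bootstrap comparison is intentionally descriptive; see the
  calibration discussion above.
* Balance search is greedy and returns one balance; it can miss jointly
  optimal sets that no greedy path reaches.
* The permutation-Shapley estimator's Monte-Carlo error scales as
  1/√(permutations); the efficiency correction redistributes residual noise
  uniformly, which slightly biases per-feature values at very low
  permutation counts.
* Genus-level analyses collapse species by summation without
  renormalization, so genus tables are sub-compositions.
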