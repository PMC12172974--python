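# Methods

## Graph features

Connectomes are symmetric Pearson-correlation matrices with a zero
diagonal. Negative edges are set to zero and all positive edges are
retained at their weights — no density threshold, no binarization.
Per node the pipeline computes within-module degree for positive edges
(MDP; summed positive weight to same-network nodes, deliberately *not*
z-scored within network so that between-participant differences are
preserved) and the participation coefficient for positive edges (PCP;
`1 − Σ_s (κ_is/k_i)²`). An isolated node (zero positive strength) gets
MDP = PCP = 0, the usual toolbox convention that avoids 0/0. PCP is
bounded by `1 − 1/M` for `M` networks; the looser informal claim that an
evenly-distributing node reaches 1 is not attainable under the standard
formula and is not used. The feature vector is all MDP values then all
PCP values (`mdp-then-pcp-v1` in file headers); models and importance
maps are only portable between files carrying the same ordering version.

`positive_part` is applied exactly once inside `build_feature_vector`;
the metric functions trust their input when called directly.

## Connectome construction

Nuisance removal is a single least-squares projection per parcel onto
the linear trend, all confound columns, a discrete-cosine high-pass
basis (default cutoff 0.008 Hz; order `⌊2·T·TR·f_c⌋`), and one spike
regressor per censored volume. Censoring uses framewise displacement
with a strict inequality (FD > 0.5 mm censored; FD exactly at threshold
kept). Spike regression followed by exclusion of censored volumes is
algebraically identical to deleting them first, and correlations are
computed over retained volumes only; a test asserts the equivalence to
1e-10. Participant retention requires a configurable number of runs
(default 2) with at least 4 minutes of retained data each. Correlations
are used as r values (no Fisher transform) by default.

## Sleep factor

Weekday/weekend durations collapse to a weekly average with calendar
weights 5/7 and 2/7. The three weekly indicators (parent report, youth
report, wearable) are standardized and fit with a one-factor
maximum-likelihood model (statsmodels); scores use the regression method
`f = Λᵀ R⁻¹ z` (pseudoinverse, so the perfectly collinear noise-free
case degrades gracefully; Bartlett scores are available) and are
re-standardized to mean 0, variance 1. Loading signs are fixed so the
mean loading is positive; the prediction target is the negated score
("sleep deficit"), asserted to correlate negatively with every raw
hours indicator. Estimation requires ≥ 50 complete cases; nonpositive
uniquenesses (Heywood) raise an error naming the indicator, while a
benign optimizer warning with finite estimates is tolerated —
hard-failing on the warning would reject degenerate-but-valid inputs
such as three identical indicators.

## Predictive model

Covariate control residualizes the *target* only (a switch for features
is not provided; standardization of features happens inside the model).
Per outer fold, the covariate model, feature means/SDs, PCA loadings and
the component count are estimated on training participants only. PCA is
the SVD of the standardized training features; the component regression
is OLS on the top-k scores (orthogonal, so coefficients are per-column
projections). The component count is selected by an inner
leave-one-site-out loop over training sites as the grid value maximizing
the pooled inner correlation, ties to the smaller k; the default grid is
{10, 25, 50, 75, 100, 150} capped at the training rank, and a global-k
mode bypasses selection. `r_cv` pools all held-out participants rather
than averaging per-site correlations; sites with fewer than two
participants are never held out (they still train) and are logged.

Feature importance is the Haufe pattern — covariance of each
standardized training feature with the model prediction, equal to the
feature covariance times the feature-space weight vector (asserted to
1e-8) — z-scored for export; sign interpretation uses the raw pattern.
Per-component contributions are correlations of the residualized target
with each component's scores; their argmax is the dominant component.
Stacking fits a second-level two-predictor OLS under the same LOSO
scheme.

## Permutation inference

Admissible relabelings shuffle individuals within families and exchange
whole families of identical size within sites; unequal-size families
never swap and nobody crosses sites. Twins are ordinary family members.
The target and its covariate rows are permuted together, so the null
preserves covariate–target coupling and tests the feature–target link
specifically. Each permutation re-runs residualization, inner k
selection, the component regression and the held-out evaluation; the
per-fold SVDs depend only on the features and are computed once — the
cached path is algebraically identical to naive recomputation and a test
pins the observed statistic to the standalone `loso_cv` result. The test
is one-sided (positive predictivity) with the add-one rule; `B ≥ 99` is
enforced and `B = 2000` is the default (at publication scale `p < 10⁻⁴`
requires `B ≥ 10⁴`).

Under the noise-only null the inner selection carries no information and
lands approximately uniformly on the grid; the ties-to-smaller-k rule
only bites on exact ties, which continuous data never produce.

## Component transport

A component is its unit-norm loading vector plus the deriving sample's
feature means/SDs. Projection standardizes new features with the
*deriving* moments then takes the dot product, keeping the component a
fixed instrument across samples. Signs are oriented so the
largest-magnitude coefficient is positive; similarities are reported
signed and sign-aligned.

## Association models

Each association is OLS of a standardized outcome on the standardized
expression score, covariates, and site fixed-effect indicators (most
frequent level as reference; singleton sites folded into the reference
with a warning). Mixed-effects site terms are out of scope. p-values are
classical two-sided t-tests, reported per outcome without
multiple-testing correction.

## Synthetic cohort generator

The generator emulates the *structure* of a multi-site, family-nested
developmental cohort at connectome level. Base matrices have mean edge
weight 0.35 within and 0.10 between networks, so positive-thresholding
removes a realistic minority of edges once noise (SD 0.06 per edge,
inflated with participant motion) and site shifts (SD 0.02) are added.
The planted motif adds `0.03 · effect_size · latent` to within-target
edges and subtracts it from target-to-rest edges; matrices are
symmetrized, clamped to [−1, 1], and zero-diagonal. The latent
sleep-deficit trait is standard normal plus covariate effects (age −0.1,
sex 0.1, motion 0.2 per SD); three hour-scale sleep indicators load on
it at (0.8, 0.7, 0.6) with noise SDs (0.60, 0.71, 0.80); context and
outcome phenotypes are linear in the latent trait with configurable
slopes. Family sizes are drawn from {1, 2, 3} with probabilities
(0.55, 0.35, 0.10); whole families go to the least-filled site. A single
seed fans out through spawned substreams keyed by participant index, so
cohorts reproduce bit-for-bit and participant `i`'s draw does not depend
on cohort size beyond `i`.

The ground-truth motif direction is the central-difference derivative of
the feature map at the base matrix, reported both in raw feature units
and — the comparable quantity for PCA components of standardized
features — divided by the cohort's feature SDs and renormalized.

What the generator does *not* emulate: fMRI time-series spectra, motion
artifact structure, spatial autocorrelation of edges, heavy-tailed edge
distributions, or realistic effect sizes — its signal-to-noise is
deliberately friendly so recovery checks are sharp. Passing tests show
the pipeline's statistical machinery is correct and calibrated, not that
real data would yield effects of this size (real multivariate
brain-phenotype correlations are an order of magnitude smaller).

## Problem sizes and numerical choices

Reference studies run at desk scale as the package's own study
conditions: planted-signal recovery uses 20 cohorts of n = 600 (6 sites,
60 nodes, 6 networks, effect size 0.5, grid {5, 10, 20, 40}); the
type-I-error study uses 200 null cohorts of n = 150 (5 sites, 30 nodes,
grid {5, 10}) at B = 199. Rank cut-off for the SVD is `S > S₁·1e-10`;
zero-SD features standardize with SD 1; correlations over fewer than two
points or against constant vectors return 0 inside CV pooling.
Determinism: the model fit has no internal randomness; all simulation
randomness flows from explicit seeds.

## Known limitations

- Covariate residualization of features (as opposed to the target) is
  not implemented; with strong feature-side confounding the importance
  maps can absorb covariate structure.
- The permutation scheme has no variance-group handling for
  heteroscedastic sites.
- The factor model is complete-case only.
- Site effects enter association models as fixed effects; random-effect
  or crossed designs are out of scope.
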