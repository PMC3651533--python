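# Methods

## The three-class selectivity measure

For a scalar marker and three classes with a declared clinical order
(healthy H < pancreatitis P < carcinoma C), the volume under the ROC
surface is

VUS = P(X < Y < Z),

with X, Y, Z drawn from the three classes. The empirical estimator
averages the ordering kernel over all n₁n₂n₃ cross-class triples.

**Tie handling.** Quantified concentration data contain ties, and the
estimator must remain calibrated under them: a triple with exactly one
ordering-consistent equality (x = y < z or x < y = z) contributes 1/2,
a triple tie 1/6, so a constant marker scores exactly the
random-classifier value 1/6. A `strict` mode (ties contribute 0) is
kept for sensitivity analysis. Internally the kernel is accumulated in
integer arithmetic (weights 6/3/1) so the vectorised rank-counting
implementation is bit-exact against brute-force triple enumeration.

**Orientation.** The class order is a declared input, never inferred:
markers that run against the clinical order legitimately score below
1/6 and are reported as such, mirroring how a published per-compound
VUS table contains sub-random entries.

**Confidence intervals.** Class-stratified bootstrap (each class
resampled within itself; B = 2000 by default) with percentile
intervals. Percentile rather than BCa is the default because it is the
simplest construction consistent with the downstream non-inferiority
CI; stratification also means no resample can empty a class. At the
study's cohort sizes (40/23/40) the measured coverage of the 95%
interval is ~0.95–0.96 (see the acceptance suite).

**ROC surface.** The surface grid enumerates all threshold pairs
c₁ ≤ c₂ over the pooled unique values with true class rates
(F̂₁(c₁), F̂₂(c₂) − F̂₂(c₁), 1 − F̂₃(c₂)). Numerically integrating
tcr₂ over the empirical (tcr₁, tcr₃) lattice reproduces the triplet
estimator to 1e-9 on tie-free data — the classical surface/probability
equivalence — and is tested as such. The
`grid_subdivisions` metadata field records the export resolution used
for external 3-D rendering; the VUS estimator itself is always the
exact empirical sum, never a smoothed approximation.

## Panel models

**Begg–Gray decomposition.** Each non-baseline class is fitted as a
binary logistic regression against the baseline class (healthy
controls; configurable), restricted to the samples of those two
classes. The total deviance is the sum of the binary deviances and
BIC = deviance + p·log(n) with n the full cohort size and p the total
free parameters (two blocks of k+1 each). The binary fits use
maximum-likelihood Newton iterations; on separation or non-convergence
the subset falls back to a lightly ridge-penalised fit and is flagged.
Rank-deficient subsets (duplicated columns) are rejected. At n = 1000
on an informative feature the decomposition's coefficients sit within
10% of the full multinomial MLE.

**Model averaging.** All subsets containing the forced-in features up
to `max_subset_size` (default 2, matching a strongly penalised
two-marker panel) are enumerated; subsets with
BIC ≤ BIC_min + 2·log(occam_ratio) (default ratio 20, standard Occam-
window practice) are retained and weighted by exp(−BIC/2),
renormalised. Averaged coefficients treat absent features as zero;
posterior inclusion probabilities are the summed weights of subsets
containing each feature. BIC of a logistic fit is invariant to affine
feature rescaling, so the weights are too (property-tested).

**Scalarisation.** A three-class probabilistic model must become one
scalar marker before VUS evaluation. The default scoring rule is the
expected ordinal class, Σ_c rank(c)·P̂(c) with ranks (0, 1, 2) along
the declared order — it respects the ordering the VUS needs and
reduces to a monotone transform of the feature for a single-feature
model (hence identical VUS, which is tested). Scoring by P(carcinoma)
is a one-line alternative via `predict_proba`.

**CAR scores.** The three classes are encoded by pseudo-metric
responses — carcinoma 1.0, healthy control 0.3, pancreatitis 0.1 by
default, exposed as configuration since any such encoding is partly
conventional. CAR = R_XX^(−1/2)·r_Xy decorrelates the marginal
correlations; features are ranked by squared CAR score, the top k
(default 2, comparable to the averaged two-marker panels) enter an OLS
fit whose linear predictor is the panel score. When the feature
correlation matrix is ill-conditioned (condition number above 1e6) it
is shrunk toward the identity by the smallest shrinkage intensity that
restores that bound; with `shrinkage=None` an ill-conditioned matrix
is a hard error. Under an exactly orthonormal design CAR equals the
marginal correlations, and on small instances it matches an
independent matrix-square-root oracle to 1e-10.

## Non-inferiority and superiority

Δ_VUS = VUS_candidate − VUS_reference is estimated on paired scores:
every outer bootstrap resample is drawn once per class and both
markers are evaluated on the identical resample (a candidate that is a
monotone transform of the reference therefore has Δ* ≡ 0 in every
resample — asserted in the tests). The (100 − 2δ)% CI is the
(δ, 1 − δ) percentile interval of the B_outer Δ* draws; with the
conventional absolute margin δ = 0.05 that is a 90% interval.
Decisions: non-inferiority iff CI_low > −δ; superiority (assessed
second) iff CI_low > 0. Boundary values use strict inequality, and
superiority implies non-inferiority by construction.

The nested inner bootstrap (B_inner, default 1000) is used only in the
optional `studentized` mode, which builds a bootstrap-t interval from
per-resample standard errors; the percentile construction is the
default because it is fully determined by the stated CI level. With
stratified resampling a degenerate (emptied-class) resample cannot
occur; the redraw guard is defensive only.

Measured at the exact margin (true Δ = −0.05, unit-variance normal
markers at cohort sizes 40/23/40, B_outer = 300), the non-inferiority
rate over 500 replicates is ~0.07 against the nominal 0.05 — the
usual mild anti-conservatism of percentile bootstrap intervals at
these sample sizes. The acceptance band [0.01, 0.10] reflects nominal
size ± Monte-Carlo error plus that finite-n distortion.

## Preprocessing

**Exclusion.** Samples whose count of missing metabolite features
exceeds a threshold are excluded outright (they represent non-random
missingness, e.g. insufficient sample volume) rather than imputed;
an exclusion that would leave a class below 2 samples is an error.

**Multiple imputation** of the reference marker: several chains
(default 3) iterate bootstrap refits of an OLS model of
log1p(marker) on class indicators plus standardised log-metabolites;
each iteration imputes prediction + resampled residual. Chains run
until the Gelman–Rubin R̂ of every imputed cell (second half of each
chain) is at or below the target (default 1.1) or `max_iterations` is
reached, in which case the result is flagged, never silently accepted.
The final value is the across-chain average; observed cells are never
altered. The iteration count at convergence is an outcome, not a
contract, and is reported as `iterations_used`. When the complete-case
count is small relative to the predictor count, the metabolite block
is reduced to the most marker-correlated columns to keep the OLS
identifiable.

**Yeo–Johnson** parameters are fitted per variable by profile maximum
likelihood, bracketed on λ ∈ [−5, 5]. The transform is strictly
increasing for every λ (property-tested), so all rank-based statistics
downstream (τ, VUS) are invariant to it — normalisation matters only
for the PCA and the descriptive tests.

**PCA** is performed on the correlation matrix of the transformed
metabolites (variables standardised first — concentrations live on
very different µmol/L scales, and only correlation PCA makes the
eigenvalue > 1 retention rule meaningful). Components are retained by
the Kaiser rule by default but `n_components` can override it; loading
signs are fixed so each component's largest-magnitude loading is
positive, making the decomposition deterministic.

## Univariate battery

Anderson–Darling composite normality uses the small-sample-adjusted
statistic and the standard piecewise-exponential P approximation
(verified to 1e-8 against R's `nortest::ad.test`). Variance
homogeneity uses the median-centred Fligner–Killeen test. Pairwise
group comparisons use Games–Howell: Welch-type statistics with
Satterthwaite degrees of freedom referred to the studentized-range
distribution with k groups; with k = 2 this reduces exactly to Welch's
t test, and under a heteroscedastic three-group null its familywise
type-I rate is the nominal 5% (measured 0.048 over 1000 replicates).
Raw pairwise P values are reported — the studentized-range reference
already embeds the familywise control. The gender split uses the exact
two-sided binomial test; the correlation analysis uses Kendall τ-b
(tie-corrected, appropriate after quantification rounding) with
Hochberg step-up adjustment over the single family of all metabolite
pairs.

## The synthetic cohort generator

The generator is the package's study-conditions definition, not a
tuning knob. Metabolite latents are multivariate normal with a
configurable correlation (default: a single-common-factor template
with mixed-sign loadings whose implied Kendall τ spans about −0.51 to
+0.71 via Greiner's relation τ = (2/π)·arcsin(ρ)); concentrations are
a fixed monotone map `scale_j · exp(0.4·z)` onto a physiological
µmol/L range. Because every selectivity measure downstream is
rank-based, the link choice is immaterial while the dependence targets
stay analytic. Class signal enters as latent location shifts: graded
monotone markers with gaps of 0.5–2 latent SD (theoretical VUS 0.34 to
0.84), one pancreatitis-specific spike (weakly ordered alone, VUS
below 1/6, but the decisive panel partner), a few mildly reversed
markers, and a null remainder — the mix a published per-compound VUS
table spans. The reference marker is log-normal per class (heavy
tailed, elevated mainly in carcinoma, theoretical three-class ordering
only modest), and missingness is MCAR on the reference marker only
(default 3%, matching a handful of missing values in ~100 samples);
non-random missingness is handled by exclusion, not simulated.

What the generator does *not* emulate: analytical (assay) noise and
per-metabolite CVs, batch/sample-set effects, covariate–metabolite
dependence, longitudinal structure, and non-Gaussian copulas. Passing
tests therefore demonstrate the correctness and calibration of the
statistical machinery under a known generative model, not clinical
performance on real sera. An analytical-noise layer can be grafted on
by widening `latent_scale`, but is deliberately off by default.

Cohort sizes default to 40/23/40 (healthy/pancreatitis/carcinoma),
the analyzed sizes after exclusion of incomplete pancreatitis samples.

## Numerical and design choices

- VUS kernels and their bootstrap use integer numerators (weights
  6/3/1) divided once, for bit-exact oracle agreement.
- Bootstrap CIs are clipped to bracket the point estimate (relevant
  only for degenerate resampling distributions).
- The studentized-range CDF comes from scipy's implementation
  (accuracy well beyond the 1e-6 needed here).
- Baseline class of the binary decompositions: healthy controls,
  configurable — the clinically natural reference.
- Hochberg family: all p(p−1)/2 metabolite pairs in one family,
  matching a single matrix-wide display.
- Pipeline stage seeds are spawned from the single run seed via
  `numpy.random.SeedSequence`, making the whole report bundle
  byte-identical across reruns; the manifest records all of them.
- Simulation sizes in the test suite (e.g. 500 replicates at B = 500
  for coverage, 500 replicates at B_outer = 300 for test size,
  100 seeds for model recovery) are chosen so Monte-Carlo error is
  small relative to the asserted bands while the whole suite stays
  fast.

## Known limitations

- The Begg–Gray BIC uses two overlapping binary likelihoods (the
  baseline class appears in both), a standard but approximate
  composite-likelihood construction; coefficients are consistent but
  not fully efficient relative to the joint multinomial MLE.
- Percentile bootstrap intervals are mildly anti-conservative at
  n ≈ 100 with a 23-sample middle class (see the measured
  non-inferiority size above); the studentized mode reduces but does
  not remove this.
- CAR pseudo-responses impose a metric geometry on the three classes;
  the defaults are conventional, not pathophysiologically derived, and
  should be treated as a sensitivity parameter.
- Subset enumeration in the model averaging is exhaustive; with many
  candidate features and large `max_subset_size` it grows
  combinatorially (at the default two-feature panels this is never a
  concern).
- Misclassification costs, partial VUS and smoothed/parametric VUS
  estimation are out of scope.
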