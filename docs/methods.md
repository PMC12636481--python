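# Methods

## The screening model

All analyses operate on log-scale abundances: aptamer-array values are
log10-transformed (they are approximately log-normal in relative
fluorescence units), immunoassay panels log2-transformed.  Associations are
ordinary least squares with the outcome and the predictor of interest
z-scored and adjustment covariates (age in years, sex code) left raw, so a
reported `beta_std` is the SD change in outcome per SD of predictor and is
comparable across analytes.  Multiple testing uses Benjamini-Hochberg
step-up q-values, corrected within one scan (one outcome, one subgroup,
all analytes).

Mediation follows the classical three-regression decomposition: a-path
(mediator on exposure), b-path and direct effect (outcome on mediator and
exposure jointly), total effect (outcome on exposure), all sharing the same
covariates and samples so that c = c′ + a·b holds as an algebraic identity.
The indirect effect a·b is the screening statistic.

### Bootstrap and BCa conventions

Inference on a·b uses case resampling: sample rows are drawn with
replacement and the a- and b-path regressions are refit per resample
(solved batch-wise via the normal equations; a resample whose Gram matrix
has eigenvalue ratio below 1e-10 is redrawn, up to five rounds, and an
error is raised if more than 20% of resamples stay rank-deficient).  The
BCa interval uses the bias term z0 = Φ⁻¹(#{boot < point}/B), clamped to
±Φ⁻¹(1 − 1/B) with a warning when the point estimate falls outside the
bootstrap range, and the jackknife third-moment acceleration; adjusted
quantiles are mapped through the empirical distribution by linear
interpolation (a nearest-rank variant is available via
`percentile="nearest-rank"`).  A constant bootstrap vector yields the
degenerate point interval with a warning.  The two-sided bootstrap p is
2·min(F(0), 1−F(0)).

Note that a *nontrivial* degenerate bootstrap cannot arise under case
resampling: the only data for which every resample returns the same a·b
have the mediator affine in the exposure, which makes the b-path design
singular.  The degenerate branch therefore only fires on genuinely
constant bootstrap vectors.

### E-values

The study variables are continuous, so the effect is converted to an
approximate risk ratio RR = exp(0.91·|β_std|) and
E = RR + sqrt(RR·(RR−1)); the CI E-value uses the interval bound nearer
the null and is 1 whenever the interval crosses zero.  This convention is
a package choice — effect sizes on other scales need their own mapping.

### Screen pass rule

Which conjunction of conditions constitutes "significant mediation" is a
genuinely open design point; the package adopts, and records in
`ScreenResult.criteria`:

* q(a-path) < FDR and q(b-path) < FDR, each corrected across the scanned
  analytes within one outcome screen (joint-significance gating controls
  the composite mediation null conservatively);
* the BCa interval of a·b excludes zero (interval level uncorrected,
  configurable);
* the bootstrap majority shares the sign of the point estimate;
* candidates must pass **every** outcome screen with one consistent
  indirect-effect sign, then re-pass against the PC1 composite of the
  outcome panel (validation), and — for replication — against each
  independent cohort's composite.

The bootstrap is only run for analytes that survive the q-value gates;
analytes failing the gates fail the conjunction regardless, so the
screen's result is unchanged and the cost drops by orders of magnitude.

## QC, missingness, imputation

Order of operations: QC filter (drop RowCheck/ColCheck flags) → log
transform → MCAR test on the immunoassay panel → multiple imputation →
analysis.  Imputation happens on the transformed scale, where the linear
model is assumed.  Whether imputation precedes or follows transformation
is not externally fixed; this order is a documented package decision.

Little's test estimates the grand mean and covariance by EM under a single
multivariate normal and sums, over missingness patterns, the Mahalanobis
distances of pattern-wise observed means, with df = Σp_j − p.  Singular
pattern covariances get a ridge of 1e-6·trace/p with a warning.  Rows with
no observed values are rejected.

The imputer is chained-equations linear regression: each incomplete column
(least missing first) is regressed on all others over its observed rows,
with bootstrap-resampled fits and residual-SD Gaussian noise added to
predictions as an approximate posterior draw.  Five independently seeded
imputations are generated ("5 iterations with different random states" is
read as five imputed datasets; the within-imputation cycle count is a
separate parameter, default 10 rounds with early stop when the largest
cell change falls below 1e-4).  The pooled table is the cell-wise mean —
a deliberate simplification of combining rules, adequate for downstream
point estimation; per-imputation tables are returned for anything needing
between-imputation variance.  Columns missing more than 40% of values are
mean-filled and excluded as regression targets (conservative default).
Observed cells are never altered.

Replicate CV is computed on raw-scale values: per duplicate pair,
sd/mean·100 with the n−1 denominator, averaged over pairs per analyte.

## Composites

Composite scores are PC1 of the z-scored member columns, i.e. the leading
eigenvector of the correlation matrix (consistent with standard-scaler
preprocessing).  The PC sign is arbitrary, so scores are oriented to
correlate nonnegatively with an anchor member — the pTau-like marker for
the outcome-panel composite, the largest-|loading| member by default —
which keeps downstream regression signs stable across runs.  Composites
are computed within-cohort, not on pooled data.

## Co-expression

The network is signed: a_ij = ((1 + cor_ij)/2)^β with β scanned over
15-26 and chosen as the smallest power whose scale-free fit R² (signed by
the negated slope) reaches 0.8, else the argmax.  The fit bins
connectivities into 10 **equal-width** bins and regresses log10 frequency
on log10 mean connectivity.  Equal-occupancy bins would force all
frequencies equal and make the regression degenerate, so they are not an
option here; exact-value grouping is used when there are few distinct
connectivities, which makes constructed power-law examples evaluate
exactly.

Topological overlap is TOM_ij = (Σ_u a_iu·a_uj + a_ij)/(min(k_i,k_j) + 1
− a_ij).  Modules come from average-linkage clustering of 1 − TOM with a
static height scan (a deliberate simplification of dynamic tree cutting):
every merge height is tried, the trivial one-cluster partition is skipped,
and the cut maximizing the number of qualifying modules wins (ties broken
toward more assigned analytes, then the finer cut).  A cluster qualifies
through per-member cohesion: a member stays only if its median overlap
with the other members exceeds background + 0.25·(max − background) of
the off-diagonal TOM, and the trimmed cluster must still reach the
minimum size (default 5).  Without the cohesion floor, a near-root cut
that sweeps unrelated analytes into one giant cluster would trivially win
the scan.  The floor makes detection conservative on matrices with no
real structure.

Module eigengenes are PC1 scores of the z-scored member submatrix,
oriented positively with the mean member profile; kME is each analyte's
correlation with each eigengene.  Cross-cohort preservation is the
Pearson correlation between the vectorized upper triangles of the
members' correlation matrices in the two cohorts — scale-invariant,
1 for identical co-expression structure, ~0 against independent data.
The permutation-based Z-summary family is out of scope.

## Cross-platform mapping

Concordance is Pearson r (Spearman behind a flag) between log-scale
values of paired analytes over matched samples, BH-corrected across
pairs; the concordance flag additionally requires r ≥ 0.3 (configurable
floor).  Surrogates are chosen from a user-supplied candidate pool by
maximal |r| with lexicographic tie-break.  The matched-null sensitivity
analysis operationalizes "matched on expression level and abundance
parameters" as joint decile bins on the mean and variance of the
platform's transformed values — computed from platform-internal
statistics only, so the target never leaks into pool construction.  Bins
widen with a warning until the pool reaches 20 analytes.  The empirical p
uses the add-one convention (1 + #{null ≥ observed})/(B + 1) and is never
zero.

## Cell-type mapping

Counts are depth-normalized to counts-per-10k per cell; per gene and cell
type, log2FC = log2((μ_type + ε)/(μ_rest + ε)) with ε = 1e-9, and the
expressing fraction comes from raw counts > 0.  No test statistic is
attached — the mapping reports effect sizes and percentages.  A gene
absent from the matrix is reported not-detected rather than raising
(secreted proteins often have no brain transcript).  For composite
filtering, a mediator maps to the cell type with maximal log2FC among
types where at least 10% of cells express it.

## The synthetic cohort generator

The generator is the package's study stand-in: linear-Gaussian structural
equations on the log scale, exponentiated to raw abundances so the
documented transforms recover Gaussian values exactly.

* Exposure: confounder loadings (age_effect·age_z + sex_effect·sex_c)
  plus unit noise.  One analyte is the designated exposure and is excluded
  from the mediator scan by id.
* Mediators: a_effect·exposure + the same confounder terms +
  mediator-specific noise.
* Latent outcome: (b_effect/√k)·Σ mediators + c′·exposure + confounders +
  outcome noise; the 4-marker panel loads on this factor with
  equicorrelation ρ = (p·λ − 1)/(p − 1) chosen so PC1 explains the
  configured share λ (default 0.85).  The factor is standardized by the
  *model-implied* (analytic) SD, not the sample SD, so zero-noise
  configurations identify the recorded coefficients exactly.
* Null analytes: planted equicorrelated modules (shared factor) plus free
  standard-normal analytes.
* Duplicate aliquots multiply raw values by lognormal error with log-SD
  (cv/100)·√π, calibrated so the expected two-aliquot sample CV equals
  the target percentage.
* Missingness is Bernoulli per cell (MCAR by construction, mask returned);
  one MAR scenario (missingness driven by an observed column) exists to
  exercise the MCAR test's power.
* Cohorts share all structural coefficients and differ in samples and
  noise; a second platform re-measures chosen analytes as
  r·z + √(1−r²)·noise on the standardized log scale.

Default sizes (200 samples, 300 analytes, 5 mediators, a = b = 0.5,
c′ = 0.2, age/sex loadings 0.3/0.2) are desk-scale stand-ins for matrices
of ~7,000 analytes and 66-1,655 donors; everything scales through the
config.  The noise defaults (mediator noise SD 1.5, latent-outcome noise
SD 0.5) were set so that the nominal standardized paths of 0.5 operate in
a realistic, high-power regime: the exposure explains ~10% of each
mediator's variance (analyte-specific variance dominates, as in real CSF
proteomics), and the per-mediator partial correlation with a marker is
~0.25-0.3 at N = 300.  Much smaller mediator-specific variance makes the
mediators near-collinear with the exposure and starves the b-path of
identifying variation.

What the generator does **not** emulate: batch and plate effects, vendor
normalization artifacts, MNAR mechanisms, heavy-tailed or skewed residuals
on the log scale, correlated missingness, non-linear dose-response, and
amyloid status is independent of everything by construction (an
amyloid-independence null).  Passing tests therefore demonstrate
correctness and calibration of the statistical machinery under the
declared model, not robustness to those real-data pathologies.

## Problem sizes and numerical tolerances in the checks

The test suite and acceptance script run the screens at 100-200 analytes
and 150-300 samples with 200-500 bootstrap iterations — large enough for
the calibration targets (coverage bands, FDR budgets, ≥0.8 sensitivity)
while keeping the whole suite in tens of seconds.  Exact identities
(c = c′ + a·b, transforms, hand examples) are asserted at 1e-6 to 1e-12;
Monte-Carlo quantities at the bands their sampling error supports (for
example, BCa coverage in [0.93, 0.97] over 1,000 simulations; spiked-panel
PC1 share within ±0.03 of the equicorrelation eigenvalue *on average* over
100 seeds, since single-draw eigenvalue shares fluctuate by ~±0.04 at
n = 300).

## Known limitations

* Counterfactual mediation estimands (natural direct/indirect effects
  under exposure-mediator interaction) are out of scope; the screen is the
  classical product-of-coefficients under linearity and no interaction.
* Mean-pooling of imputations understates between-imputation variance;
  use the per-imputation tables when that matters.
* The static height-scan module cut is coarser than dynamic tree cutting
  and conservative near the cohesion floor.
* E-values use one fixed continuous-outcome convention.
* The amyloid stratification thresholds (SUVR ≤ 1.32, Centiloids < 25)
  are configuration defaults for consuming continuous measures, not
  validated cut-points.
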