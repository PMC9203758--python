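# Methods

## The latent factor model

For a z-scored continuous trait measured in mothers (M), fathers (F) and
children (C) we assume

    Y_k = α P_k + β G_k + ε_k,   k ∈ {M, F, C},

where `P` is the standardized genetic component captured by a polygenic
risk score, `G` an independent standardized latent component (unmeasured
common variation, rare variants, non-additive effects, inherited
exposures), and `ε` the non-genetic residual.  `α, β ≥ 0` are assumed
equal across generations; total heritability is `h² = α² + β² ≤ 1`.
Each component has parent–child covariance 1/2 (Mendelian transmission),
zero spousal covariance (no assortative mating, no consanguinity), and
`P ⟂ G` (orthogonality).  These assumptions give the joint normal
distribution of `(Y_C, Y_M, Y_F, P_C)` with

    Cov(Y_C, Y_M/F) = h²/2,  Cov(Y_C, P_C) = α,  Cov(Y_M/F, P_C) = α/2,

from which everything else follows:

* **Mid-parental variance explained.** The regression of the child trait
  on `(Y_M + Y_F)/2` has population R² equal to `(h²)²/2`.  Inverting,
  `h² = √(2·R²_mid)` and the under-captured fraction is
  `β² = √(2·R²_mid) − R²_PRS`.  Summary statistics implying `h²` outside
  `[R²_PRS, 1]` are mutually incompatible under the model and raise a
  diagnostic error rather than being clamped (clamping is applied only
  within 1e−6 of a bound, as numerical noise).  A single-parent variant
  (`R²_single = (h²/2)²`, so `h² = 2·√R²_single`) is provided for the case
  where only one parent's association is published; it is an extrapolation
  of the same algebra and is labelled as such.
* **Joint predictors.** Predictors are conditional expectations under the
  joint normal: with both parents, weights solve the 3×3 system
  `A w = c` with `A = Cov(Y_M, Y_F, P_C)` and `c = Cov(Y_C, (Y_M,Y_F,P_C))`;
  with one parent the analogous 2×2 system; with neither, `E[Y_C|P_C] =
  α·p`.  Missing parents change the conditioning set (never imputed as
  zero — mean imputation would silently change the weights).  Systems are
  solved directly (`numpy.linalg.solve`), not by explicit inversion.  The
  population R² of the joint predictor, `cᵀA⁻¹c`, is exposed so simulated
  performance can be checked against its closed form.

## Binary diseases

Disease status is Bernoulli given the genetic liability `H = αP + βG`
through a **logit** link:

    Pr(Z = 1 | H = h, Q = q) = expit(μ₀ + h + γq),

with measured covariates `q` (e.g. age, sex) and baseline log-odds `μ₀`
at the covariate reference.  The logit link (rather than the probit of
classical liability-threshold models) lets every parameter be read off
standard logistic regressions.  `α` and `β` are unconstrained above zero.
Heritability fractions are still reported on the liability scale via the
probit-shift approximation

    τ = d / √(1 + d²),  d = Φ⁻¹(F_L(μ₀ + effect)) − Φ⁻¹(F_L(μ₀)),

where `F_L` is the logistic CDF with variance π²/3 and the component has
unit variance; `τ²` is the liability-scale heritability contribution.

* **Theoretical parent–child odds ratio.** `(H_C, H_parent)` is bivariate
  normal with variances `h²` and covariance `h²/2`.  The four joint
  probabilities `f(Z_C, Z_parent)` are integrals of the two Bernoulli
  kernels against that density, computed on a Gauss–Hermite tensor grid
  (default 64 nodes per dimension, after a Cholesky transform); their
  cross ratio is the model-implied OR.  Convergence was checked by node
  doubling (64 vs 128 nodes agree to ~1e−8 relative).  `h² = 0` is
  handled as the independence limit (OR = 1).  Maternal and paternal ORs
  differ only through the parental covariate vector (a sex covariate is
  fixed by the parent role).
* **Line search for β.** Observed parental-history ORs are inverted by
  locating the root of the signed sum of maternal and paternal log-OR
  discrepancies on `β ∈ [0, 5]` (configurable), by bracketed root-finding
  to 1e−4.  The theoretical log OR is strictly increasing in β, so the
  root is unique, and it is exactly the minimizer of the absolute
  signed-sum objective.  We deliberately do **not** minimize the sum of
  absolute per-parent errors: between the two per-parent roots that
  objective is numerically flat (the two discrepancy slopes nearly
  cancel), and a generic scalar minimizer returns an essentially
  arbitrary point of the valley; the signed-sum root always lies inside
  the same valley and is well conditioned.  Quadrature settings are held
  fixed across evaluations, so the estimate is deterministic.  Observed
  ratios at or below the β = 0 theoretical values yield β̂ = 0; a
  discrepancy still positive at the bracket end raises an error
  suggesting a larger bracket.
* **Joint liability predictor.** The target is `E[H_C | Z_M, Z_F, P_C]`.
  Each observed parent's posterior liability `f(H|Z)` is sampled by
  importance sampling with the prior `N(0, h²)` as proposal, so the prior
  density cancels and the self-normalized weights are the Bernoulli
  likelihood of the observed status alone; log-weights are shifted by
  their maximum before exponentiation (stable for rare diseases).  The
  inner conditional mean given parental liabilities and the child PRS is
  linear, so the average over L draws reduces to the same linear form at
  the weighted posterior means, and one weighted sample set per
  `(z_M, z_F)` cell serves an entire cohort exactly — this grouping is an
  identity, not an approximation.  The Monte-Carlo SE combines the
  per-parent self-normalized importance-sampling variances through the
  linear weights and is always reported; an effective sample size below a
  configurable floor (default 100) flags a warning rather than raising.
  Default L = 1,000,000, configurable.  With no parental history the
  predictor is the exact closed form `α·p_C` (no sampling).

### Parental covariates

The Bernoulli kernels for parents require parental covariate values,
which are typically unobserved apart from sex.  By default parents are
assigned the covariate reference vector (zeros after centering) with the
sex entry fixed by the parent role; the reference is configurable.  This
is a modelling decision, not an estimate: marginalizing over a parental
covariate distribution is an alternative the implementation does not
attempt.

## Estimation from individual-level tables

The training recipe is two marginal regressions, mirroring how such
parameters are obtained in biobank training subsets:

1. logistic (or OLS) fit of child outcome on PRS plus covariates →
   `α̂` (log-OR per SD), `μ̂₀`, `γ̂`;
2. logistic fit of child status on maternal and paternal history (two
   indicators) plus covariates → observed OR_M, OR_F — or OLS of child
   z-score on the mid-parental z-score for continuous traits.

Continuous covariates are centered at their training means (recorded with
the fitted parameters) so the intercept is the baseline log-odds at the
covariate reference; sex keeps its 0/1 coding with reference 0.  Fits are
plain maximum likelihood (statsmodels IRLS/Newton, deviance tolerance
1e−8, no regularization); separation or non-convergence raises an
estimation error.  Note that a marginal logistic `α̂` is mildly attenuated
relative to the structural `α` (non-collapsibility of the odds ratio: the
unmodelled `βG` acts as heterogeneity), and `β̂` inherits a small
compensating shift — the benchmark recovery bands below absorb this.  A
seeded train/test split helper defaults to 10%/90%.

## The trio simulator

The simulator draws parental components `P_M, P_F, G_M, G_F` iid standard
normal and builds child components as the mid-parental mean plus an
independent `N(0, 1/2)` segregation residual, which reproduces the exact
covariance algebra (unit variances, parent–child covariance 1/2, spousal
covariance 0) without simulating loci — a per-locus simulator would add
nothing, because the model is defined on components.  Traits add a
residual of variance `1 − h²`; liabilities are `αP + βG` and statuses are
Bernoulli through the logit link.  Default covariates, when enabled,
loosely mirror a middle-aged population cohort (age uniform 40–69, sex
balanced, parental sex fixed by role); all configurable.  Latent columns
are written only behind an explicit flag so files can serve as blind
inputs.  What the simulator deliberately does **not** emulate: assortative
mating, P–G correlation (e.g. gene–environment interaction leaking into
the PRS), age-dependent onset, misclassified family history, and
ancestry/portability effects.  Tests passing on simulated data therefore
validate the machinery and the model's internal consistency, not the
model's adequacy for any real cohort.

## Evaluation metrics

R² is the squared Pearson correlation (a constant predictor scores 0 by
convention); RMSE multiplies residuals by an original-scale SD, optionally
per stratum (e.g. sex-stratified height SDs).  AUROC uses the
Mann–Whitney statistic with midrank ties; AUPRC is step-wise average
precision.  DeLong's paired test uses the structural-components
covariance estimate; degenerate variance reports p = 1 with a flag.  NRI
classifies individuals strictly above each score's own within-sample
percentile as high risk (ties break low; a cut-off leaving an empty
high-risk class is flagged undefined).  IDI needs probabilities, and
liability scores are not probabilities, so each score passes through a
one-dimensional logistic recalibration first; IDI is therefore invariant
under affine, not arbitrary monotone, transforms.

## Benchmark problem sizes and tolerances

The package's own end-to-end checks run at: 200,000 simulated trios for
the continuous R² agreement (±0.01 against the closed form, ±0.005
against in-sample OLS) and for disease parameter recovery (α within
±0.03, β within ±0.05 — roughly 2.5 SD of the estimator's sampling
distribution at this n, so an unlucky seed can legitimately miss);
L = 100,000 importance draws against an 801-node tensor-grid quadrature
oracle (agreement within 3 Monte-Carlo SE) over a 3×3×3 grid of
(μ₀, α, β); 100,000 held-out trios for the discrimination-ordering check
(joint predictor above PRS-only on AUROC and IDI, positive NRI at the
95th percentile); and a 10,000-draw paired permutation oracle for DeLong's
test.  These sizes keep every check well-resolved while the whole suite
runs in minutes on one core.

## Known limitations

* The model assumes `P ⟂ G`, no assortative mating, effects constant
  across generations, and (for diseases) lifetime-risk-like parental
  history with no age-at-onset structure; violations bias `β²` in ways the
  package does not correct.
* The parental-history posterior conditions each parent's liability only
  on that parent's own status (the factorization used by the predictor);
  the child's PRS is not fed back into the parental posteriors.
* Only parents are modelled; siblings and second-degree relatives would
  need their own covariance structure.
* Single-parent summary inversion is an extrapolation (see above).
* Predicted liabilities are scores, not calibrated absolute risks;
  absolute-risk statements require the recalibration step used for IDI or
  an external baseline hazard.
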