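# famprs

**Joint genetic risk prediction from polygenic risk scores and family
history under a latent factor model.**

Polygenic risk scores (PRS) capture only part of the heritability of
complex traits and diseases; parental phenotypes or disease history carry
information about the rest — rare variants, unmeasured common variation,
epistasis, inherited exposures.  `famprs` implements a latent factor model
that makes this precise and turns it into predictors:

* A z-scored trait is decomposed as `Y = αP + βG + ε`, where `P` is the
  standardized genetic component captured by a PRS, `G` an orthogonal
  latent component, and both are transmitted from parents to children with
  covariance 1/2.  The captured heritability is `α²`, the under-captured
  heritability `β²`, and the mid-parental value explains `(α²+β²)²/2` of
  the child trait variance — which can be inverted to estimate `β²` from
  published summary statistics alone: `β² = √(2·R²_midparent) − R²_PRS`.
* For binary diseases, status is Bernoulli with a logit link on the
  genetic liability, `Pr(Z=1) = expit(μ₀ + αP + βG + γq)`.  Theoretical
  parent–child odds ratios follow by quadrature over the bivariate normal
  liability, and `β` is recovered from observed parental-history odds
  ratios by a monotone line search.  The joint risk predictor
  `E[H_C | Z_M, Z_F, P_C]` is computed by importance sampling of each
  parent's posterior liability given their disease status.

Both predictors need **no individual-level training data**: the inputs are
association summary statistics from reference cohorts (variance fractions,
odds ratios), after which predictions require only a person's PRS and
their parents' measures or history.  The package also fits those summary
statistics from individual-level tables, simulates parent–child trios with
exactly the model's covariance structure, and evaluates predictors with
AUROC/AUPRC, DeLong's paired test, net reclassification improvement (NRI)
and integrated discrimination improvement (IDI).

Intended users: statistical geneticists and epidemiologists building or
benchmarking PRS + family-history risk models.

## Worked example

Height-like summary statistics — a PRS explaining 36.7% of trait variance
and a mid-parental z-score explaining 44.9%:

```python
from famprs import ContinuousFamilyModel

res = ContinuousFamilyModel.from_summary(r2_prs=0.367, r2_midparent=0.449).fit()
print(res.summary())
```

```
================== Continuous family model ===================
captured heritability alpha^2                0.3670
under-captured heritability beta^2           0.5806
total heritability h^2                       0.9476
input R^2 (PRS)                              0.3670
input R^2 (mid-parental)                     0.4490
expected R^2, joint (both parents)           0.5734
expected R^2, joint (single parent)          0.4598
==============================================================
```

Reading: 58.1% of the trait variance is heritable but not captured by the
PRS, and a predictor combining the PRS with both parents' measures is
expected to explain 57.3% of the variance — versus 36.7% for the PRS
alone.  `res.predict(frame)` then scores individuals, dispatching on
whether both, one, or neither parent is measured.

A disease model from odds-ratio summary statistics, and predictions for
three children:

```python
import pandas as pd
from famprs import DiseaseFamilyModel

res = DiseaseFamilyModel.from_summary(
    or_prs_per_sd=1.35, or_maternal_history=1.30, or_paternal_history=1.27,
    baseline_log_odds=-2.0).fit()

frame = pd.DataFrame({"id": ["A", "B", "C"], "prs": [1.0, 1.0, 0.0],
                      "mother_status": [0, 1, 1], "father_status": [0, 1, None]})
print(res.predict(frame, L=200_000, seed=1).to_string(index=False))
```

```
id    value    mc_se     pattern
 A 0.090402 0.001055        both
 B 0.588772 0.001375        both
 C 0.204706 0.000933 mother_only
```

`value` is the predicted genetic liability `E[H_C | Z_M, Z_F, P_C]`:
child B, with the same PRS as child A but two affected parents, is
assigned a much higher liability; child C's missing father is handled by
the single-parent conditional expectation, never by imputation.  `mc_se`
is the Monte-Carlo standard error of the importance-sampling average.

The same workflows are available from the shell via the `famprs` console
script (`simulate`, `estimate`, `predict`, `evaluate` subcommands driven
by a YAML config; see `famprs --help`).

## Layout

| Module | Contents |
| --- | --- |
| `famprs.model` | `ContinuousFamilyModel` / `DiseaseFamilyModel` and their Results objects |
| `famprs.gaussian` | trio covariance, summary inversion, conditional-expectation trait predictors |
| `famprs.liability` | logit-link liability model: OR quadrature, line search, importance-sampling predictor |
| `famprs.estimation` | marginal OLS/logistic fits, summary-statistic inversion, train/test split |
| `famprs.simulate` | trio simulator with Mendelian component transmission and known ground truth |
| `famprs.metrics` | R²/RMSE, AUROC/AUPRC, DeLong's test, NRI, IDI |
| `famprs.io`, `famprs.cli` | TSV trio tables, YAML config, console script |

See `docs/methods.md` for the model, its assumptions, and the numerical
choices.
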