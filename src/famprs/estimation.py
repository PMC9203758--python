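"""Model parameter estimation from summary statistics or training tables.

Two routes lead to a fitted model.  Summary statistics from well-powered
reference studies (variance fractions for continuous traits; odds ratios
for diseases) are inverted in closed form or by line search.  Alternatively
an individual-level training table is reduced to exactly those summary
statistics by two marginal regressions - child outcome on PRS plus
covariates, and child outcome on maternal and paternal history plus
covariates - mirroring how such parameters are estimated in biobank
training subsets, after which the same inversion applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gaussian import estimate_beta_sq_from_midparent
from .liability import LineSearchResult, estimate_beta_line_search, parent_reference_covariates
from .params import BinaryParams, ContinuousParams

__all__ = [
    "SummaryInputs",
    "EstimationError",
    "params_from_summary",
    "fit_marginal_continuous_models",
    "fit_marginal_binary_models",
    "split_train_test",
]


class EstimationError(RuntimeError):
    """A regression failed to converge or the inputs cannot be fitted."""


@dataclass
class SummaryInputs:
    """Summary statistics sufficient to fit either trait type.

    Exactly one of ``continuous`` / ``binary`` is populated.  The
    continuous block holds ``r2_prs`` and ``r2_midparent``; the binary
    block holds ``or_prs_per_sd``, ``or_maternal_history``,
    ``or_paternal_history``, ``baseline_log_odds`` and per-covariate
    ``covariate_effects``.  ``covariate_reference`` records the covariate
    values at which the baseline log-odds applies.
    """

    continuous: dict | None = None
    binary: dict | None = None
    covariate_reference: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.continuous is None) == (self.binary is None):
            raise ValueError("exactly one of continuous/binary must be populated")
        if self.continuous is not None:
            for key in ("r2_prs", "r2_midparent"):
                v = self.continuous.get(key)
                if v is None or not 0.0 <= v <= 1.0:
                    raise ValueError(f"continuous summary {key} must lie in [0, 1], got {v}")
        else:
            for key in ("or_prs_per_sd", "or_maternal_history", "or_paternal_history"):
                v = self.binary.get(key)
                if v is None or v <= 0:
                    raise ValueError(f"binary summary {key} must be a positive odds ratio, got {v}")
            if "baseline_log_odds" not in self.binary:
                raise ValueError("binary summary requires baseline_log_odds")


def params_from_summary(
    inputs: SummaryInputs, **line_search_kwargs
) -> ContinuousParams | BinaryParams | tuple[BinaryParams, LineSearchResult]:
    """Invert summary statistics to model parameters.

    Continuous: ``alpha**2 = r2_prs`` and ``beta**2`` from the mid-parental
    inversion; returns :class:`ContinuousParams`.

    Binary: ``alpha = log(or_prs_per_sd)``, baseline log-odds and covariate
    effects pass through, and ``beta`` is found by the odds-ratio line
    search; returns ``(BinaryParams, LineSearchResult)``.
    """
    if inputs.continuous is not None:
        beta_sq, alpha_sq = estimate_beta_sq_from_midparent(
            inputs.continuous["r2_prs"], inputs.continuous["r2_midparent"]
        )
        return ContinuousParams.from_variance_fractions(alpha_sq, beta_sq)

    b = inputs.binary
    alpha = float(np.log(b["or_prs_per_sd"]))
    mu0 = float(b["baseline_log_odds"])
    effects = b.get("covariate_effects", {})
    covariates = tuple(effects)
    gamma = tuple(float(effects[k]) for k in covariates)
    probe = BinaryParams(mu0=mu0, alpha=alpha, beta=0.0, gamma=gamma, covariates=covariates)
    q_m = parent_reference_covariates(probe, "mother")
    q_f = parent_reference_covariates(probe, "father")
    q_c = np.zeros(len(covariates)) if covariates else None
    result = estimate_beta_line_search(
        or_m_observed=b["or_maternal_history"],
        or_f_observed=b["or_paternal_history"],
        mu0=mu0,
        alpha=alpha,
        gamma=gamma,
        covariates=covariates,
        q_child=q_c,
        q_mother=q_m,
        q_father=q_f,
        **line_search_kwargs,
    )
    params = BinaryParams(
        mu0=mu0, alpha=alpha, beta=result.beta, gamma=gamma, covariates=covariates
    )
    return params, result


def fit_marginal_continuous_models(table: pd.DataFrame) -> SummaryInputs:
    """OLS variance fractions of child trait on PRS and on mid-parental value.

    ``r2_prs`` uses every row with PRS and child phenotype; ``r2_midparent``
    uses rows where both parents are measured.  All columns are assumed
    z-scored.
    """
    needed = {"pheno", "prs", "mother_pheno", "father_pheno"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"training table lacks columns {sorted(missing)}")
    prs_rows = table.dropna(subset=["pheno", "prs"])
    trio_rows = table.dropna(subset=["pheno", "mother_pheno", "father_pheno"])
    if len(prs_rows) < 3 or len(trio_rows) < 3:
        raise ValueError("fewer than 3 complete rows for a regression")
    r2_prs = _ols_r2(prs_rows["pheno"].to_numpy(), prs_rows["prs"].to_numpy())
    midparent = (trio_rows["mother_pheno"].to_numpy() + trio_rows["father_pheno"].to_numpy()) / 2.0
    r2_mid = _ols_r2(trio_rows["pheno"].to_numpy(), midparent)
    return SummaryInputs(continuous={"r2_prs": r2_prs, "r2_midparent": r2_mid})


def _ols_r2(y: np.ndarray, x: np.ndarray) -> float:
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.rsquared)


def fit_marginal_binary_models(
    table: pd.DataFrame, covariates: tuple[str, ...] = ()
) -> SummaryInputs:
    """The two marginal logistic fits behind the disease summary statistics.

    (i) ``status ~ PRS + covariates`` gives the PRS log-odds effect, the
    baseline log-odds and covariate effects; continuous covariates are
    centered at their training means (recorded in ``covariate_reference``)
    so the intercept is the log-odds at the covariate reference, with sex
    left on its 0/1 coding (reference level 0).
    (ii) ``status ~ maternal history + paternal history + covariates``
    gives the two parental-history odds ratios.
    """
    needed = {"status", "prs", "mother_status", "father_status"} | set(covariates)
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"training table lacks columns {sorted(missing)}")
    if table["mother_status"].isna().all() or table["father_status"].isna().all():
        raise ValueError("parental status columns are entirely missing")

    reference: dict[str, float] = {}
    centered = {}
    for name in covariates:
        col = table[name].astype(float)
        if name == "sex" or set(col.dropna().unique()) <= {0.0, 1.0}:
            reference[name] = 0.0
            centered[name] = col
        else:
            ref = float(col.mean())
            reference[name] = ref
            centered[name] = col - ref

    rows_prs = table.dropna(subset=["status", "prs"] + list(covariates))
    X1 = np.column_stack(
        [rows_prs["prs"].to_numpy()] + [centered[c].loc[rows_prs.index].to_numpy() for c in covariates]
    )
    fit1 = _logit_fit(rows_prs["status"].to_numpy(float), X1)
    mu0 = float(fit1.params[0])
    alpha_hat = float(fit1.params[1])
    gamma_hat = {c: float(fit1.params[2 + i]) for i, c in enumerate(covariates)}

    rows_fh = table.dropna(subset=["status", "mother_status", "father_status"] + list(covariates))
    X2 = np.column_stack(
        [
            rows_fh["mother_status"].to_numpy(float),
            rows_fh["father_status"].to_numpy(float),
        ]
        + [centered[c].loc[rows_fh.index].to_numpy() for c in covariates]
    )
    fit2 = _logit_fit(rows_fh["status"].to_numpy(float), X2)
    or_m = float(np.exp(fit2.params[1]))
    or_f = float(np.exp(fit2.params[2]))

    return SummaryInputs(
        binary={
            "or_prs_per_sd": float(np.exp(alpha_hat)),
            "or_maternal_history": or_m,
            "or_paternal_history": or_f,
            "baseline_log_odds": mu0,
            "covariate_effects": gamma_hat,
        },
        covariate_reference=reference,
    )


def _logit_fit(y: np.ndarray, X: np.ndarray):
    # plain maximum-likelihood logistic regression (IRLS via statsmodels)
    model = sm.Logit(y, sm.add_constant(X, prepend=True))
    try:
        fit = model.fit(disp=False, maxiter=100, tol=1e-8)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise EstimationError(f"logistic regression failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise EstimationError(
            "logistic regression did not converge: "
            f"{fit.mle_retvals.get('iterations', '?')} iterations"
        )
    return fit


def split_train_test(
    table: pd.DataFrame, train_frac: float = 0.1, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded split into a small training subset and a large test remainder.

    Defaults to a 10%/90% split, the usual proportion when parameters are
    estimated on a biobank training subset and evaluated on the remainder.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(table)
    n_train = int(round(train_frac * n))
    idx = rng.permutation(n)
    train = table.iloc[idx[:n_train]].reset_index(drop=True)
    test = table.iloc[idx[n_train:]].reset_index(drop=True)
    return train, test
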