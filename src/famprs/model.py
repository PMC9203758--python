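"""Model and Results objects tying estimation, prediction and simulation together.

The public entry points follow the familiar modelling-package idiom: a
model object is constructed from data (``from_summary`` for published
summary statistics, ``from_dataframe`` for an individual-level training
table), ``fit()`` performs the estimation and returns a results object
carrying the parameter estimates, diagnostics and a ``summary()`` table,
and prediction/simulation hang off the results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import estimation, gaussian, liability, simulate
from .estimation import SummaryInputs
from .params import BinaryParams, ContinuousParams

__all__ = [
    "ContinuousFamilyModel",
    "ContinuousFamilyResults",
    "DiseaseFamilyModel",
    "DiseaseFamilyResults",
]


def _rule(title: str, width: int = 62) -> str:
    pad = width - len(title) - 2
    return "=" * (pad // 2) + f" {title} " + "=" * (pad - pad // 2)


class ContinuousFamilyModel:
    """Latent factor model for a z-scored continuous trait.

    Construct with :meth:`from_summary` (variance fractions explained by
    the PRS and by the mid-parental value) or :meth:`from_dataframe` (a
    training table with ``pheno``, ``prs``, ``mother_pheno``,
    ``father_pheno`` columns); then call :meth:`fit`.
    """

    def __init__(self, summary: SummaryInputs | None = None, data: pd.DataFrame | None = None):
        if (summary is None) == (data is None):
            raise ValueError("supply exactly one of summary statistics or a training table")
        self.summary_inputs = summary
        self.data = data

    @classmethod
    def from_summary(cls, r2_prs: float, r2_midparent: float) -> "ContinuousFamilyModel":
        return cls(summary=SummaryInputs(continuous={"r2_prs": r2_prs, "r2_midparent": r2_midparent}))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "ContinuousFamilyModel":
        return cls(data=data)

    def fit(self) -> "ContinuousFamilyResults":
        summary = self.summary_inputs
        if summary is None:
            summary = estimation.fit_marginal_continuous_models(self.data)
        params = estimation.params_from_summary(summary)
        return ContinuousFamilyResults(model=self, params=params, summary_inputs=summary)


@dataclass
class ContinuousFamilyResults:
    """Fitted continuous-trait model: estimates, expected performance, predictors."""

    model: ContinuousFamilyModel
    params: ContinuousParams
    summary_inputs: SummaryInputs

    @property
    def alpha_sq(self) -> float:
        """Heritability fraction captured by the PRS."""
        return self.params.alpha**2

    @property
    def beta_sq(self) -> float:
        """Under-captured heritability fraction, inferable from parents."""
        return self.params.beta**2

    @property
    def h2(self) -> float:
        return self.params.h2

    def expected_r2_midparent(self) -> float:
        return gaussian.expected_r2_midparent(self.params)

    def expected_r2_joint(self, mode: str = "both") -> float:
        return gaussian.expected_r2_joint(self.params, mode)

    def predict(self, data: pd.DataFrame) -> pd.DataFrame:
        """Per-row conditional-expectation trait predictions.

        Accepts a frame with ``prs`` and optional ``mother_pheno`` /
        ``father_pheno`` columns (``NaN`` = unavailable) and returns a
        frame with the predicted z-score and the availability pattern that
        selected the predictor.
        """
        n = len(data)
        y_m = data["mother_pheno"].to_numpy(float) if "mother_pheno" in data else np.full(n, np.nan)
        y_f = data["father_pheno"].to_numpy(float) if "father_pheno" in data else np.full(n, np.nan)
        values, patterns = gaussian.predict_continuous_frame(
            data["prs"].to_numpy(float), y_m, y_f, self.params
        )
        out = pd.DataFrame({"value": values, "pattern": patterns})
        if "id" in data:
            out.insert(0, "id", data["id"].to_numpy())
        return out

    def simulate(self, n: int, seed: int = 0, keep_latent: bool = False) -> simulate.SimulatedTrioTable:
        return simulate.simulate_continuous_trios(self.params, n, seed, keep_latent)

    def summary(self) -> str:
        c = self.summary_inputs.continuous
        lines = [
            _rule("Continuous family model"),
            f"{'captured heritability alpha^2':40s} {self.alpha_sq:10.4f}",
            f"{'under-captured heritability beta^2':40s} {self.beta_sq:10.4f}",
            f"{'total heritability h^2':40s} {self.h2:10.4f}",
            f"{'input R^2 (PRS)':40s} {c['r2_prs']:10.4f}",
            f"{'input R^2 (mid-parental)':40s} {c['r2_midparent']:10.4f}",
            f"{'expected R^2, joint (both parents)':40s} {self.expected_r2_joint('both'):10.4f}",
            f"{'expected R^2, joint (single parent)':40s} {self.expected_r2_joint('single'):10.4f}",
            "=" * 62,
        ]
        return "\n".join(lines)


class DiseaseFamilyModel:
    """Logit-link liability model for a binary disease.

    Construct with :meth:`from_summary` (odds ratios per SD of PRS and for
    maternal/paternal history, plus the baseline log-odds and covariate
    effects) or :meth:`from_dataframe` (a training table with ``status``,
    ``prs``, ``mother_status``, ``father_status`` and covariate columns).
    ``fit()`` runs the marginal regressions when needed and the odds-ratio
    line search for the latent effect.
    """

    def __init__(
        self,
        summary: SummaryInputs | None = None,
        data: pd.DataFrame | None = None,
        covariates: tuple[str, ...] = (),
        beta_max: float = 5.0,
        beta_tol: float = 1e-4,
        n_nodes: int = 64,
    ):
        if (summary is None) == (data is None):
            raise ValueError("supply exactly one of summary statistics or a training table")
        self.summary_inputs = summary
        self.data = data
        self.covariates = tuple(covariates)
        self.beta_max = beta_max
        self.beta_tol = beta_tol
        self.n_nodes = n_nodes

    @classmethod
    def from_summary(
        cls,
        or_prs_per_sd: float,
        or_maternal_history: float,
        or_paternal_history: float,
        baseline_log_odds: float,
        covariate_effects: dict | None = None,
        covariate_reference: dict | None = None,
        **kwargs,
    ) -> "DiseaseFamilyModel":
        summary = SummaryInputs(
            binary={
                "or_prs_per_sd": or_prs_per_sd,
                "or_maternal_history": or_maternal_history,
                "or_paternal_history": or_paternal_history,
                "baseline_log_odds": baseline_log_odds,
                "covariate_effects": covariate_effects or {},
            },
            covariate_reference=covariate_reference or {},
        )
        return cls(summary=summary, covariates=tuple(covariate_effects or ()), **kwargs)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, covariates: tuple[str, ...] = (), **kwargs) -> "DiseaseFamilyModel":
        return cls(data=data, covariates=covariates, **kwargs)

    def fit(self) -> "DiseaseFamilyResults":
        summary = self.summary_inputs
        if summary is None:
            summary = estimation.fit_marginal_binary_models(self.data, self.covariates)
        params, line_search = estimation.params_from_summary(
            summary, beta_max=self.beta_max, tol=self.beta_tol, n_nodes=self.n_nodes
        )
        return DiseaseFamilyResults(
            model=self, params=params, summary_inputs=summary, line_search=line_search
        )


@dataclass
class DiseaseFamilyResults:
    """Fitted disease model: log-odds effects, liability-scale heritability,
    and the importance-sampling joint risk predictor."""

    model: DiseaseFamilyModel
    params: BinaryParams
    summary_inputs: SummaryInputs
    line_search: liability.LineSearchResult

    @property
    def alpha(self) -> float:
        return self.params.alpha

    @property
    def beta(self) -> float:
        return self.params.beta

    @property
    def mu0(self) -> float:
        return self.params.mu0

    def liability_heritability(self) -> dict[str, float]:
        """Captured and under-captured heritability on the liability scale."""
        tau_a = liability.liability_scale_effect(self.params.alpha, self.params.mu0)
        tau_b = liability.liability_scale_effect(self.params.beta, self.params.mu0)
        return {"captured": tau_a**2, "under_captured": tau_b**2}

    def predict(self, data: pd.DataFrame, L: int = 1_000_000, seed: int = 0) -> pd.DataFrame:
        """Joint liability predictions ``E[H_C | Z_M, Z_F, P_C]`` per row.

        Parental covariates are reference-filled (sex set by parent role);
        returns predicted liability, Monte-Carlo SE (``NaN`` for rows
        predicted in closed form) and the availability pattern used.
        """
        n = len(data)
        z_m = data["mother_status"].to_numpy(float) if "mother_status" in data else np.full(n, np.nan)
        z_f = data["father_status"].to_numpy(float) if "father_status" in data else np.full(n, np.nan)
        q_m = liability.parent_reference_covariates(self.params, "mother")
        q_f = liability.parent_reference_covariates(self.params, "father")
        values, ses = liability.predict_liability_frame(
            data["prs"].to_numpy(float), z_m, z_f, self.params, L=L, seed=seed,
            q_mother=q_m, q_father=q_f,
        )
        has_m, has_f = ~np.isnan(z_m), ~np.isnan(z_f)
        patterns = np.where(
            has_m & has_f, "both",
            np.where(has_m, "mother_only", np.where(has_f, "father_only", "none")),
        )
        out = pd.DataFrame({"value": values, "mc_se": ses, "pattern": patterns})
        if "id" in data:
            out.insert(0, "id", data["id"].to_numpy())
        return out

    def predict_prs_only(self, data: pd.DataFrame) -> pd.DataFrame:
        """Baseline predictor ignoring parental history: ``alpha * prs``."""
        out = pd.DataFrame({"value": self.params.alpha * data["prs"].to_numpy(float)})
        if "id" in data:
            out.insert(0, "id", data["id"].to_numpy())
        return out

    def simulate(
        self,
        n: int,
        covariate_spec: simulate.CovariateSpec | None = None,
        seed: int = 0,
        keep_latent: bool = False,
    ) -> simulate.SimulatedTrioTable:
        return simulate.simulate_binary_trios(self.params, n, covariate_spec, seed, keep_latent)

    def summary(self) -> str:
        b = self.summary_inputs.binary
        h = self.liability_heritability()
        lines = [
            _rule("Disease family model (logit-link liability)"),
            f"{'baseline log-odds mu0':40s} {self.mu0:10.4f}",
            f"{'PRS log-odds effect alpha':40s} {self.alpha:10.4f}",
            f"{'latent log-odds effect beta':40s} {self.beta:10.4f}",
            f"{'line-search objective':40s} {self.line_search.objective:10.2e}",
            f"{'observed maternal-history OR':40s} {b['or_maternal_history']:10.4f}",
            f"{'fitted maternal-history OR':40s} {self.line_search.or_m_theoretical:10.4f}",
            f"{'observed paternal-history OR':40s} {b['or_paternal_history']:10.4f}",
            f"{'fitted paternal-history OR':40s} {self.line_search.or_f_theoretical:10.4f}",
            f"{'liability-scale h^2 (captured)':40s} {h['captured']:10.4f}",
            f"{'liability-scale h^2 (under-captured)':40s} {h['under_captured']:10.4f}",
        ]
        for name, g in zip(self.params.covariates, self.params.gamma):
            lines.append(f"{'covariate ' + name:40s} {g:10.4f}")
        lines.append("=" * 62)
        return "\n".join(lines)
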