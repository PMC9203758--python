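"""Synthetic parent-child trios with the model's exact covariance structure.

Each genetic component (P, captured; G, latent) is standard normal in the
parents and transmitted to the child as the mid-parental mean plus an
independent Mendelian-segregation residual of variance 1/2, which realizes
unit variances, parent-child covariance 1/2, and zero spousal covariance
without simulating individual loci.  Traits and disease liabilities are
then built from the components exactly as the model assumes, so simulated
tables carry known ground truth for every latent quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit

from .params import BinaryParams, ContinuousParams, ParameterError

__all__ = [
    "Covariate",
    "CovariateSpec",
    "SimulatedTrioTable",
    "default_covariate_spec",
    "simulate_continuous_trios",
    "simulate_binary_trios",
]


@dataclass(frozen=True)
class Covariate:
    """One covariate column: how to draw it and its reference value.

    Effects in :class:`~famprs.params.BinaryParams` apply to the covariate
    centered at ``reference``, so the baseline log-odds ``mu0`` is the
    log-odds at the reference point.  ``sampler(rng, n, role)`` draws raw
    values; ``role`` is ``"child"``, ``"mother"`` or ``"father"`` so that
    e.g. parental sex is fixed by role.
    """

    name: str
    sampler: Callable[[np.random.Generator, int, str], np.ndarray]
    reference: float = 0.0


def _age_sampler(low: float = 40.0, high: float = 69.0):
    def sample(rng: np.random.Generator, n: int, role: str) -> np.ndarray:
        return rng.uniform(low, high, size=n)

    return sample


def _sex_sampler(rng: np.random.Generator, n: int, role: str) -> np.ndarray:
    # 0 = female, 1 = male; parental sex is determined by the role
    if role == "mother":
        return np.zeros(n)
    if role == "father":
        return np.ones(n)
    return rng.integers(0, 2, size=n).astype(float)


@dataclass(frozen=True)
class CovariateSpec:
    covariates: tuple[Covariate, ...] = ()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    @property
    def reference(self) -> np.ndarray:
        return np.array([c.reference for c in self.covariates])

    def draw(self, rng: np.random.Generator, n: int, role: str) -> np.ndarray:
        if not self.covariates:
            return np.empty((n, 0))
        return np.column_stack([c.sampler(rng, n, role) for c in self.covariates])


def default_covariate_spec() -> CovariateSpec:
    """Age uniform over 40-69 years and balanced sex, loosely mirroring a
    middle-aged population cohort; age reference is the interval midpoint
    and the sex reference level is female (0)."""
    return CovariateSpec(
        covariates=(
            Covariate("age", _age_sampler(), reference=54.5),
            Covariate("sex", _sex_sampler, reference=0.0),
        )
    )


@dataclass
class SimulatedTrioTable:
    """A simulated cohort plus the generating parameters and seed."""

    table: pd.DataFrame
    params: ContinuousParams | BinaryParams
    seed: int
    kind: str  # "continuous" | "binary"
    meta: dict = field(default_factory=dict)


def _transmit(rng: np.random.Generator, parent_m: np.ndarray, parent_f: np.ndarray) -> np.ndarray:
    # child = mid-parental mean + segregation residual of variance 1/2
    n = parent_m.shape[0]
    return (parent_m + parent_f) / 2.0 + rng.normal(0.0, np.sqrt(0.5), size=n)


def _draw_components(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    comp = {}
    for label in ("p", "g"):
        m = rng.normal(size=n)
        f = rng.normal(size=n)
        comp[f"{label}_m"] = m
        comp[f"{label}_f"] = f
        comp[f"{label}_c"] = _transmit(rng, m, f)
    return comp


def simulate_continuous_trios(
    params: ContinuousParams,
    n: int,
    seed: int = 0,
    keep_latent: bool = False,
) -> SimulatedTrioTable:
    """Simulate trios for a z-scored continuous trait.

    ``Y_k = alpha*P_k + beta*G_k + eps_k`` with residual variance
    ``1 - alpha**2 - beta**2`` for each family member; the observed table
    carries the child PRS (= P_C) and all three trait values.  Latent
    component columns are retained only when ``keep_latent`` so the same
    files can serve as blind test inputs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params.h2 > 1.0:
        raise ParameterError("alpha**2 + beta**2 must not exceed 1")
    rng = np.random.default_rng(seed)
    comp = _draw_components(rng, n)
    resid_sd = np.sqrt(max(1.0 - params.h2, 0.0))
    y = {}
    for who in ("m", "f", "c"):
        y[who] = (
            params.alpha * comp[f"p_{who}"]
            + params.beta * comp[f"g_{who}"]
            + rng.normal(0.0, resid_sd, size=n)
        )
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "prs": comp["p_c"],
            "mother_pheno": y["m"],
            "father_pheno": y["f"],
            "pheno": y["c"],
        }
    )
    if keep_latent:
        for k, v in comp.items():
            df[k] = v
    meta = {"n": n, "alpha": params.alpha, "beta": params.beta, "seed": seed}
    return SimulatedTrioTable(table=df, params=params, seed=seed, kind="continuous", meta=meta)


def simulate_binary_trios(
    params: BinaryParams,
    n: int,
    covariate_spec: CovariateSpec | None = None,
    seed: int = 0,
    keep_latent: bool = False,
) -> SimulatedTrioTable:
    """Simulate disease trios under the logit-link liability model.

    Liabilities ``H_k = alpha*P_k + beta*G_k`` follow the same Mendelian
    construction as the continuous traits; disease status is Bernoulli with
    probability ``expit(mu0 + H_k + gamma @ (q_k - reference))`` where each
    family member's covariates are drawn from ``covariate_spec`` (parental
    sex fixed by role).  Case counts per family member are recorded in
    ``meta``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = covariate_spec if covariate_spec is not None else CovariateSpec()
    if spec.names != params.covariates:
        raise ParameterError(
            f"covariate spec names {spec.names} do not match the parameter "
            f"schema {params.covariates}"
        )
    rng = np.random.default_rng(seed)
    comp = _draw_components(rng, n)
    roles = {"m": "mother", "f": "father", "c": "child"}
    df = pd.DataFrame({"id": np.arange(n), "prs": comp["p_c"]})
    meta = {
        "n": n,
        "mu0": params.mu0,
        "alpha": params.alpha,
        "beta": params.beta,
        "seed": seed,
        "cases": {},
    }
    gamma = np.asarray(params.gamma)
    for who, role in roles.items():
        h = params.alpha * comp[f"p_{who}"] + params.beta * comp[f"g_{who}"]
        q = spec.draw(rng, n, role)
        eta = params.mu0 + h
        if gamma.size:
            eta = eta + (q - spec.reference) @ gamma
        z = rng.binomial(1, expit(eta))
        col = "status" if who == "c" else f"{role}_status"
        df[col] = z
        meta["cases"][col] = int(z.sum())
        for j, name in enumerate(spec.names):
            prefix = "" if who == "c" else f"{role}_"
            df[f"{prefix}{name}"] = q[:, j]
        if keep_latent:
            df[f"h_{who}"] = h
    if keep_latent:
        for k, v in comp.items():
            df[k] = v
    return SimulatedTrioTable(table=df, params=params, seed=seed, kind="binary", meta=meta)
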