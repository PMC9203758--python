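"""Parameter containers for the latent factor model.

The model partitions the genetic determination of a trait into two
orthogonal standardized components: ``P``, the part captured by a polygenic
risk score, and ``G``, the under-captured part that parental phenotypes or
disease history can partially reveal.  For a unit-variance continuous trait
the standardized effects ``alpha`` (on P) and ``beta`` (on G) satisfy
``alpha**2 + beta**2 <= 1`` and their squares are the captured and
under-captured heritability fractions.  For a binary disease the effects
act on the log-odds scale and are unconstrained above zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContinuousParams",
    "BinaryParams",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when model parameters violate their invariants."""


_BOUND_SLACK = 1e-9


@dataclass(frozen=True)
class ContinuousParams:
    """Standardized effects of the captured (P) and latent (G) components.

    Parameters
    ----------
    alpha : float
        Standardized effect of the PRS-captured component; ``alpha**2`` is
        the heritability captured by the score.
    beta : float
        Standardized effect of the latent component; ``beta**2`` is the
        under-captured heritability.

    Notes
    -----
    The trait is assumed z-scored, so total heritability
    ``h2 = alpha**2 + beta**2`` cannot exceed 1.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or not np.isfinite(self.beta):
            raise ParameterError("alpha and beta must be finite")
        if self.alpha < -_BOUND_SLACK:
            raise ParameterError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta < -_BOUND_SLACK:
            raise ParameterError(f"beta must be >= 0, got {self.beta}")
        if self.h2 > 1.0 + 1e-8:
            raise ParameterError(
                f"alpha**2 + beta**2 = {self.h2:.6f} exceeds 1 "
                "(total heritability of a unit-variance trait)"
            )

    @property
    def h2(self) -> float:
        """Total heritability ``alpha**2 + beta**2``."""
        return float(self.alpha**2 + self.beta**2)

    @classmethod
    def from_variance_fractions(cls, alpha_sq: float, beta_sq: float) -> "ContinuousParams":
        """Build from the captured/under-captured heritability fractions."""
        if alpha_sq < 0 or beta_sq < 0:
            raise ParameterError("variance fractions must be non-negative")
        return cls(alpha=float(np.sqrt(alpha_sq)), beta=float(np.sqrt(beta_sq)))


@dataclass(frozen=True)
class BinaryParams:
    """Log-odds-scale parameters of the liability model for a binary disease.

    Disease status is Bernoulli with success probability
    ``expit(mu0 + alpha*P + beta*G + gamma @ q)`` where ``P`` and ``G`` are
    independent standard normal genetic components and ``q`` are measured
    covariates.  ``mu0`` is the baseline log-odds at the covariate reference.
    Unlike the continuous model, ``alpha`` and ``beta`` are unconstrained
    above zero.
    """

    mu0: float
    alpha: float
    beta: float
    gamma: tuple[float, ...] = ()
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma", tuple(float(g) for g in self.gamma))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        for name in ("mu0", "alpha", "beta"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")
        if self.alpha < -_BOUND_SLACK:
            raise ParameterError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta < -_BOUND_SLACK:
            raise ParameterError(f"beta must be >= 0, got {self.beta}")
        if len(self.gamma) != len(self.covariates):
            raise ParameterError(
                f"gamma has {len(self.gamma)} effects but the covariate "
                f"schema names {len(self.covariates)} columns"
            )

    @property
    def h2(self) -> float:
        """Variance of the genetic liability ``H = alpha*P + beta*G``."""
        return float(self.alpha**2 + self.beta**2)

    def linear_predictor(self, h: np.ndarray | float, q: np.ndarray | None) -> np.ndarray:
        """Log-odds ``mu0 + h + gamma @ q`` for liability ``h`` and covariates ``q``."""
        eta = self.mu0 + np.asarray(h, dtype=float)
        if self.covariates:
            if q is None:
                raise ParameterError(
                    f"covariates {self.covariates} required but none supplied"
                )
            q = np.asarray(q, dtype=float)
            if q.shape[-1] != len(self.gamma):
                raise ParameterError(
                    f"covariate vector has length {q.shape[-1]}, schema expects "
                    f"{len(self.gamma)}"
                )
            eta = eta + q @ np.asarray(self.gamma)
        elif q is not None and np.size(q):
            raise ParameterError("covariates supplied but the schema is empty")
        return eta
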