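"""Continuous-trait latent factor model for parent-child trios.

A z-scored trait ``Y = alpha*P + beta*G + eps`` is measured in mothers,
fathers and children.  ``P`` (captured by a PRS) and ``G`` (latent) are
independent standard normal components, each transmitted so that a parent
and child share covariance 1/2 in that component; spouses are unrelated.
The joint distribution of ``(Y_C, Y_M, Y_F, P_C)`` is then multivariate
normal with a covariance fully determined by ``(alpha, beta)``, and joint
predictors of the child's trait are conditional expectations under it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ContinuousParams, ParameterError

__all__ = [
    "ContinuousTrioObservation",
    "Prediction",
    "InfeasibleSummaryError",
    "build_trio_covariance",
    "estimate_beta_sq_from_midparent",
    "estimate_beta_sq_from_single_parent",
    "expected_r2_midparent",
    "predictor_weights",
    "predict_continuous",
    "predict_continuous_frame",
    "expected_r2_joint",
]

# numerical noise allowance when clamping an estimated fraction to its bound
_CLAMP_TOL = 1e-6


class InfeasibleSummaryError(ValueError):
    """Summary statistics imply a heritability outside its admissible range."""


@dataclass(frozen=True)
class ContinuousTrioObservation:
    """One child's PRS z-score plus whichever parental trait z-scores exist.

    ``None`` marks an unavailable parent; the availability pattern selects
    which conditional predictor applies (never mean-imputation).
    """

    p_c: float
    y_m: float | None = None
    y_f: float | None = None

    @property
    def pattern(self) -> str:
        if self.y_m is not None and self.y_f is not None:
            return "both"
        if self.y_m is not None:
            return "mother_only"
        if self.y_f is not None:
            return "father_only"
        return "none"


@dataclass(frozen=True)
class Prediction:
    """A conditional-expectation score; ``mc_se`` present only when sampled."""

    value: float
    mc_se: float | None = None

    def __post_init__(self) -> None:
        if self.mc_se is not None and self.mc_se < 0:
            raise ValueError("mc_se must be non-negative")


def build_trio_covariance(params: ContinuousParams, mode: str = "both") -> np.ndarray:
    """Covariance of the observed family vector under the latent factor model.

    Parameters
    ----------
    params : ContinuousParams
    mode : {"both", "single"}
        ``"both"`` returns the 4x4 covariance of ``(Y_C, Y_M, Y_F, P_C)``;
        ``"single"`` the 3x3 covariance of ``(Y_C, Y_parent, P_C)``.

    Returns
    -------
    numpy.ndarray
        Symmetric positive semi-definite matrix with unit diagonal,
        parent-child trait covariance ``h2/2``, spousal covariance 0,
        ``Cov(Y_C, P_C) = alpha`` and ``Cov(Y_parent, P_C) = alpha/2``.
    """
    a = params.alpha
    half_h2 = params.h2 / 2.0
    if mode == "both":
        return np.array(
            [
                [1.0, half_h2, half_h2, a],
                [half_h2, 1.0, 0.0, a / 2.0],
                [half_h2, 0.0, 1.0, a / 2.0],
                [a, a / 2.0, a / 2.0, 1.0],
            ]
        )
    if mode == "single":
        return np.array(
            [
                [1.0, half_h2, a],
                [half_h2, 1.0, a / 2.0],
                [a, a / 2.0, 1.0],
            ]
        )
    raise ValueError(f"mode must be 'both' or 'single', got {mode!r}")


def estimate_beta_sq_from_midparent(r2_prs: float, r2_midparent: float) -> tuple[float, float]:
    """Invert the mid-parental R2 to the under-captured heritability.

    The mid-parental predictor explains ``(h2)**2 / 2`` of the child trait
    variance, so ``h2 = sqrt(2 * r2_midparent)`` and the under-captured
    fraction is ``beta_sq = h2 - r2_prs``.

    Parameters
    ----------
    r2_prs : float
        Variance fraction explained by the PRS alone (= ``alpha**2``).
    r2_midparent : float
        Variance fraction explained by the mid-parental trait z-score.

    Returns
    -------
    (beta_sq, alpha_sq) : tuple of float

    Raises
    ------
    InfeasibleSummaryError
        If the implied total heritability falls outside ``[r2_prs, 1]``.
    """
    for name, v in (("r2_prs", r2_prs), ("r2_midparent", r2_midparent)):
        if not 0.0 <= v <= 1.0:
            raise InfeasibleSummaryError(f"{name} must lie in [0, 1], got {v}")
    h2 = float(np.sqrt(2.0 * r2_midparent))
    return _beta_sq_from_h2(h2, r2_prs)


def estimate_beta_sq_from_single_parent(r2_prs: float, r2_single_parent: float) -> tuple[float, float]:
    """Single-parent analogue of the mid-parental inversion (extrapolation).

    A single parent's trait explains ``(h2/2)**2 = h2**2/4`` of the child
    variance, giving ``h2 = 2*sqrt(r2_single_parent)``.  This inversion is
    an extrapolation of the model beyond the mid-parental case and should
    be preferred only when no mid-parental estimate exists.
    """
    for name, v in (("r2_prs", r2_prs), ("r2_single_parent", r2_single_parent)):
        if not 0.0 <= v <= 1.0:
            raise InfeasibleSummaryError(f"{name} must lie in [0, 1], got {v}")
    h2 = float(2.0 * np.sqrt(r2_single_parent))
    return _beta_sq_from_h2(h2, r2_prs)


def _beta_sq_from_h2(h2: float, r2_prs: float) -> tuple[float, float]:
    if h2 > 1.0 + _CLAMP_TOL or h2 < r2_prs - _CLAMP_TOL:
        raise InfeasibleSummaryError(
            f"implied total heritability h2 = {h2:.6f} is outside "
            f"[r2_prs, 1] = [{r2_prs:.6f}, 1]; the summary statistics are "
            "mutually incompatible under the latent factor model"
        )
    h2 = min(max(h2, r2_prs), 1.0)
    beta_sq = h2 - r2_prs
    return beta_sq, r2_prs


def expected_r2_midparent(params: ContinuousParams) -> float:
    """Population R2 of the mid-parental predictor: ``(alpha^2+beta^2)^2 / 2``."""
    return params.h2**2 / 2.0


def predictor_weights(params: ContinuousParams, pattern: str) -> np.ndarray:
    """Linear weights of the conditional-expectation predictor.

    Solves ``A w = c`` where ``A`` is the covariance of the conditioning
    variables and ``c`` their covariance with the child trait; a direct
    solve is used rather than explicit inversion.

    Parameters
    ----------
    pattern : {"both", "mother_only", "father_only", "single", "none"}
        Which inputs are available.  ``"both"`` orders weights as
        ``(y_m, y_f, p_c)``; single-parent patterns as ``(y_parent, p_c)``;
        ``"none"`` returns the single weight on ``p_c``.
    """
    a = params.alpha
    half_h2 = params.h2 / 2.0
    if pattern == "both":
        cov = build_trio_covariance(params, "both")
        A, c = cov[1:, 1:], cov[0, 1:]
    elif pattern in ("mother_only", "father_only", "single"):
        cov = build_trio_covariance(params, "single")
        A, c = cov[1:, 1:], cov[0, 1:]
    elif pattern == "none":
        return np.array([a])
    else:
        raise ValueError(f"unknown availability pattern {pattern!r}")
    try:
        return np.linalg.solve(A, c)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - invalid params only
        raise ParameterError(f"singular conditioning covariance: {exc}") from exc


def predict_continuous(obs: ContinuousTrioObservation, params: ContinuousParams) -> Prediction:
    """Joint trait predictor: the conditional expectation of the child z-score.

    Dispatches on the availability pattern: both parents condition on
    ``(Y_M, Y_F, P_C)``, one parent on ``(Y_parent, P_C)``, and with no
    parental measure the predictor reduces to ``alpha * p_c``.  Closed
    form, so ``mc_se`` is absent.
    """
    w = predictor_weights(params, obs.pattern)
    if obs.pattern == "both":
        x = np.array([obs.y_m, obs.y_f, obs.p_c])
    elif obs.pattern == "mother_only":
        x = np.array([obs.y_m, obs.p_c])
    elif obs.pattern == "father_only":
        x = np.array([obs.y_f, obs.p_c])
    else:
        x = np.array([obs.p_c])
    return Prediction(value=float(w @ x), mc_se=None)


def predict_continuous_frame(
    prs: np.ndarray,
    y_m: np.ndarray,
    y_f: np.ndarray,
    params: ContinuousParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized joint trait predictor for a cohort.

    ``y_m``/``y_f`` use ``nan`` for unavailable parents; each row is
    predicted with the conditional expectation matching its availability
    pattern.  Returns ``(values, patterns)``.
    """
    prs = np.asarray(prs, dtype=float)
    y_m = np.asarray(y_m, dtype=float)
    y_f = np.asarray(y_f, dtype=float)
    has_m, has_f = ~np.isnan(y_m), ~np.isnan(y_f)
    values = np.empty(prs.shape[0])
    patterns = np.empty(prs.shape[0], dtype=object)
    for pattern, mask in (
        ("both", has_m & has_f),
        ("mother_only", has_m & ~has_f),
        ("father_only", ~has_m & has_f),
        ("none", ~has_m & ~has_f),
    ):
        patterns[mask] = pattern
        if not np.any(mask):
            continue
        w = predictor_weights(params, pattern)
        if pattern == "both":
            values[mask] = w[0] * y_m[mask] + w[1] * y_f[mask] + w[2] * prs[mask]
        elif pattern == "mother_only":
            values[mask] = w[0] * y_m[mask] + w[1] * prs[mask]
        elif pattern == "father_only":
            values[mask] = w[0] * y_f[mask] + w[1] * prs[mask]
        else:
            values[mask] = w[0] * prs[mask]
    return values, patterns


def expected_r2_joint(params: ContinuousParams, mode: str = "both") -> float:
    """Population variance fraction explained by the joint predictor.

    Equals ``c @ A^{-1} @ c`` with ``A``, ``c`` as in
    :func:`predictor_weights`; the empirical R2 of
    :func:`predict_continuous` converges to this value.
    """
    if mode == "both":
        cov = build_trio_covariance(params, "both")
    elif mode == "single":
        cov = build_trio_covariance(params, "single")
    else:
        raise ValueError(f"mode must be 'both' or 'single', got {mode!r}")
    A, c = cov[1:, 1:], cov[0, 1:]
    return float(c @ np.linalg.solve(A, c))
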