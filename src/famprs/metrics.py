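"""Predictive-performance metrics for joint PRS + family-history predictors.

Continuous traits are judged by variance explained and RMSE transformed
back to the original measurement scale; binary predictors by AUROC, AUPRC,
DeLong's paired AUROC test, net reclassification improvement (NRI) at
percentile cut-offs, and integrated discrimination improvement (IDI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "EvaluationReport",
    "r2_and_rmse",
    "auroc_auprc",
    "delong_test",
    "nri_at_percentiles",
    "idi",
]


@dataclass
class EvaluationReport:
    """Metrics computed from whichever prediction/label columns were supplied."""

    r2: float | None = None
    rmse: float | None = None
    auroc: float | None = None
    auprc: float | None = None
    delong_p: float | None = None
    nri: dict[float, float] = field(default_factory=dict)
    idi: float | None = None

    def as_dict(self) -> dict:
        out: dict = {}
        for name in ("r2", "rmse", "auroc", "auprc", "delong_p", "idi"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        for pct, v in self.nri.items():
            out[f"nri_{pct:g}"] = v
        return out


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if not set(classes) <= {0, 1} or len(classes) < 2:
        raise ValueError("labels must contain both classes 0 and 1")
    return labels.astype(int)


def r2_and_rmse(
    predicted: np.ndarray,
    observed: np.ndarray,
    scale_sd: float | dict | None = None,
    strata: np.ndarray | None = None,
) -> dict[str, float]:
    """Variance explained and original-scale RMSE of a z-score predictor.

    ``r2`` is the squared Pearson correlation.  The RMSE multiplies each
    residual by the original-scale SD - a scalar, or per-stratum values
    keyed by the labels in ``strata`` (e.g. sex-stratified height SDs) -
    so the error is reported in measurement units.
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValueError("predicted and observed must be equal-length with >= 3 values")
    if np.std(observed) == 0:
        raise ValueError("observed values have zero variance; r2 undefined")
    # a constant predictor carries no information: r2 = 0 by convention
    r = 0.0 if np.std(predicted) == 0 else np.corrcoef(predicted, observed)[0, 1]
    resid = observed - predicted
    if scale_sd is None:
        scaled = resid
    elif isinstance(scale_sd, dict):
        if strata is None:
            raise ValueError("per-stratum scale_sd requires strata labels")
        sds = np.array([scale_sd[s] for s in np.asarray(strata)])
        scaled = resid * sds
    else:
        scaled = resid * float(scale_sd)
    return {"r2": float(r**2), "rmse": float(np.sqrt(np.mean(scaled**2)))}


def auroc_auprc(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """AUROC (Mann-Whitney with midrank ties) and AUPRC (average precision)."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, float)
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
    }


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC plus per-case and per-control placement values (midranks)."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    m, n = len(cases), len(controls)
    all_ranks = rankdata(np.concatenate([cases, controls]))
    case_ranks = rankdata(cases)
    control_ranks = rankdata(controls)
    v_case = (all_ranks[:m] - case_ranks) / n  # P(score_control < case_i)
    v_control = 1.0 - (all_ranks[m:] - control_ranks) / m
    auc = float(v_case.mean())
    return auc, v_case, v_control


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> dict[str, float | bool]:
    """DeLong's paired two-sided test for equality of two correlated AUROCs.

    Uses the structural-components estimate of the covariance between the
    two empirical AUROCs on the same individuals.  A degenerate variance
    (e.g. identical scores) is reported as ``p_value = 1`` with
    ``degenerate = True`` rather than as an error.
    """
    labels = _check_binary(labels)
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned")
    auc_a, va_case, va_ctrl = _placements(scores_a, labels)
    auc_b, vb_case, vb_ctrl = _placements(scores_b, labels)
    m, n = int(labels.sum()), int((1 - labels).sum())
    s_case = np.cov(np.stack([va_case, vb_case]))
    s_ctrl = np.cov(np.stack([va_ctrl, vb_ctrl]))
    cov = s_case / m + s_ctrl / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0 or not np.isfinite(var_diff):
        return {"auroc_a": auc_a, "auroc_b": auc_b, "p_value": 1.0, "degenerate": True}
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2 * norm.sf(abs(z)))
    return {"auroc_a": auc_a, "auroc_b": auc_b, "p_value": p, "degenerate": False}


def nri_at_percentiles(
    scores_new: np.ndarray,
    scores_old: np.ndarray,
    labels: np.ndarray,
    percentiles: tuple[float, ...] = (50, 80, 95, 99),
) -> dict[float, float]:
    """Net reclassification improvement (%) at within-sample percentile cut-offs.

    Each score classifies individuals strictly above its own sample
    percentile as high risk.  NRI sums the net fraction of cases moved up
    and noncases moved down when replacing the old score with the new one.
    A cut-off leaving an empty high-risk class for either score is flagged
    as undefined (``nan``) at that percentile.
    """
    labels = _check_binary(labels)
    scores_new = np.asarray(scores_new, float)
    scores_old = np.asarray(scores_old, float)
    out: dict[float, float] = {}
    for pct in percentiles:
        if not 0.0 < pct < 100.0:
            raise ValueError(f"percentile must lie in (0, 100), got {pct}")
        high_new = scores_new > np.percentile(scores_new, pct)
        high_old = scores_old > np.percentile(scores_old, pct)
        if not high_new.any() or not high_old.any():
            out[pct] = float("nan")
            continue
        up = high_new & ~high_old
        down = ~high_new & high_old
        case = labels == 1
        p_up_case = up[case].mean()
        p_down_case = down[case].mean()
        p_up_ctrl = up[~case].mean()
        p_down_ctrl = down[~case].mean()
        out[pct] = float(100.0 * ((p_up_case - p_down_case) + (p_down_ctrl - p_up_ctrl)))
    return out


def _calibrate(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-dimensional logistic recalibration of a score to probabilities."""
    X = sm.add_constant(np.asarray(scores, float))
    try:
        fit = sm.Logit(labels, X).fit(disp=False, maxiter=100)
    except Exception as exc:
        raise RuntimeError(f"logistic calibration failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise RuntimeError("logistic calibration did not converge")
    return expit(X @ fit.params)


def idi(scores_new: np.ndarray, scores_old: np.ndarray, labels: np.ndarray) -> float:
    """Integrated discrimination improvement (%), new score vs old.

    Scores are mapped to probabilities by per-model logistic recalibration
    (liability scores are not probabilities); the IDI is the gain in the
    case/noncase separation of mean predicted risk.
    """
    labels = _check_binary(labels)
    p_new = _calibrate(scores_new, labels)
    p_old = _calibrate(scores_old, labels)
    case = labels == 1
    gain_case = p_new[case].mean() - p_old[case].mean()
    gain_ctrl = p_new[~case].mean() - p_old[~case].mean()
    return float(100.0 * (gain_case - gain_ctrl))
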