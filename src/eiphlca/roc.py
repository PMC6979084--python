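"""ROC construction and F1-optimal threshold selection for the BALFRBC test.

Given the fitted two-component model of log red-cell counts, the ROC of the
rule "call EIPH when BALFRBC >= threshold" follows in closed form from the
normal distribution functions of the two components:

    sensitivity(t) = 1 - Phi((t - mu_pos) / sigma_pos)
    specificity(t) = Phi((t - mu_neg) / sigma_neg)

with t the threshold on the natural-log scale.  The working threshold is
the one maximizing the F1 score — the harmonic mean of precision and recall
— under a balanced 50/50 prevalence assumption, so the recommendation does
not depend on how EIPH-prone any particular exercise discipline is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .cohort import LatentClassParams

__all__ = [
    "RocCurve",
    "ThresholdResult",
    "TestMetrics",
    "roc_from_normals",
    "f1_at",
    "optimal_threshold",
    "test_metrics_at",
]


@dataclass(frozen=True)
class RocCurve:
    """Parallel arrays over a log-threshold grid."""

    thresholds_log: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    prevalence_assumed: float = 0.5

    @property
    def thresholds_natural(self) -> np.ndarray:
        return np.exp(self.thresholds_log)


@dataclass(frozen=True)
class ThresholdResult:
    """F1-optimal BALFRBC cutoff and the operating point it implies."""

    threshold_natural: float
    threshold_log: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    prevalence_assumed: float
    boundary: bool = False  # True when F1 is maximized at the grid edge


class TestMetrics(NamedTuple):
    sensitivity: float
    specificity: float


def _sens_spec(params: LatentClassParams, t_log) -> tuple[np.ndarray, np.ndarray]:
    sens = norm.sf(t_log, loc=params.mu_pos, scale=params.sigma_pos)
    spec = norm.cdf(t_log, loc=params.mu_neg, scale=params.sigma_neg)
    return sens, spec


def f1_at(sensitivity, specificity, prevalence: float = 0.5, mean: str = "harmonic"):
    """F1 score of a test with the given operating point.

    Precision comes from Bayes' rule at the assumed prevalence:
    ``prec = se*p / (se*p + (1-sp)(1-p))``.  The default is the standard
    harmonic mean of precision and recall; ``mean='geometric'`` (the Fowlkes-
    Mallows variant) is available for comparison.  Returns 0 where
    sensitivity is 0.  Accepts scalars or arrays.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must lie in [0, 1], got {prevalence}")
    if mean not in ("harmonic", "geometric"):
        raise ValueError(f"mean must be 'harmonic' or 'geometric', got {mean!r}")
    se = np.asarray(sensitivity, dtype=float)
    sp = np.asarray(specificity, dtype=float)
    if np.any((se < 0) | (se > 1)) or np.any((sp < 0) | (sp > 1)):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    tp = se * prevalence
    fp = (1.0 - sp) * (1.0 - prevalence)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        if mean == "harmonic":
            f1 = np.where(prec + se > 0, 2.0 * prec * se / (prec + se), 0.0)
        else:
            f1 = np.sqrt(prec * se)
    f1 = np.where(se == 0, 0.0, f1)
    if f1.ndim == 0:
        return float(f1)
    return f1


def roc_from_normals(
    params: LatentClassParams,
    grid: Sequence[float],
    prevalence: float = 0.5,
    mean: str = "harmonic",
) -> RocCurve:
    """Closed-form ROC of the thresholded BALFRBC rule on a log-count grid."""
    t = np.asarray(grid, dtype=float)
    if t.size == 0:
        raise ValueError("empty threshold grid")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("threshold grid must be strictly increasing")
    if not (params.sigma_pos > 0 and params.sigma_neg > 0):
        raise ValueError("sigmas must be positive")
    sens, spec = _sens_spec(params, t)
    tp = sens * prevalence
    fp = (1.0 - spec) * (1.0 - prevalence)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
    f1 = f1_at(sens, spec, prevalence, mean)
    return RocCurve(t, sens, spec, prec, np.asarray(f1), prevalence)


def optimal_threshold(
    params: LatentClassParams,
    prevalence: float = 0.5,
    mean: str = "harmonic",
    n_grid: int = 4001,
) -> ThresholdResult:
    """Locate the F1-maximizing BALFRBC threshold.

    Dense grid over [mu_neg - 5*sigma_neg, mu_pos + 5*sigma_pos] on the log
    scale, then bounded scalar refinement between the grid neighbours of the
    argmax.  Grid-then-refine is deliberate: for degenerate parameter sets
    (indistinguishable components) F1 is maximized in the classify-all-
    positive limit and the result is flagged as a boundary solution rather
    than chased to -infinity.
    """
    if not (params.sigma_pos > 0 and params.sigma_neg > 0):
        raise ValueError("sigmas must be positive")
    lo = params.mu_neg - 5.0 * params.sigma_neg
    hi = params.mu_pos + 5.0 * params.sigma_pos
    if hi <= lo:  # components in reversed order: still produce a grid
        lo, hi = hi - 1.0, lo + 1.0
    grid = np.linspace(lo, hi, n_grid)
    sens, spec = _sens_spec(params, grid)
    f1 = np.asarray(f1_at(sens, spec, prevalence, mean))
    k = int(np.argmax(f1))
    boundary = k == 0 or k == n_grid - 1

    t_star = float(grid[k])
    if not boundary:
        res = minimize_scalar(
            lambda t: -f1_at(
                float(norm.sf(t, params.mu_pos, params.sigma_pos)),
                float(norm.cdf(t, params.mu_neg, params.sigma_neg)),
                prevalence,
                mean,
            ),
            bounds=(float(grid[k - 1]), float(grid[k + 1])),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if -res.fun >= f1[k]:
            t_star = float(res.x)

    se_star, sp_star = _sens_spec(params, np.array([t_star]))
    se_star, sp_star = float(se_star[0]), float(sp_star[0])
    tp = se_star * prevalence
    fp = (1.0 - sp_star) * (1.0 - prevalence)
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    return ThresholdResult(
        threshold_natural=math.exp(t_star),
        threshold_log=t_star,
        sensitivity=se_star,
        specificity=sp_star,
        precision=prec,
        f1=float(f1_at(se_star, sp_star, prevalence, mean)),
        prevalence_assumed=prevalence,
        boundary=boundary,
    )


def test_metrics_at(params: LatentClassParams, threshold_natural: float) -> TestMetrics:
    """Model-based sensitivity and specificity of "BALFRBC >= threshold"."""
    if not threshold_natural > 0:
        raise ValueError(f"threshold must be positive, got {threshold_natural}")
    t = math.log(threshold_natural)
    sens, spec = _sens_spec(params, np.array([t]))
    return TestMetrics(float(sens[0]), float(spec[0]))
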