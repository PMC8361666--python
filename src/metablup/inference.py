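"""Pooled random-effects inference.

Given a StudySet and a between-study variance estimate, the pooled average
effect is the inverse-variance weighted mean

    theta_hat = sum_i w_i Y_i / sum_i w_i,   w_i = 1 / (v_i + tau^2),

with Var(theta_hat) = 1 / sum_i w_i. Confidence intervals use the normal
pivot, or optionally the Knapp-Hartung adjustment (variance scaled by the
residual-based factor q with a t_{n-1} pivot). The prediction interval for
the true effect in a hypothetical new study is

    theta_hat +/- t_{n-2; 1-alpha/2} * sqrt(1/w + tau^2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from .data import StudySet
from .heterogeneity import Tau2Estimate

__all__ = [
    "Interval",
    "RandomEffectsFit",
    "fit_random_effects",
    "knapp_hartung_scale",
    "pooled_confidence_interval",
    "new_study_prediction_interval",
]


@dataclass(frozen=True)
class Interval:
    """A two-sided interval with its nominal coverage level."""

    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self):
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x) -> bool:
        return bool(np.all((self.lower <= x) & (x <= self.upper)))


@dataclass(frozen=True)
class RandomEffectsFit:
    """Pooled random-effects fit: tau^2, weights, theta_hat and its variance."""

    tau2: Tau2Estimate
    weights: np.ndarray
    theta_hat: float
    var_theta_hat: float
    kh_scale: Optional[float] = None
    level: float = 0.95

    @property
    def total_weight(self) -> float:
        """w = sum of the study weights (reciprocal of var_theta_hat)."""
        return float(np.sum(self.weights))

    @property
    def se_theta_hat(self) -> float:
        return float(np.sqrt(self.var_theta_hat))


def _as_tau2(tau2) -> Tau2Estimate:
    if isinstance(tau2, Tau2Estimate):
        return tau2
    return Tau2Estimate(value=float(tau2), estimator="fixed")


def fit_random_effects(data: StudySet, tau2, level: float = 0.95) -> RandomEffectsFit:
    """Compute the pooled estimate under the random-effects model.

    ``tau2`` may be a :class:`Tau2Estimate` or a plain nonnegative number
    (treated as a fixed, known between-study variance).
    """
    t2 = _as_tau2(tau2)
    weights = 1.0 / (data.v + t2.value)
    total = float(np.sum(weights))
    theta_hat = float(np.sum(weights * data.y) / total)
    return RandomEffectsFit(
        tau2=t2,
        weights=weights,
        theta_hat=theta_hat,
        var_theta_hat=1.0 / total,
        level=level,
    )


def knapp_hartung_scale(
    data: StudySet, fit: RandomEffectsFit, truncate: bool = False
) -> float:
    """Knapp-Hartung variance-scaling factor q.

    q = sum_i w_i (Y_i - theta_hat)^2 / (n - 1). Untruncated by default;
    with ``truncate=True`` the scale is floored at one so the adjustment
    can only widen intervals.
    """
    if data.n < 2:
        raise ValueError("the Knapp-Hartung pivot requires at least 2 studies")
    q = float(
        np.sum(fit.weights * (data.y - fit.theta_hat) ** 2) / (data.n - 1)
    )
    return max(q, 1.0) if truncate else q


def with_knapp_hartung(
    data: StudySet, fit: RandomEffectsFit, truncate: bool = False
) -> RandomEffectsFit:
    """Return a copy of the fit carrying the Knapp-Hartung scale."""
    return replace(fit, kh_scale=knapp_hartung_scale(data, fit, truncate=truncate))


def pooled_confidence_interval(
    fit: RandomEffectsFit, data: StudySet = None, use_kh: bool = False
) -> Interval:
    """Confidence interval for the average effect theta.

    Without the Knapp-Hartung adjustment: theta_hat +/- z * sqrt(1/w).
    With it: theta_hat +/- t_{n-1} * sqrt(q/w), where q is the fit's
    ``kh_scale`` (computed on the fly from ``data`` when absent).
    """
    alpha = 1.0 - fit.level
    if not use_kh:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        half = z * fit.se_theta_hat
    else:
        if data is None:
            raise ValueError("the Knapp-Hartung interval needs the study data")
        q = fit.kh_scale
        if q is None:
            q = knapp_hartung_scale(data, fit)
        t = stats.t.ppf(1.0 - alpha / 2.0, df=data.n - 1)
        half = t * np.sqrt(q * fit.var_theta_hat)
    return Interval(fit.theta_hat - half, fit.theta_hat + half, level=fit.level)


def new_study_prediction_interval(fit: RandomEffectsFit, n: int) -> Interval:
    """Prediction interval for the true effect in a new study.

    Uses the t distribution with n - 2 degrees of freedom, so at least
    three studies are required.
    """
    if n < 3:
        raise ValueError(
            "the new-study prediction interval needs n >= 3 studies "
            "(t distribution with n - 2 degrees of freedom)"
        )
    alpha = 1.0 - fit.level
    t = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    half = t * np.sqrt(fit.var_theta_hat + fit.tau2.value)
    return Interval(fit.theta_hat - half, fit.theta_hat + half, level=fit.level)
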