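"""Empirical Bayes / BLUP study-specific estimates and their variances.

The study-specific true effect theta_i is estimated by the shrinkage
estimator

    theta_hat_i = B_i * theta_hat + (1 - B_i) * Y_i,
    B_i = v_i / (v_i + tau^2),

which is simultaneously the empirical Bayes estimate and the best linear
unbiased prediction (BLUP) under the random-effects model. Three variance
formulae are available for the accompanying study-specific prediction
intervals:

* ``crude``:       V_i = v_i * tau^2 / (v_i + tau^2)
                   (posterior variance ignoring all parameter uncertainty;
                   collapses to zero width when tau^2 = 0)
* ``raudenbush``:  V_i = v_i * tau^2 / (v_i + tau^2)
                       + (1/w) * v_i^2 / (v_i + tau^2)^2
                   (accounts for uncertainty in theta; the recommended
                   formula, also the variance of theta_hat_i - theta_i)
* ``quan``:        V_i = tau^4 / (v_i + tau^2)
                       + (1/w) * v_i * (v_i + 2 tau^2) / (v_i + tau^2)^2
                   (this is Var(theta_hat_i): a variance for inference about
                   the *average* effect theta, not theta_i; provided for
                   comparison and known to miscover theta_i)

Here w = sum_i (v_i + tau^2)^{-1} is the total random-effects weight, so
1/w is the variance of the pooled estimate. The estimated tau^2 is plugged
in wherever tau^2 appears; its uncertainty is deliberately ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .data import StudySet
from .inference import Interval, RandomEffectsFit, knapp_hartung_scale

__all__ = [
    "FORMULAE",
    "ZeroTau2Warning",
    "ShrinkageEstimate",
    "shrinkage_factors",
    "blup_estimates",
    "variance_crude",
    "variance_raudenbush",
    "variance_quan",
    "blup_decomposition_terms",
    "study_prediction_intervals",
]

FORMULAE = ("crude", "raudenbush", "quan")


class ZeroTau2Warning(UserWarning):
    """Warns that tau^2 = 0 makes the crude variance (and intervals) zero."""


def shrinkage_factors(data: StudySet, tau2: float) -> np.ndarray:
    """Per-study shrinkage factors B_i = v_i / (v_i + tau^2), in [0, 1]."""
    if tau2 < 0:
        raise ValueError("tau^2 must be nonnegative")
    return data.v / (data.v + tau2)


def blup_estimates(data: StudySet, fit: RandomEffectsFit):
    """Empirical Bayes / BLUP estimates theta_hat_i and deviations gamma_hat_i.

    Returns ``(theta_i, gamma_i)`` with theta_i = B_i theta_hat + (1-B_i) Y_i
    and gamma_i = theta_i - theta_hat.
    """
    b = shrinkage_factors(data, fit.tau2.value)
    theta_i = b * fit.theta_hat + (1.0 - b) * data.y
    return theta_i, theta_i - fit.theta_hat


def variance_crude(v_i, tau2: float):
    """Crude variance v_i tau^2 / (v_i + tau^2).

    Satisfies the precision identity 1/V = 1/v_i + 1/tau^2 when tau^2 > 0.
    Emits :class:`ZeroTau2Warning` at tau^2 = 0, where it degenerates to 0.
    """
    if tau2 < 0:
        raise ValueError("tau^2 must be nonnegative")
    if tau2 == 0:
        warnings.warn(
            "crude variance is zero when tau^2 = 0: the resulting "
            "study-specific intervals have zero width",
            ZeroTau2Warning,
            stacklevel=2,
        )
    v_i = np.asarray(v_i, dtype=float)
    return v_i * tau2 / (v_i + tau2)


def variance_raudenbush(v_i, tau2: float, w: float):
    """Recommended variance for study-specific prediction intervals."""
    if tau2 < 0 or w <= 0:
        raise ValueError("need tau^2 >= 0 and total weight w > 0")
    v_i = np.asarray(v_i, dtype=float)
    s = v_i + tau2
    return v_i * tau2 / s + (1.0 / w) * v_i**2 / s**2


def variance_quan(v_i, tau2: float, w: float):
    """Var(theta_hat_i) — appropriate for inference about theta, not theta_i."""
    if tau2 < 0 or w <= 0:
        raise ValueError("need tau^2 >= 0 and total weight w > 0")
    v_i = np.asarray(v_i, dtype=float)
    s = v_i + tau2
    return tau2**2 / s + (1.0 / w) * v_i * (v_i + 2.0 * tau2) / s**2


def blup_decomposition_terms(v_i, tau2: float, w: float):
    """The three terms of Var(theta_hat_i - theta_i).

    Returns ``(var_blup, var_theta_i, neg2cov)`` where var_blup is
    Var(theta_hat_i) (identical to the Quan formula), var_theta_i = tau^2,
    and neg2cov = -2 Cov(theta_hat_i, theta_i). Their sum equals the
    Raudenbush variance identically.
    """
    if tau2 < 0 or w <= 0:
        raise ValueError("need tau^2 >= 0 and total weight w > 0")
    v_i = np.asarray(v_i, dtype=float)
    s = v_i + tau2
    var_blup = variance_quan(v_i, tau2, w)
    neg2cov = -(2.0 / w) * v_i * tau2 / s**2 - 2.0 * tau2**2 / s
    return var_blup, np.broadcast_to(float(tau2), v_i.shape).copy(), neg2cov


@dataclass(frozen=True)
class ShrinkageEstimate:
    """Per-study shrinkage results and prediction intervals.

    ``lower``/``upper`` hold the interval endpoints under the selected
    ``formula``; all three candidate variances are recorded so they can be
    compared without recomputation.
    """

    B: np.ndarray
    theta_i: np.ndarray
    gamma_i: np.ndarray
    var_crude: np.ndarray
    var_raudenbush: np.ndarray
    var_quan: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    formula: str
    level: float = 0.95

    @property
    def intervals(self):
        """The study-specific prediction intervals as Interval objects."""
        return [
            Interval(lo, up, level=self.level)
            for lo, up in zip(self.lower, self.upper)
        ]

    @property
    def variance(self) -> np.ndarray:
        return {
            "crude": self.var_crude,
            "raudenbush": self.var_raudenbush,
            "quan": self.var_quan,
        }[self.formula]


def study_prediction_intervals(
    data: StudySet,
    fit: RandomEffectsFit,
    formula: str = "raudenbush",
    use_kh: bool = False,
    level: Optional[float] = None,
    kh_t: bool = False,
) -> ShrinkageEstimate:
    """Study-specific prediction intervals theta_hat_i +/- z sqrt(V_i).

    With ``use_kh`` the 1/w factor in the second term of the Raudenbush and
    Quan variances is replaced by q/w (the crude formula has no such term
    and is unchanged). The quantile stays normal by default even under the
    Knapp-Hartung scaling; ``kh_t=True`` switches to t_{n-1}.
    """
    if formula not in FORMULAE:
        raise ValueError(f"unknown variance formula {formula!r}; choose from {FORMULAE}")
    if level is None:
        level = fit.level
    tau2 = fit.tau2.value
    w = fit.total_weight
    theta_i, gamma_i = blup_estimates(data, fit)
    b = shrinkage_factors(data, tau2)

    with warnings.catch_warnings():
        if formula != "crude":
            warnings.simplefilter("ignore", ZeroTau2Warning)
        var_crude = variance_crude(data.v, tau2)
    var_raud = variance_raudenbush(data.v, tau2, w)
    var_quan_ = variance_quan(data.v, tau2, w)

    if use_kh:
        q = fit.kh_scale
        if q is None:
            q = knapp_hartung_scale(data, fit)
        s = data.v + tau2
        sel_raud = var_crude + (q / w) * data.v**2 / s**2
        sel_quan = tau2**2 / s + (q / w) * data.v * (data.v + 2.0 * tau2) / s**2
        selected = {"crude": var_crude, "raudenbush": sel_raud, "quan": sel_quan}[
            formula
        ]
    else:
        selected = {
            "crude": var_crude,
            "raudenbush": var_raud,
            "quan": var_quan_,
        }[formula]

    alpha = 1.0 - level
    if use_kh and kh_t:
        crit = stats.t.ppf(1.0 - alpha / 2.0, df=data.n - 1)
    else:
        crit = stats.norm.ppf(1.0 - alpha / 2.0)
    half = crit * np.sqrt(selected)
    return ShrinkageEstimate(
        B=b,
        theta_i=theta_i,
        gamma_i=gamma_i,
        var_crude=var_crude,
        var_raudenbush=var_raud,
        var_quan=var_quan_,
        lower=theta_i - half,
        upper=theta_i + half,
        formula=formula,
        level=level,
    )
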