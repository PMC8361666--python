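"""Estimators of the between-study variance tau^2.

Three standard estimators are provided:

* DerSimonian-Laird (``DL``): method of moments on Cochran's Q with
  inverse-variance weights, truncated at zero. Closed form.
* Paule-Mandel (``PM``): the tau^2 that equates the generalized Q statistic
  Q_gen(tau^2) = sum_i (v_i + tau^2)^{-1} (Y_i - theta_hat(tau^2))^2 to its
  degrees of freedom n - 1. Q_gen is monotone decreasing in tau^2, so the
  root is unique and is located by bisection on an expanding bracket.
* Restricted maximum likelihood (``REML``): bounded maximization of the
  restricted log-likelihood of the marginal model Y_i ~ N(theta, v_i + tau^2).

Within-study variances are treated as fixed and known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data import StudySet

__all__ = [
    "Tau2Estimate",
    "EstimationError",
    "estimate_tau2_dl",
    "estimate_tau2_pm",
    "estimate_tau2_reml",
    "estimate_tau2",
    "q_generalized",
    "restricted_loglikelihood",
]

#: number of bracket doublings allowed before PM/REML declare non-convergence
_MAX_DOUBLINGS = 60


class EstimationError(RuntimeError):
    """Raised when a tau^2 estimator cannot be applied or fails to converge."""


@dataclass(frozen=True)
class Tau2Estimate:
    """A between-study variance estimate.

    ``estimator`` is one of ``{"DL", "PM", "REML", "fixed"}``; ``"fixed"``
    marks a user-supplied value (e.g. a known true tau^2) that bypassed
    estimation. ``converged`` is always True for closed-form estimators.
    """

    value: float
    estimator: str
    converged: bool = True
    iterations: int = 0

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("tau^2 must be nonnegative")


def _require_studies(data: StudySet, minimum: int = 2) -> None:
    if data.n < minimum:
        raise EstimationError(
            f"between-study variance estimation requires at least {minimum} "
            f"studies, got {data.n}"
        )


def estimate_tau2_dl(data: StudySet) -> Tau2Estimate:
    """DerSimonian-Laird moment estimator, truncated at zero."""
    _require_studies(data)
    w = 1.0 / data.v
    theta_fe = np.sum(w * data.y) / np.sum(w)
    q = np.sum(w * (data.y - theta_fe) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    value = max(0.0, (q - (data.n - 1)) / c)
    return Tau2Estimate(value=value, estimator="DL")


def q_generalized(data: StudySet, tau2: float) -> float:
    """Generalized Q statistic at a candidate tau^2."""
    w = 1.0 / (data.v + tau2)
    theta = np.sum(w * data.y) / np.sum(w)
    return float(np.sum(w * (data.y - theta) ** 2))


def _initial_upper(data: StudySet) -> float:
    spread = float(np.var(data.y, ddof=1)) if data.n > 1 else 0.0
    return 10.0 * (float(np.max(data.v)) + spread) + 1e-8


def estimate_tau2_pm(data: StudySet, tol: float = 1e-10) -> Tau2Estimate:
    """Paule-Mandel estimator: root of Q_gen(tau^2) = n - 1."""
    _require_studies(data)
    df = data.n - 1
    if q_generalized(data, 0.0) <= df:
        return Tau2Estimate(value=0.0, estimator="PM")
    upper = _initial_upper(data)
    doublings = 0
    while q_generalized(data, upper) > df:
        upper *= 2.0
        doublings += 1
        if doublings > _MAX_DOUBLINGS:
            raise EstimationError(
                f"Paule-Mandel bracket expansion failed; last bracket "
                f"[0, {upper:g}]"
            )
    # bracketing root-finder run essentially to machine precision so the
    # moment condition Q_gen(tau^2) = n - 1 holds to well within tol
    root, res = optimize.brentq(
        lambda t: q_generalized(data, t) - df,
        0.0,
        upper,
        xtol=min(tol, 1e-13),
        rtol=4.0 * np.finfo(float).eps,
        full_output=True,
    )
    return Tau2Estimate(
        value=float(max(0.0, root)),
        estimator="PM",
        converged=bool(res.converged),
        iterations=int(res.iterations),
    )


def restricted_loglikelihood(data: StudySet, tau2: float) -> float:
    """Restricted log-likelihood of tau^2 (additive constants dropped)."""
    s = data.v + tau2
    w = 1.0 / s
    theta = np.sum(w * data.y) / np.sum(w)
    return float(
        -0.5 * np.sum(np.log(s))
        - 0.5 * np.log(np.sum(w))
        - 0.5 * np.sum(w * (data.y - theta) ** 2)
    )


def estimate_tau2_reml(
    data: StudySet, tol: float = 1e-8, max_iter: int = 500
) -> Tau2Estimate:
    """REML estimator via bounded scalar maximization over [0, U].

    If the maximizer presses the upper bound U, U is doubled and the
    optimization repeated. Non-convergence is flagged in ``converged``
    (the last iterate is still returned; no exception is raised).
    """
    _require_studies(data)
    upper = _initial_upper(data)
    iterations = 0
    converged = False
    value = 0.0
    for _ in range(_MAX_DOUBLINGS):
        res = optimize.minimize_scalar(
            lambda t: -restricted_loglikelihood(data, t),
            bounds=(0.0, upper),
            method="bounded",
            options={"xatol": tol, "maxiter": max_iter},
        )
        iterations += int(res.nfev)
        value = float(max(0.0, res.x))
        converged = bool(res.success)
        if value < upper - 10.0 * tol * (1.0 + upper):
            break
        upper *= 2.0
    else:
        converged = False
    return Tau2Estimate(
        value=value, estimator="REML", converged=converged, iterations=iterations
    )


_ESTIMATORS = {
    "dl": estimate_tau2_dl,
    "pm": estimate_tau2_pm,
    "reml": estimate_tau2_reml,
}


def estimate_tau2(data: StudySet, method: str = "reml", **kwargs) -> Tau2Estimate:
    """Dispatch to a tau^2 estimator by name (``dl``, ``pm`` or ``reml``)."""
    key = method.lower()
    if key not in _ESTIMATORS:
        raise ValueError(
            f"unknown tau^2 estimator {method!r}; choose from "
            f"{sorted(_ESTIMATORS)}"
        )
    return _ESTIMATORS[key](data, **kwargs)
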