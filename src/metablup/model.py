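"""Model/Results interface for random-effects meta-analysis with shrinkage.

``RandomEffectsMeta`` is built from study-level data; its :meth:`fit` returns
a ``RandomEffectsMetaResults`` carrying the between-study variance estimate,
the pooled effect with its interval, the empirical Bayes / BLUP study
estimates with study-specific prediction intervals, and a text ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data import StudySet
from .heterogeneity import Tau2Estimate, estimate_tau2
from .inference import (
    Interval,
    RandomEffectsFit,
    fit_random_effects,
    new_study_prediction_interval,
    pooled_confidence_interval,
)
from .shrinkage import FORMULAE, ShrinkageEstimate, study_prediction_intervals

__all__ = ["RandomEffectsMeta", "RandomEffectsMetaResults", "MetaAnalysisReport", "run_full_analysis"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetaAnalysisReport:
    """Everything a forest plot or report table needs, from one StudySet."""

    data: StudySet
    fit: RandomEffectsFit
    shrinkage: ShrinkageEstimate
    pooled_ci: Interval
    new_study_pi: Optional[Interval]
    study_cis: list
    provenance: dict


class RandomEffectsMeta:
    """Random-effects meta-analysis model for per-study estimates.

    Parameters
    ----------
    y, v : array_like
        Effect estimates and their within-study variances.
    labels : sequence of str, optional
        Study identifiers.
    """

    def __init__(self, y, v, labels=None):
        self.data = y if isinstance(y, StudySet) else StudySet(y=y, v=v, labels=labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **cols) -> "RandomEffectsMeta":
        return cls(StudySet.from_dataframe(df, **cols), None)

    @classmethod
    def from_csv(cls, path, **cols) -> "RandomEffectsMeta":
        return cls(StudySet.from_dataframe(pd.read_csv(path), **cols), None)

    def fit(
        self,
        method: str = "reml",
        tau2: Optional[float] = None,
        level: float = 0.95,
        use_kh: bool = False,
        formula: str = "raudenbush",
        **estimator_kwargs,
    ) -> "RandomEffectsMetaResults":
        """Estimate tau^2 (or plug in a fixed value) and pool the studies.

        Parameters
        ----------
        method : {"reml", "dl", "pm", "fixed"}
            Between-study variance estimator; ``"fixed"`` uses ``tau2``.
        tau2 : float, optional
            Known between-study variance, used when ``method="fixed"``.
        use_kh : bool
            Apply the Knapp-Hartung adjustment (requires n >= 2).
        formula : {"crude", "raudenbush", "quan"}
            Default variance formula for study-specific prediction intervals.
        """
        if formula not in FORMULAE:
            raise ValueError(f"unknown variance formula {formula!r}")
        if method == "fixed":
            if tau2 is None:
                raise ValueError('method="fixed" requires a tau2 value')
            t2 = Tau2Estimate(value=float(tau2), estimator="fixed")
        else:
            t2 = estimate_tau2(self.data, method=method, **estimator_kwargs)
            if not t2.converged:
                logger.warning(
                    "tau^2 estimation (%s) did not converge; using last "
                    "iterate %.6g",
                    t2.estimator,
                    t2.value,
                )
        if formula == "quan":
            logger.warning(
                "the Quan formula is a variance for the average effect, "
                "not the study-specific effects; its intervals miscover "
                "theta_i"
            )
        fit = fit_random_effects(self.data, t2, level=level)
        if use_kh:
            from .inference import with_knapp_hartung

            fit = with_knapp_hartung(self.data, fit)
        return RandomEffectsMetaResults(
            model=self, fit=fit, use_kh=use_kh, formula=formula
        )


class RandomEffectsMetaResults:
    """Fit results: pooled effect, heterogeneity, shrinkage and intervals."""

    def __init__(self, model, fit: RandomEffectsFit, use_kh: bool, formula: str):
        self.model = model
        self.data: StudySet = model.data
        self.fit: RandomEffectsFit = fit
        self.use_kh = use_kh
        self.formula = formula
        self._shrinkage_cache = {}

    # -- pooled quantities -------------------------------------------------
    @property
    def tau2(self) -> float:
        return self.fit.tau2.value

    @property
    def theta_hat(self) -> float:
        return self.fit.theta_hat

    @property
    def se(self) -> float:
        return self.fit.se_theta_hat

    @property
    def weights(self) -> np.ndarray:
        return self.fit.weights

    @property
    def kh_scale(self) -> Optional[float]:
        return self.fit.kh_scale

    @property
    def i2(self) -> float:
        """I^2 with the Higgins-Thompson typical within-study variance."""
        w = 1.0 / self.data.v
        s2 = (self.data.n - 1) * np.sum(w) / (np.sum(w) ** 2 - np.sum(w**2))
        return float(self.tau2 / (s2 + self.tau2))

    def conf_int(self) -> Interval:
        """Confidence interval for the average effect."""
        return pooled_confidence_interval(self.fit, self.data, use_kh=self.use_kh)

    def new_study_prediction_interval(self) -> Interval:
        """Prediction interval for the true effect in a new study (n >= 3)."""
        return new_study_prediction_interval(self.fit, self.data.n)

    # -- study-specific quantities ----------------------------------------
    def shrinkage(self, formula: Optional[str] = None) -> ShrinkageEstimate:
        """Empirical Bayes estimates and study-specific prediction intervals."""
        formula = formula or self.formula
        if formula not in self._shrinkage_cache:
            self._shrinkage_cache[formula] = study_prediction_intervals(
                self.data, self.fit, formula=formula, use_kh=self.use_kh
            )
        return self._shrinkage_cache[formula]

    def study_confidence_intervals(self) -> list:
        """Conventional per-study intervals Y_i +/- z sqrt(v_i)."""
        z = stats.norm.ppf(1.0 - (1.0 - self.fit.level) / 2.0)
        half = z * self.data.se
        return [
            Interval(lo, up, level=self.fit.level)
            for lo, up in zip(self.data.y - half, self.data.y + half)
        ]

    def report(self) -> MetaAnalysisReport:
        new_pi = (
            self.new_study_prediction_interval() if self.data.n >= 3 else None
        )
        return MetaAnalysisReport(
            data=self.data,
            fit=self.fit,
            shrinkage=self.shrinkage(),
            pooled_ci=self.conf_int(),
            new_study_pi=new_pi,
            study_cis=self.study_confidence_intervals(),
            provenance={
                "tau2_estimator": self.fit.tau2.estimator,
                "formula": self.formula,
                "level": self.fit.level,
                "use_kh": self.use_kh,
            },
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-study table: data, conventional CIs, shrinkage estimates, PIs."""
        shr = self.shrinkage()
        cis = self.study_confidence_intervals()
        return pd.DataFrame(
            {
                "study": self.data.labels,
                "yi": self.data.y,
                "vi": self.data.v,
                "ci_lower": [c.lower for c in cis],
                "ci_upper": [c.upper for c in cis],
                "B": shr.B,
                "theta_i": shr.theta_i,
                "gamma_i": shr.gamma_i,
                "pi_lower": shr.lower,
                "pi_upper": shr.upper,
            }
        )

    def plot_forest(self, path=None, **options):
        """Forest plot with empirical Bayes estimates and prediction intervals."""
        from .plotting import forest_plot

        return forest_plot(self.report(), path=path, **options)

    def summary(self) -> str:
        """Human-readable summary (3 decimals, matching common reporting)."""
        ci = self.conf_int()
        lines = [
            "Random-effects meta-analysis",
            "=" * 64,
            f"Studies:               {self.data.n}",
            f"tau^2 ({self.fit.tau2.estimator}):          {self.tau2:.3f}",
            f"I^2:                   {100 * self.i2:.1f}%",
            f"Pooled estimate:       {self.theta_hat:.3f}  (SE {self.se:.3f})",
            f"{100 * self.fit.level:.0f}% CI"
            + (" (KH)" if self.use_kh else "")
            + f":           [{ci.lower:.3f}, {ci.upper:.3f}]",
        ]
        if self.data.n >= 3:
            pi = self.new_study_prediction_interval()
            lines.append(
                f"New-study {100 * self.fit.level:.0f}% PI:      "
                f"[{pi.lower:.3f}, {pi.upper:.3f}]"
            )
        lines.append("-" * 64)
        lines.append(
            f"Study-specific prediction intervals ({self.formula} formula)"
        )
        frame = self.to_frame()
        with pd.option_context("display.float_format", "{:.3f}".format):
            lines.append(frame.to_string(index=False))
        return "\n".join(lines)


def run_full_analysis(
    data: StudySet,
    method: str = "reml",
    formula: str = "raudenbush",
    level: float = 0.95,
    use_kh: bool = False,
    tau2: Optional[float] = None,
) -> MetaAnalysisReport:
    """End-to-end pipeline: estimate tau^2, pool, shrink, and report."""
    res = RandomEffectsMeta(data, None).fit(
        method=method, tau2=tau2, level=level, use_kh=use_kh, formula=formula
    )
    return res.report()
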