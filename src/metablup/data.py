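"""Study-level meta-analytic data: effect estimates and within-study variances.

The observed input to a random-effects meta-analysis is a set of per-study
effect estimates :math:`Y_i` (on any outcome scale: standardized mean
difference, log odds ratio, ...) together with their within-study sampling
variances :math:`\\sigma_i^2`, which are treated as fixed and known
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StudySet", "SchemaError", "read_study_table"]


class SchemaError(ValueError):
    """Raised when an input study table lacks a required column."""


@dataclass(frozen=True)
class StudySet:
    """Per-study effect estimates and within-study variances.

    Parameters
    ----------
    y : array_like
        Effect estimate of each study (:math:`Y_i`), in outcome units.
    v : array_like
        Within-study variance of each estimate (:math:`\\sigma_i^2`),
        in squared outcome units. Must be strictly positive and finite.
    labels : sequence of str, optional
        Study identifiers; defaults to ``"study 1"``, ``"study 2"``, ...
    """

    y: np.ndarray
    v: np.ndarray
    labels: tuple = field(default=None)

    def __post_init__(self):
        y = np.atleast_1d(np.asarray(self.y, dtype=float))
        v = np.atleast_1d(np.asarray(self.v, dtype=float))
        if y.ndim != 1 or v.ndim != 1 or y.shape != v.shape:
            raise ValueError("y and v must be one-dimensional and of equal length")
        if y.size < 1:
            raise ValueError("a StudySet needs at least one study")
        if not np.all(np.isfinite(y)):
            raise ValueError("all effect estimates y must be finite")
        if not (np.all(np.isfinite(v)) and np.all(v > 0)):
            raise ValueError("all within-study variances v must be finite and > 0")
        labels = self.labels
        if labels is None:
            labels = tuple(f"study {i + 1}" for i in range(y.size))
        else:
            labels = tuple(str(lab) for lab in labels)
            if len(labels) != y.size:
                raise ValueError("labels length must match the number of studies")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        """Number of studies."""
        return self.y.size

    def __len__(self) -> int:
        return self.n

    @property
    def se(self) -> np.ndarray:
        """Within-study standard errors, sqrt(v)."""
        return np.sqrt(self.v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"study": self.labels, "yi": self.y, "vi": self.v})

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        effect_col: str = "yi",
        variance_col: str = "vi",
        se_col: str = "sei",
        label_col: str = "study",
    ) -> "StudySet":
        """Build a StudySet from a data frame.

        The frame must contain ``effect_col`` and either ``variance_col`` or
        ``se_col`` (the standard error is squared to obtain the variance).
        """
        if effect_col not in df.columns:
            raise SchemaError(f"missing required effect column {effect_col!r}")
        if variance_col in df.columns:
            var = _numeric(df[variance_col], variance_col)
        elif se_col in df.columns:
            var = _numeric(df[se_col], se_col) ** 2
        else:
            raise SchemaError(
                f"need a variance column {variance_col!r} or a standard-error "
                f"column {se_col!r}"
            )
        y = _numeric(df[effect_col], effect_col)
        if np.any(var <= 0):
            bad = int(np.flatnonzero(var <= 0)[0])
            raise ValueError(f"non-positive within-study variance in row {bad + 1}")
        labels = (
            tuple(str(s) for s in df[label_col])
            if label_col in df.columns
            else None
        )
        return cls(y=y, v=var, labels=labels)


def _numeric(col: pd.Series, name: str) -> np.ndarray:
    out = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(out))
    if bad.size:
        raise ValueError(
            f"non-numeric value {col.iloc[bad[0]]!r} in column {name!r}, "
            f"row {bad[0] + 1}"
        )
    return out


def read_study_table(
    path,
    effect_col: str = "yi",
    variance_col: str = "vi",
    se_col: str = "sei",
    label_col: str = "study",
) -> StudySet:
    """Read a delimited study table (CSV with header) into a StudySet.

    Row order is preserved. ``variance_col`` takes precedence over
    ``se_col`` when both are present.
    """
    df = pd.read_csv(path)
    return StudySet.from_dataframe(
        df,
        effect_col=effect_col,
        variance_col=variance_col,
        se_col=se_col,
        label_col=label_col,
    )
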