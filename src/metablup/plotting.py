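"""Forest plots embellished with empirical Bayes estimates.

Each study occupies one row showing the conventional estimate Y_i (square,
solid confidence-interval line) and, offset just below it, the empirical
Bayes / BLUP estimate theta_hat_i (circle, dashed study-specific prediction
interval). Marker areas scale with the random-effects weight w_i, so more
precise studies draw larger. A summary diamond shows the pooled estimate
(width = pooled confidence interval) with dashed whiskers for the new-study
prediction interval when at least three studies are available. The
shrinkage layer is drawn in addition to — never instead of — the
conventional display.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .model import MetaAnalysisReport

__all__ = ["forest_plot"]

_MAX_MARKER_AREA = 120.0  # points^2 for the most precise study


def forest_plot(
    report: MetaAnalysisReport,
    path=None,
    ax=None,
    show_shrinkage: bool = True,
    xlabel: str = "Effect size",
):
    """Draw a forest plot for a :class:`MetaAnalysisReport`.

    Parameters
    ----------
    report : MetaAnalysisReport
        Output of ``RandomEffectsMetaResults.report()`` / ``run_full_analysis``.
    path : path-like, optional
        When given the figure is written there (vector formats such as
        ``.pdf``/``.svg`` preferred) and closed.
    show_shrinkage : bool
        Disable to obtain a conventional forest plot only.

    Returns
    -------
    matplotlib.axes.Axes
    """
    data = report.data
    n = data.n
    if n < 1:
        raise ValueError("cannot plot an empty report")
    if ax is None:
        _, ax = plt.subplots(figsize=(7.0, 1.0 + 0.6 * (n + 1)))

    weights = report.fit.weights
    area = _MAX_MARKER_AREA * weights / weights.max()
    rows = np.arange(n, 0, -1, dtype=float)  # study 1 on top, summary at 0

    for i in range(n):
        ci = report.study_cis[i]
        ax.plot([ci.lower, ci.upper], [rows[i], rows[i]], color="black", lw=1.2)
    ax.scatter(
        data.y, rows, s=area, marker="s", color="black", zorder=3, label="$Y_i$"
    )

    if show_shrinkage:
        shr = report.shrinkage
        off = rows - 0.28
        for i in range(n):
            ax.plot(
                [shr.lower[i], shr.upper[i]],
                [off[i], off[i]],
                color="0.35",
                lw=1.2,
                ls="--",
            )
        ax.scatter(
            shr.theta_i,
            off,
            s=area,
            marker="o",
            facecolors="white",
            edgecolors="0.35",
            zorder=3,
            label=r"$\hat\theta_i$",
        )

    # summary diamond: midpoint theta_hat, width = pooled CI
    ci = report.pooled_ci
    theta = report.fit.theta_hat
    h = 0.22
    ax.fill(
        [ci.lower, theta, ci.upper, theta],
        [0.0, h, 0.0, -h],
        color="black",
        zorder=3,
    )
    if report.new_study_pi is not None:
        pi = report.new_study_pi
        ax.plot([pi.lower, ci.lower], [0.0, 0.0], color="black", ls="--", lw=1.2)
        ax.plot([ci.upper, pi.upper], [0.0, 0.0], color="black", ls="--", lw=1.2)

    ax.axvline(theta, color="0.7", lw=0.8, zorder=0)
    ax.set_yticks(np.concatenate([rows, [0.0]]))
    ax.set_yticklabels(list(data.labels) + ["RE model"])
    ax.set_ylim(-0.8, n + 0.8)
    ax.set_xlabel(xlabel)
    ax.legend(loc="best", frameon=False, fontsize=8)
    ax.figure.tight_layout()

    if path is not None:
        ax.figure.savefig(path)
        plt.close(ax.figure)
    return ax
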