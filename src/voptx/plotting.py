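"""Diagnostic plots: bound-vs-actual scatters and compression trade-off curves."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import ComparisonCurve, EvaluationReport

__all__ = ["plot_overestimation_scatter", "plot_comparison_curves"]


def plot_overestimation_scatter(report: EvaluationReport, ax=None, title: str = ""):
    """VOP-bounded SAR versus actual maximum local SAR, with the unity line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(report.actual_sar, report.vop_sar, s=2, alpha=0.3, rasterized=True)
    lim = float(max(report.actual_sar.max(), report.vop_sar.max()))
    ax.plot([0, lim], [0, lim], color="gold", lw=1.2, label="zero overestimation")
    i = report.argmax_vector_index
    ax.plot(
        report.actual_sar[i],
        report.vop_sar[i],
        "rx",
        ms=9,
        label=f"max rel. overestimation {report.max_relative_overestimation:.1f}%",
    )
    ax.set_xlabel("actual max local SAR (W/kg)")
    ax.set_ylabel("VOP-bounded SAR (W/kg)")
    ax.set_title(title or report.metadata.get("strategy", ""))
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_comparison_curves(curves: Sequence[ComparisonCurve], ax=None):
    """Maximum relative overestimation (%) versus total VOP count, per strategy."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    by_tag: dict[str, list] = {}
    for c in curves:
        by_tag.setdefault(c.strategy_tag, []).extend(c.points)
    for tag, pts in by_tag.items():
        pts = sorted(pts, key=lambda p: p[1])
        n = np.array([p[1] for p in pts])
        rel = np.array([p[2] for p in pts])
        ax.plot(n, rel, "x-", label=tag)
    ax.set_xlabel("number of VOPs (incl. pre-VOPs)")
    ax.set_ylabel("max relative overestimation (%)")
    ax.set_yscale("log")
    ax.legend()
    return ax
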