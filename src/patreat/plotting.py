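"""Plot helpers for fitted results (matplotlib, Agg-safe).

Each function accepts an optional ``ax`` and returns the axes, so the
plots compose into panel figures.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_gompertz_fit", "plot_roc", "plot_depth_bias"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_gompertz_fit(results, ax=None, show_data: bool = True):
    """Fitted volume-time curve with the observations it was fit to."""
    ax = _axes(ax)
    days = results.model.days
    t = np.linspace(0, max(days.max() * 1.1, days.max() + 2), 300)
    ax.plot(t, results.predict(t), label="Gompertz fit")
    if show_data:
        ax.plot(days, results.model.volumes, "o", label="observed")
    ax.set_xlabel("days post-implantation")
    ax.set_ylabel("tumor volume (mm$^3$)")
    ax.legend()
    return ax


def plot_roc(roc, ax=None, label: str | None = None):
    """Empirical ROC step curve with the chance diagonal and AUC label."""
    ax = _axes(ax)
    lbl = label or f"AUC = {roc.auc:.3f}"
    ax.step(roc.fpr, roc.tpr, where="post", label=lbl)
    ax.plot([0, 1], [0, 1], ls=":", color="grey")
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right")
    return ax


def plot_depth_bias(profile, ax=None):
    """Estimated StO2 (mean +/- SD) vs depth, against the ground truth."""
    ax = _axes(ax)
    ax.errorbar(
        profile["depth_mm"], profile["mean_sto2"], yerr=profile["sd_sto2"],
        marker="o", label="estimated",
    )
    ax.plot(profile["depth_mm"], profile["truth_sto2"], ls="--", label="truth")
    ax.set_xlabel("tube depth (mm)")
    ax.set_ylabel("StO$_2$ (%)")
    ax.legend()
    return ax
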