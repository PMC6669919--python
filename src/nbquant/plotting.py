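"""Plots for FRAP results: mean recovery curve with SD band and fit overlay."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .frap import MeanCurve, RecoveryFit

__all__ = ["plot_recovery"]


def plot_recovery(
    mean_curve: MeanCurve,
    fit: RecoveryFit | None = None,
    path: str | Path | None = None,
    title: str = "FRAP recovery",
):
    """Mean normalized recovery (black) with SD band (gray) and, when given,
    the fitted curve (red) — the standard presentation of averaged FRAP data."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    t, m, s = mean_curve.times_s, mean_curve.mean, mean_curve.sd
    ax.fill_between(t, m - s, m + s, color="0.8", label="SD")
    ax.plot(t, m, "k-", lw=1.5, label=f"mean (n={mean_curve.n})")
    if fit is not None:
        ax.plot(t, fit.predict(t), "r-", lw=1.2, label=f"{fit.model} fit")
    ax.set_xlabel("time after bleach (s)")
    ax.set_ylabel("normalized intensity")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
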