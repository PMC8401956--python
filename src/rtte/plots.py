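"""Plotting helpers for visual predictive checks and hazard shapes."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .hazard import HazardModel, hazard
from .simulate import VPCBand, VPCResult

__all__ = ["plot_vpc", "plot_hazard_shape"]


def _draw_band(ax, band: VPCBand) -> None:
    ax.fill_between(band.grid, band.pi_lo, band.pi_hi, alpha=0.3, lw=0,
                    label="95% prediction interval")
    ax.plot(band.grid, band.pi_med, ls="--", lw=1, label="simulated median")
    ax.plot(band.grid, band.observed, drawstyle="steps-post", color="black",
            lw=1.5, label="observed KM")
    # censoring marks on the observed curve
    c = band.observed_curve
    if c.censor_times.size:
        from .simulate import km_evaluate

        y = km_evaluate(c, c.censor_times)
        ax.plot(c.censor_times, y, "|", color="black", ms=8)
    ax.set_xlabel("weeks since first dose")
    ax.set_ylabel("fraction without improvement")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(band.stratum)


def plot_vpc(result: VPCResult, path=None):
    """One panel per stratum: observed KM over the simulated percentile band."""
    n = len(result.bands)
    fig, axes = plt.subplots(1, n, figsize=(6 * n, 4.5), squeeze=False)
    for ax, band in zip(axes[0], result.bands):
        _draw_band(ax, band)
    axes[0][0].legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_hazard_shape(model: HazardModel, horizon: float = 800.0, path=None):
    """Baseline hazard over time for a reference subject (eta = 0)."""
    t = np.linspace(1e-6, horizon, 512)
    cov = {e.name: e.center for e in model.effects}
    h = hazard(model, t, cov=cov or None)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(t, h)
    ax.set_xlabel("weeks since first dose")
    ax.set_ylabel("hazard of improvement (per week)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
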