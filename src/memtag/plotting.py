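"""Headless-safe figures for the test-period analyses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402  headless by construction
import matplotlib.pyplot as plt
import numpy as np

from .model_free import DeltaForceSeries, moving_average

__all__ = ["plot_delta_force", "plot_residual_blocks"]


def plot_delta_force(series: DeltaForceSeries, ax=None, smooth: int = 5):
    """ΔForce over the test period with the bootstrap SD band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    n = np.arange(1, len(series.values) + 1)
    ax.plot(n, moving_average(series.values, smooth), color="k", lw=2,
            label="ΔForce (moving avg)")
    if series.boot_mean is not None:
        mid = moving_average(series.boot_mean, smooth)
        sd = moving_average(series.boot_sd, smooth)
        ax.fill_between(n, mid - sd, mid + sd, color="0.7", alpha=0.6,
                        label="bootstrap ±SD")
    for b in (22.5, 44.5, 66.5):
        ax.axvline(b, color="0.85", lw=4, zorder=0)
    ax.axhline(0, color="0.5", lw=0.8)
    ax.set_xlabel("test trial")
    ax.set_ylabel("ΔForce (N)")
    ax.legend(frameon=False)
    return ax


def plot_residual_blocks(block_means_by_subgroup: dict[str, np.ndarray], ax=None):
    """Blockwise residual means per subgroup (anti-phase under a true effect)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    blocks = np.arange(1, 5)
    styles = {"ACAC": "--o", "CACA": "-s"}
    for sub, means in block_means_by_subgroup.items():
        ax.plot(blocks, means, styles.get(sub, "-o"), label=sub, mfc="w")
    ax.axhline(0, color="0.5", lw=0.8)
    ax.set_xticks(blocks)
    ax.set_xlabel("test block")
    ax.set_ylabel("mean residual (N)")
    ax.legend(frameon=False)
    return ax
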