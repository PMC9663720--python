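"""Figure export: activation overlays and bootstrap stability curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .activation import ActivationResult  # noqa: E402
from .robustness import BootstrapCurve  # noqa: E402

__all__ = ["save_activation_overlay", "save_bootstrap_plot"]


def save_activation_overlay(path: str | Path, result: ActivationResult,
                            background: np.ndarray) -> None:
    """z-score map thresholded by Bonferroni, overlaid on a grayscale image."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(background, cmap="gray")
    z = np.where(result.significant_mask, result.zscore_map, np.nan)
    im = ax.imshow(z, cmap="hot", interpolation="nearest")
    ax.plot(result.roi_center[1], result.roi_center[0], "c+", markersize=12)
    fig.colorbar(im, ax=ax, label="z-score")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_bootstrap_plot(path: str | Path, curve: BootstrapCurve) -> None:
    """Mean +/- sd of each fitted parameter versus the number of trials."""
    params = list(curve.mean)
    fig, axes = plt.subplots(1, len(params), figsize=(4 * len(params), 3),
                             squeeze=False)
    for ax, name in zip(axes[0], params):
        m, s = curve.mean[name], curve.sd[name]
        ax.fill_between(curve.subset_sizes, m - s, m + s, alpha=0.3)
        ax.plot(curve.subset_sizes, m)
        ax.set_xlabel("number of trials")
        ax.set_title(name.replace("_", " "))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
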