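"""Optional per-image diagnostic figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_MASK_CMAP = matplotlib.colors.ListedColormap(["white", "#7bc96f", "#5a3a29"])


def plot_segmentation(mask, path: Path) -> None:
    """Save the cleaned label mask (white/green/brown = bg/hair/root)."""
    fig, ax = plt.subplots(figsize=(4, 8))
    ax.imshow(mask.labels, cmap=_MASK_CMAP, vmin=0, vmax=2, interpolation="nearest")
    ax.set_title("segmentation")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_transformation(before, after, path: Path) -> None:
    """Save a before/after view of the straightening warp."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 8))
    for ax, m, title in zip(axes, (before, after), ("input", "straightened")):
        ax.imshow(m.labels, cmap=_MASK_CMAP, vmin=0, vmax=2, interpolation="nearest")
        ax.set_title(title)
        ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_summary(profile, ez, path: Path) -> None:
    """RHL / RHA profiles per side with the elongation zone marked."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = profile.distance_mm
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    for side, col in (("left", "tab:green"), ("right", "tab:purple")):
        y = profile.rhl_left if side == "left" else profile.rhl_right
        ax1.plot(x, y, ".", color=col, label=f"{side} RHL")
        if len(x) >= 5:
            fit = lowess(y, x, frac=0.1, it=0, return_sorted=False)
            ax1.plot(x, fit, "--", color=col, alpha=0.7)
        a = profile.rha_left if side == "left" else profile.rha_right
        ax2.plot(x, a, ".", color=col, label=f"{side} RHA")
    mean_rhl = np.mean(np.concatenate([profile.rhl_left, profile.rhl_right]))
    ax1.axhline(mean_rhl, ls="--", color="plum", label="mean RHL")
    if ez is not None and np.isfinite(ez.start):
        for ax in (ax1, ax2):
            ax.axvline(ez.start, ls="--", color="maroon")
            ax.axvline(ez.end, ls="--", color="maroon")
    ax1.set_ylabel("RHL (mm)")
    ax2.set_ylabel("RHA (mm$^2$)")
    ax2.set_xlabel("distance from tip (mm)")
    ax1.legend(fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
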