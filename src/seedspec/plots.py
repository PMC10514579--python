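"""Diagnostic plots: selection criterion curves, loss curves, confusion matrices."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .selection import SelectionResult

__all__ = ["plot_criterion_curve", "plot_band_counts", "plot_loss_curves", "plot_confusion"]


def plot_criterion_curve(result: SelectionResult, path) -> None:
    """RMSE vs subset size (SPA) or RMSECV vs sampling run (CARS)."""
    steps = [s for s, _ in result.criterion_curve]
    vals = [v for _, v in result.criterion_curve]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(steps, vals, "o-", ms=3)
    if result.chosen_step is not None:
        s, v = result.criterion_curve[result.chosen_step]
        ax.plot([s], [v], "r*", ms=12, label=f"chosen ({result.n_selected} bands)")
        ax.legend()
    ax.set_xlabel("number of variables" if result.method == "spa" else "sampling run")
    ax.set_ylabel("RMSE" if result.method == "spa" else "RMSECV")
    ax.set_title(f"{result.method.upper()} criterion curve")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_band_counts(result: SelectionResult, path) -> None:
    """Retained-band count per step (the CARS coarse-to-fine descent)."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(range(1, len(result.subsets_per_step) + 1), [len(s) for s in result.subsets_per_step], "o-", ms=3)
    ax.set_xlabel("sampling run")
    ax.set_ylabel("retained bands")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_loss_curves(histories: dict[str, list[float]], path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    for name, hist in histories.items():
        ax.plot(hist, label=name, lw=1)
    ax.set_xlabel("epoch")
    ax.set_ylabel("cross-entropy loss")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_confusion(confusion: np.ndarray, path, title: str = "") -> None:
    conf = np.asarray(confusion)
    fig, ax = plt.subplots(figsize=(4.2, 3.8))
    im = ax.imshow(conf, cmap="Blues")
    for i in range(conf.shape[0]):
        for j in range(conf.shape[1]):
            ax.text(j, i, str(conf[i, j]), ha="center", va="center", fontsize=7)
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    if title:
        ax.set_title(title)
    fig.colorbar(im, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
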