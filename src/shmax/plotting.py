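"""Figure exports: STRF mosaics, PSI heatmaps, TVI scatter."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_strf_mosaic", "plot_psi_heatmap", "plot_tvi_scatter"]


def plot_strf_mosaic(strfs, path, n_cols: int = 8):
    """Save a grid of STRF matrices (low frequency at the bottom)."""
    n = len(strfs)
    n_rows = int(np.ceil(n / n_cols))
    fig, axes = plt.subplots(n_rows, n_cols, figsize=(1.4 * n_cols, 1.4 * n_rows))
    axes = np.atleast_1d(axes).ravel()
    for ax in axes:
        ax.axis("off")
    for ax, m in zip(axes, strfs):
        v = np.max(np.abs(m)) or 1.0
        ax.imshow(m, origin="lower", cmap="RdBu_r", vmin=-v, vmax=v, aspect="auto")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_psi_heatmap(psi, path):
    """Units-by-phonemes PSI heatmap ordered by group and dendrogram."""
    values = psi.values
    order_u = np.argsort(psi.groups) if psi.groups is not None else np.arange(len(values))
    order_p = psi.phoneme_order if psi.phoneme_order is not None else \
        np.arange(values.shape[1])
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(values[order_u][:, order_p].T, aspect="auto", cmap="magma")
    ax.set_xlabel("unit (grouped)")
    ax.set_ylabel("phoneme")
    ax.set_yticks(range(len(order_p)))
    ax.set_yticklabels([psi.phoneme_labels[i] for i in order_p], fontsize=6)
    fig.colorbar(im, ax=ax, label="PSI")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tvi_scatter(corr_f1, corr_f2, path):
    """Per-unit F1-TVI vs F2-TVI response correlations."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(corr_f1, corr_f2, s=12, alpha=0.7)
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_xlim(-1, 1)
    ax.set_ylim(-1, 1)
    ax.set_xlabel("correlation with F1 TVI")
    ax.set_ylabel("correlation with F2 TVI")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
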