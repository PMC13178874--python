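"""Plotting helpers: DCI radar charts and traversal heatmap grids."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_dci_radar", "save_tmap_grid"]


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_dci_radar(scores_by_stream: dict[str, dict[str, float]], path=None):
    """Radar chart of D/C/I per stream (one polygon per stream).

    ``scores_by_stream`` maps a stream name to a dict with keys ``D``, ``C``
    and ``I`` in [0, 1].
    """
    plt = _mpl()
    axes_names = ["D", "C", "I"]
    angles = np.linspace(0, 2 * np.pi, len(axes_names), endpoint=False).tolist()
    angles += angles[:1]
    fig, ax = plt.subplots(subplot_kw={"polar": True}, figsize=(5, 5))
    for stream, scores in scores_by_stream.items():
        vals = [float(scores[a]) for a in axes_names]
        vals += vals[:1]
        ax.plot(angles, vals, label=stream)
        ax.fill(angles, vals, alpha=0.12)
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels(axes_names)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def save_tmap_grid(tmaps: dict[int, np.ndarray], path, ncols: int = 8):
    """Save a grid of per-dimension t-map heatmaps."""
    plt = _mpl()
    dims = sorted(tmaps)
    ncols = min(ncols, max(len(dims), 1))
    nrows = int(np.ceil(len(dims) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(1.6 * ncols, 1.6 * nrows), squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for k, dim in enumerate(dims):
        ax = axes[k // ncols][k % ncols]
        ax.imshow(tmaps[dim], cmap="inferno", vmin=0, vmax=1)
        ax.set_title(f"z{dim}", fontsize=7)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
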