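"""Minimal figure export: metagene curves and summit-centered heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_metagene(profiles: pd.DataFrame, path) -> None:
    """One curve per expression class / gene set (rows of ``profiles``)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, row in profiles.iterrows():
        ax.plot(np.arange(len(row)), row.to_numpy(), label=str(name))
    ax.set_xlabel("bin (5' flank | scaled body | 3' flank)")
    ax.set_ylabel("mean CPM coverage")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_summit_heatmap(matrix: np.ndarray, path) -> None:
    """Rows sorted by total signal, one row per summit window."""
    order = np.argsort(-matrix.sum(axis=1))
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(matrix[order], aspect="auto", interpolation="nearest",
                   cmap="viridis")
    fig.colorbar(im, ax=ax, label="coverage")
    ax.set_xlabel("bin")
    ax.set_ylabel("summit windows")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_profile(values: np.ndarray, path, ylabel: str = "mean coverage") -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(values)
    ax.set_xlabel("bin")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
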