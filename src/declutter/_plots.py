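"""Figure rendering for pipeline outputs.

Figures are a convenience view only: every number shown here is also
written to a CSV by the pipeline.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def save_heatmap(matrix, meta, time_s, path) -> None:
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(
        matrix, aspect="auto", interpolation="nearest", cmap="viridis",
        extent=[time_s[0], time_s[-1], matrix.shape[0], 0],
    )
    fig.colorbar(im, ax=ax, label="ΔF/F₀")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cell (grouped, peak-sorted)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_eigenfunctions(model, K, path) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    for k in range(min(K, 3)):
        fve = model.fve[k] * 100
        ax.plot(model.time_s, model.eigenfunctions[k], label=f"ϕ{k + 1} ({fve:.1f}%)")
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("eigenfunction")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_elbow(elbow, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(elbow.ks, elbow.wss, "o-")
    ax.axvline(elbow.suggested_k, color="red", ls="--",
               label=f"suggested k={elbow.suggested_k}")
    ax.set_xlabel("k")
    ax.set_ylabel("within-cluster sum of squares")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_umap(embedding, labels, path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(11, 5))
    groups = embedding.group or ["all"] * len(embedding.coords)
    for g in dict.fromkeys(groups):
        sel = np.asarray([gg == g for gg in groups])
        axes[0].scatter(*embedding.coords[sel].T, s=8, label=g)
    axes[0].set_title("by group")
    axes[0].legend(fontsize=7)
    sc = axes[1].scatter(*embedding.coords.T, c=labels, s=8, cmap="tab10")
    axes[1].set_title("by cluster")
    fig.colorbar(sc, ax=axes[1], label="cluster")
    for ax in axes:
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_profiles(norm, labels, profiles, path) -> None:
    clusters = sorted(profiles["cluster"].unique())
    fig, axes = plt.subplots(1, len(clusters), figsize=(4 * len(clusters), 3.5),
                             sharey=True, squeeze=False)
    labels = np.asarray(labels)
    for ax, k in zip(axes[0], clusters):
        for row in norm.values[labels == k]:
            ax.plot(norm.time_s, row, color="lightgray", lw=0.4)
        med = profiles[profiles["cluster"] == k]
        ax.plot(med["time_s"], med["median_dff"], color="black", lw=1.5)
        ax.set_title(f"cluster {k} (n={int((labels == k).sum())})")
        ax.set_xlabel("time (s)")
    axes[0][0].set_ylabel("ΔF/F₀")
    fig.savefig(path, dpi=120)
    plt.close(fig)
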