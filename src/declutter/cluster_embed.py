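"""k-means clustering of FPC scores, elbow k selection, UMAP display.

Clustering operates on the truncated functional-PCA scores, never on the
2-D embedding: UMAP is display-only, so embedding distortions cannot leak
into cluster assignment.  Scores are used unstandardized by default — their
scale already encodes the eigenvalues — with per-component standardization
available as a sensitivity flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core_io import NormalizedTraceMatrix

DEFAULT_SEED = 2023
DEFAULT_K_RANGE = range(1, 9)


@dataclass
class ClusterResult:
    """Chosen k, per-cell labels (1..k) and the WSS curve behind the choice."""

    k: int
    labels: np.ndarray
    wss_curve: pd.DataFrame  # columns k, wss
    seed: int
    profiles: pd.DataFrame | None = None  # per-cluster median ΔF/F₀ track
    composition: pd.DataFrame | None = None  # group × cluster counts


@dataclass
class Embedding2D:
    """2-D UMAP coordinates with the parameters that produced them."""

    coords: np.ndarray
    parameters: dict = field(default_factory=dict)
    seed: int = DEFAULT_SEED
    cell_ids: list = field(default_factory=list)
    group: list = field(default_factory=list)


@dataclass
class ElbowResult:
    """WSS per candidate k plus the automated elbow suggestion.

    ``low_confidence`` flags a near-flat curve (relative WSS drop at the
    suggested k below 5%): the suggestion should then be reviewed visually,
    e.g. on the UMAP plot.
    """

    ks: np.ndarray
    wss: np.ndarray
    suggested_k: int
    low_confidence: bool

    @property
    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "wss": self.wss})


def kmeans_cluster(
    scores: np.ndarray, k: int, seed: int = DEFAULT_SEED, n_init: int = 10
) -> tuple[np.ndarray, float]:
    """Lloyd k-means with k-means++ init, best of ``n_init`` restarts.

    Labels are renumbered 1..k by decreasing cluster size (ties: smaller
    centroid norm first) so numbering is deterministic under (seed, n_init).
    Returns (labels, WSS).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = scores.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init,
        random_state=seed, algorithm="lloyd",
    ).fit(scores)
    raw = km.labels_
    sizes = np.bincount(raw, minlength=k)
    norms = np.linalg.norm(km.cluster_centers_, axis=1)
    order = sorted(range(k), key=lambda c: (-sizes[c], norms[c]))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[raw], float(km.inertia_)


def elbow_select(
    scores: np.ndarray,
    k_range=DEFAULT_K_RANGE,
    seed: int = DEFAULT_SEED,
    n_init: int = 10,
) -> ElbowResult:
    """WSS curve over candidate k with an automated elbow suggestion.

    The suggestion is the interior k of greatest curvature of the WSS
    curve.  Curvature κ = |y''| / (1 + y'²)^{3/2} is evaluated with central
    differences on the min-max-normalized curve (both axes scaled to [0,1]),
    which keeps the bend detectable when one inter-cluster gap dwarfs the
    others: the raw second difference would then always point at k=2,
    because the k=1 → 2 drop dominates it.  The full curve is always
    returned so a human can override the suggestion.
    """
    ks = np.array(sorted(k_range), dtype=int)
    if ks.size < 3:
        raise ValueError("k_range needs at least 3 values for an interior elbow")
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if ks.max() > scores.shape[0]:
        raise ValueError("largest candidate k exceeds the number of cells")
    wss = np.array([kmeans_cluster(scores, k, seed, n_init)[1] for k in ks])
    span = wss.max() - wss.min()
    y = (wss - wss.min()) / span if span > 0 else np.zeros_like(wss)
    dx = 1.0 / (ks.size - 1)
    d2y = (y[:-2] - 2 * y[1:-1] + y[2:]) / dx**2
    dy = (y[2:] - y[:-2]) / (2 * dx)
    curvature = np.abs(d2y) / (1 + dy**2) ** 1.5
    best_interior = int(np.argmax(curvature)) + 1
    suggested = int(ks[best_interior])
    prev = wss[best_interior - 1]
    drop = (prev - wss[best_interior]) / prev if prev > 0 else 0.0
    return ElbowResult(
        ks=ks, wss=wss, suggested_k=suggested, low_confidence=bool(drop < 0.05)
    )


def embed_umap(
    scores: np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = DEFAULT_SEED,
    cell_ids: list | None = None,
    group: list | None = None,
) -> Embedding2D:
    """2-D UMAP embedding of the FPC scores, reproducible under ``seed``.

    If the dataset is smaller than ``n_neighbors`` the parameter is reduced
    to n − 1 with a warning, and the effective value is recorded in the
    embedding's parameters.
    """
    import umap  # deferred: numba compilation is slow at import time

    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = scores.shape[0]
    effective = n_neighbors
    if n <= n_neighbors:
        effective = max(2, n - 1)
        warnings.warn(
            f"n_neighbors={n_neighbors} >= n_cells={n}; reduced to {effective}"
        )
    reducer = umap.UMAP(
        n_components=2, n_neighbors=effective, min_dist=min_dist, random_state=seed
    )
    coords = reducer.fit_transform(scores)
    return Embedding2D(
        coords=np.asarray(coords, dtype=float),
        parameters={
            "n_neighbors": effective,
            "n_neighbors_requested": n_neighbors,
            "min_dist": min_dist,
        },
        seed=seed,
        cell_ids=list(cell_ids) if cell_ids is not None else [],
        group=list(group) if group is not None else [],
    )


def cluster_profiles(
    norm: NormalizedTraceMatrix, labels: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster pointwise-median ΔF/F₀ track and group × cluster counts."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (norm.n_cells,):
        raise ValueError(
            f"labels length {labels.shape} does not match {norm.n_cells} cells"
        )
    records = []
    for k in np.unique(labels):
        med = np.median(norm.values[labels == k], axis=0)
        for t, v in zip(norm.time_s, med):
            records.append({"cluster": int(k), "time_s": t, "median_dff": v})
    profiles = pd.DataFrame(records)
    composition = (
        pd.crosstab(pd.Series(norm.group, name="group"), pd.Series(labels, name="cluster"))
        .reindex(list(dict.fromkeys(norm.group)))
    )
    return profiles, composition
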