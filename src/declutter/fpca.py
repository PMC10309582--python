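"""Functional PCA of densely sampled ΔF/F₀ traces.

Every cell is observed on the same regular 1 frame/s grid, so the functional
eigenproblem reduces to a weighted eigendecomposition of the raw T×T sample
covariance — no smoothing, fully deterministic:

    eig( W^{1/2} C W^{1/2} ),   C = sample covariance,  W = quadrature weights

Eigenfunctions ϕₖ are normalized to unit L² norm (∫ϕₖ² dt = 1), eigenvalues
λₖ sort descending, and per-cell scores are the quadrature inner products
ξᵢₖ = Σₜ wₜ (Xᵢ(t) − μ(t)) ϕₖ(t).  On a uniform grid the weights are the
Riemann weights wₜ = Δt, which makes the estimator exactly equivalent to
standard PCA of the trace matrix up to Δt scaling (λ = Δt·λ_PCA,
ξ = √Δt·ξ_PCA); for a non-uniform grid trapezoid weights are used and a
warning is emitted.  An optional covariance pre-smoother is reserved as a
config flag but off by default.

Truncating the expansion at the smallest K whose cumulative fraction of
variance explained (FVE) reaches a threshold — 95% by default — denoises the
traces and gives the low-dimensional scores used for clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import NormalizedTraceMatrix

#: eigenvalues below this fraction of the leading one are treated as zero
EIGENVALUE_CLAMP = 1e-12


@dataclass
class FPCAModel:
    """Fitted functional-PCA decomposition of a trace matrix.

    ``eigenvalues`` holds min(n_cells − 1, T) components, clamped-to-zero
    trailing components included; ``k_max`` counts the strictly positive
    ones and bounds reconstruction/truncation.
    """

    time_s: np.ndarray
    mean_fn: np.ndarray
    eigenfunctions: np.ndarray  # (n_components, T)
    eigenvalues: np.ndarray  # descending, >= 0
    scores: np.ndarray  # (n_cells, n_components)
    weights: np.ndarray  # quadrature weights, (T,)

    @property
    def k_max(self) -> int:
        """Number of retained (strictly positive) components."""
        return int(np.count_nonzero(self.eigenvalues > 0))

    @property
    def fve(self) -> np.ndarray:
        """Per-component fraction of variance explained, λₖ/Σλ."""
        total = self.eigenvalues.sum()
        if total <= 0:
            raise ValueError("all eigenvalues are zero; FVE undefined")
        return self.eigenvalues / total


def _quadrature_weights(time_s: np.ndarray) -> tuple[np.ndarray, bool]:
    """Integration weights for the grid; (weights, is_uniform)."""
    t = np.asarray(time_s, dtype=float)
    if t.size == 1:
        return np.ones(1), True
    dt = np.diff(t)
    uniform = np.allclose(dt, dt[0], rtol=1e-8, atol=0.0)
    if uniform:
        return np.full(t.size, dt[0]), True
    w = np.empty(t.size)
    w[0] = dt[0] / 2
    w[-1] = dt[-1] / 2
    w[1:-1] = (dt[:-1] + dt[1:]) / 2
    return w, False


def fit_fpca(norm: NormalizedTraceMatrix) -> FPCAModel:
    """Fit the dense-grid functional PCA to ΔF/F₀ traces.

    Requires at least 2 cells.  The cross-sectional mean is removed, the
    quadrature-weighted sample covariance is eigendecomposed, and each
    eigenfunction is oriented so its largest-magnitude value is positive
    (reproducible across eigensolvers).
    """
    X = np.asarray(norm.values, dtype=float)
    n, T = X.shape
    if n < 2:
        raise ValueError("fPCA needs at least 2 cells")
    w, uniform = _quadrature_weights(norm.time_s)
    if not uniform:
        warnings.warn("non-uniform time grid; using trapezoid quadrature weights")
    mu = X.mean(axis=0)
    Xc = X - mu
    C = (Xc.T @ Xc) / (n - 1)
    sw = np.sqrt(w)
    A = sw[:, None] * C * sw[None, :]
    lam, U = np.linalg.eigh(A)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    U = U[:, order]
    n_comp = min(n - 1, T)
    lam = lam[:n_comp]
    U = U[:, :n_comp]
    # clamp relative to the leading eigenvalue AND the data's own scale, so
    # duplicate traces (covariance ~ 0 up to round-off) yield no components
    data_scale = float(np.sum(w * (X**2).mean(axis=0)))
    floor = EIGENVALUE_CLAMP * max(lam[0], data_scale, 0.0)
    lam = np.where(lam < floor, 0.0, lam)
    phi = (U / sw[:, None]).T  # rows are eigenfunctions
    # deterministic sign: largest-magnitude value positive
    for k in range(phi.shape[0]):
        j = np.argmax(np.abs(phi[k]))
        if phi[k, j] < 0:
            phi[k] *= -1.0
            U[:, k] *= -1.0
    scores = Xc @ (w[:, None] * phi.T)
    return FPCAModel(
        time_s=np.asarray(norm.time_s, dtype=float),
        mean_fn=mu,
        eigenfunctions=phi,
        eigenvalues=lam,
        scores=scores,
        weights=w,
    )


def fraction_variance(model: FPCAModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-component FVE and its cumulative sum (non-decreasing to 1)."""
    fve = model.fve
    return fve, np.cumsum(fve)


def select_k(model: FPCAModel, threshold: float = 0.95) -> int:
    """Smallest number of components whose cumulative FVE reaches threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    _, cum = fraction_variance(model)
    reached = np.flatnonzero(cum >= threshold - 1e-12)
    if reached.size == 0:  # only from float round-off at threshold = 1
        return model.k_max
    return int(reached[0]) + 1


def reconstruct(model: FPCAModel, K: int) -> np.ndarray:
    """Rank-K denoised reconstruction X̂ᵢ(t) = μ(t) + Σ_{k≤K} ξᵢₖ ϕₖ(t).

    With K = k_max the centered data lie entirely in the retained span and
    the input is recovered (up to numerical precision).
    """
    if not 1 <= K <= model.k_max:
        raise ValueError(f"K must be in 1..{model.k_max}, got {K}")
    return model.mean_fn + model.scores[:, :K] @ model.eigenfunctions[:K]
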