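"""Pluggable velocity-method contract plus a built-in steady-state estimator.

Any velocity method is an object with a ``name``, a ``deterministic`` flag
and a ``fit(spliced, unspliced) -> VelocityResult``; external tools (scVelo,
UniTVelo, VeloVI, scTour, ...) can be wrapped behind this contract without
being dependencies.  The built-in ``SteadyStateVelocity`` implements the
classic first-order model: per gene, the degradation-to-splicing ratio g is
fit by least squares through the origin on cells in the extreme expression
quantiles (assumed near kinetic equilibrium), and the velocity of cell i is
the residual  v_ij = u~_ij - g_j * s~_ij  of the smoothed, library-size
normalized layers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix, VelocityResult

__all__ = [
    "VelocityMethod",
    "SteadyStateVelocity",
    "RandomVelocity",
    "steady_state_velocity",
    "steady_state_r2",
    "project_to_shared_basis",
    "normalize_library",
    "knn_smooth",
    "METHOD_REGISTRY",
    "get_method",
]


def normalize_library(X: CountMatrix, target: float = 1e4) -> np.ndarray:
    """Library-size normalize each cell to a fixed total (dense float).

    The fixed target (counts-per-10k by default) makes the result invariant
    to uniform sequencing-depth changes.  Cells with zero total stay at zero.
    """
    D = X.dense()
    totals = D.sum(axis=1)
    scale = np.where(totals > 0, target / np.maximum(totals, 1e-300), 0.0)
    return D * scale[:, None]


def _pca_embed(norm: np.ndarray, n_pcs: int, random_state: int = 0) -> np.ndarray:
    logged = np.log1p(norm)
    n_pcs = min(n_pcs, max(1, min(logged.shape) - 1))
    return PCA(n_components=n_pcs, random_state=random_state).fit_transform(logged)


def knn_smooth(values: np.ndarray, embedding: np.ndarray, k: int) -> np.ndarray:
    """Average ``values`` over each cell's k nearest neighbors (self included)."""
    n = embedding.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    return values[idx].mean(axis=1)


def _steady_state_fit(
    spliced: CountMatrix,
    unspliced: CountMatrix,
    k_smooth: int,
    extreme_quantile: float,
):
    """Shared core: smooth both layers, fit g per gene through the origin.

    Returns ``(keep_mask, g, s_sm, u_sm)`` over the retained genes.
    """
    if not spliced.cell_ids.equals(unspliced.cell_ids):
        raise ValueError("layers must share cells")
    if not spliced.gene_ids.equals(unspliced.gene_ids):
        raise ValueError("layers must share genes")
    if not 0 < extreme_quantile < 0.5:
        raise ValueError("extreme_quantile must be in (0, 0.5)")
    n = spliced.n_cells
    if n < 2 * k_smooth:
        k_smooth = max(1, n // 2)

    s_norm = normalize_library(spliced)
    u_norm = normalize_library(unspliced)
    emb = _pca_embed(s_norm, n_pcs=30)
    s_sm = knn_smooth(s_norm, emb, k_smooth)
    u_sm = knn_smooth(u_norm, emb, k_smooth)

    keep = s_sm.max(axis=0) > 0
    if not keep.any():
        raise ValueError("no genes with nonzero spliced signal remain")
    s_sm, u_sm = s_sm[:, keep], u_sm[:, keep]

    # Through-origin fit of u on s restricted to the extreme quantiles of s.
    q_lo = np.quantile(s_sm, extreme_quantile, axis=0)
    q_hi = np.quantile(s_sm, 1 - extreme_quantile, axis=0)
    mask = (s_sm <= q_lo) | (s_sm >= q_hi)
    sx = np.where(mask, s_sm, 0.0)
    ux = np.where(mask, u_sm, 0.0)
    denom = (sx * sx).sum(axis=0)
    # Extremes can all be zero for very sparse genes; fall back to all cells.
    fallback = denom <= 0
    if fallback.any():
        denom = np.where(fallback, (s_sm * s_sm).sum(axis=0), denom)
        num = np.where(fallback, (u_sm * s_sm).sum(axis=0), (ux * sx).sum(axis=0))
    else:
        num = (ux * sx).sum(axis=0)
    g = num / denom
    return keep, g, s_sm, u_sm


def steady_state_velocity(
    spliced: CountMatrix,
    unspliced: CountMatrix,
    k_smooth: int = 30,
    extreme_quantile: float = 0.05,
) -> VelocityResult:
    """Steady-state velocity estimate in gene space.

    Parameters
    ----------
    k_smooth
        Neighborhood size for kNN-mean smoothing of both layers, computed on
        principal components of the log1p-normalized spliced counts.
    extreme_quantile
        Fraction in (0, 0.5): the ratio ``g_j`` is fit only on cells whose
        smoothed spliced expression lies in the top or bottom quantile, the
        cells presumed closest to steady state.

    Genes with identically zero spliced signal have no defined ratio and are
    dropped from the result.
    """
    keep, g, s_sm, u_sm = _steady_state_fit(
        spliced, unspliced, k_smooth, extreme_quantile
    )
    V = u_sm - g[None, :] * s_sm
    return VelocityResult(V, spliced.gene_ids[keep], spliced.cell_ids, space_tag="gene")


def steady_state_r2(
    spliced: CountMatrix,
    unspliced: CountMatrix,
    k_smooth: int = 30,
    extreme_quantile: float = 0.05,
) -> pd.Series:
    """Per-gene R^2 of the through-origin steady-state fit on smoothed layers.

    R^2 = 1 - SS_res/SS_tot with SS_tot the centered total sum of squares of
    smoothed u; through-origin fits can give negative values, reported as-is.
    Genes with zero spliced signal or constant smoothed u get NaN.
    """
    keep, g, s_sm, u_sm = _steady_state_fit(
        spliced, unspliced, k_smooth, extreme_quantile
    )
    resid = u_sm - g[None, :] * s_sm
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((u_sm - u_sm.mean(axis=0)) ** 2).sum(axis=0)
    r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), np.nan)
    out = pd.Series(np.full(spliced.n_genes, np.nan), index=spliced.gene_ids)
    out[spliced.gene_ids[keep]] = r2
    return out


def project_to_shared_basis(V: VelocityResult, basis: np.ndarray) -> VelocityResult:
    """Project gene-space velocities onto a shared orthonormal basis.

    Both splits must use the SAME basis — computed from the full, unsplit
    data — so the projected vectors remain comparable across splits.
    """
    basis = np.asarray(basis, dtype=float)
    if basis.shape[0] != V.gene_ids.size:
        raise ValueError("basis rows must align with the velocity gene set")
    gram = basis.T @ basis
    if np.max(np.abs(gram - np.eye(basis.shape[1]))) > 1e-6:
        raise ValueError("basis columns must be orthonormal")
    proj = V.velocities @ basis
    dims = pd.Index([f"dim_{i}" for i in range(basis.shape[1])])
    return VelocityResult(proj, dims, V.cell_ids, space_tag="embedding")


class VelocityMethod:
    """Abstract contract for a pluggable velocity method."""

    name: str = "abstract"
    deterministic: bool = True

    def fit(self, spliced: CountMatrix, unspliced: CountMatrix) -> VelocityResult:
        raise NotImplementedError


class SteadyStateVelocity(VelocityMethod):
    """Built-in deterministic steady-state estimator."""

    name = "steady_state"
    deterministic = True

    def __init__(self, k_smooth: int = 30, extreme_quantile: float = 0.05):
        self.k_smooth = k_smooth
        self.extreme_quantile = extreme_quantile

    def fit(self, spliced: CountMatrix, unspliced: CountMatrix) -> VelocityResult:
        return steady_state_velocity(
            spliced, unspliced, self.k_smooth, self.extreme_quantile
        )


class RandomVelocity(VelocityMethod):
    """Negative control: isotropic Gaussian velocities, fresh per fit.

    Useful as a null method — its replicate coherence should center at zero,
    and the signal-to-random score over seeds should hover near zero.
    """

    name = "random"
    deterministic = False

    def __init__(self, seed: int = 0):
        self._rng = np.random.default_rng(seed)

    def fit(self, spliced: CountMatrix, unspliced: CountMatrix) -> VelocityResult:
        V = self._rng.standard_normal((spliced.n_cells, spliced.n_genes))
        return VelocityResult(V, spliced.gene_ids, spliced.cell_ids, space_tag="gene")


METHOD_REGISTRY: dict[str, type[VelocityMethod]] = {
    SteadyStateVelocity.name: SteadyStateVelocity,
    RandomVelocity.name: RandomVelocity,
}


def get_method(name: str, **kwargs) -> VelocityMethod:
    """Instantiate a registered velocity method by name."""
    try:
        cls = METHOD_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown velocity method {name!r}; registered: {sorted(METHOD_REGISTRY)}"
        ) from None
    return cls(**kwargs)
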