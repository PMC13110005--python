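"""Replicate and local coherence of velocity fields.

Replicate coherence of cell i is the UNCENTERED cosine similarity between
its two velocity vectors, one from each count split:

    theta_rep_i = <v_i(1), v_i(2)> / (||v_i(1)|| * ||v_i(2)||)

Local coherence of cell i is the mean cosine similarity between the cell's
gene-mean-CENTERED velocity vector and those of its neighbors:

    theta_loc_i = mean_{k in ne(i)}  <v_k', v_i'> / (||v_k'|| * ||v_i'||)

where v' subtracts each cell's across-gene mean.  The centering asymmetry is
deliberate and follows the two definitions exactly.  Cells with a zero-norm
vector get the missing sentinel (NaN) and are excluded from summaries.

Velocity methods may retain different gene subsets on the two splits; before
comparing, both results are expanded to the union of their genes with zeros
filled in, so genes selected in only one split penalize the coherence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, CoherenceVector, VelocityResult
from .velocity import _pca_embed, normalize_library

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborGraph",
    "union_align",
    "replicate_coherence",
    "local_coherence",
    "shuffled_pair_null",
    "build_knn_graph",
    "summarize_coherence",
]


@dataclass
class NeighborGraph:
    """Per-cell neighbor index sets (self excluded)."""

    neighbor_sets: list[np.ndarray]
    k: int

    def __post_init__(self) -> None:
        n = len(self.neighbor_sets)
        for i, ne in enumerate(self.neighbor_sets):
            ne = np.asarray(ne, dtype=int)
            if ne.size and (i in ne or ne.min() < 0 or ne.max() >= n):
                raise ValueError(f"invalid neighbor set for cell {i}")
            self.neighbor_sets[i] = ne


def union_align(V1: VelocityResult, V2: VelocityResult) -> tuple[VelocityResult, VelocityResult]:
    """Expand two velocity results to the sorted union of their genes.

    Genes present in one result but absent from the other are zero-filled, so
    they contribute to the norms (and hence penalize coherence) without
    contributing to the dot product.
    """
    if not V1.cell_ids.equals(V2.cell_ids):
        raise ValueError("velocity results must share cells")
    if V1.space_tag != V2.space_tag:
        raise ValueError("velocity results must live in the same space")
    union = V1.gene_ids.union(V2.gene_ids).sort_values()

    def expand(V: VelocityResult) -> VelocityResult:
        M = np.zeros((len(V.cell_ids), len(union)))
        M[:, union.get_indexer(V.gene_ids)] = V.velocities
        return VelocityResult(M, union, V.cell_ids, V.space_tag)

    return expand(V1), expand(V2)


def _row_cosines(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    ok = (na > 0) & (nb > 0)
    out = np.full(A.shape[0], np.nan)
    out[ok] = np.einsum("ij,ij->i", A[ok], B[ok]) / (na[ok] * nb[ok])
    return np.clip(out, -1.0, 1.0)


def replicate_coherence(V1: VelocityResult, V2: VelocityResult) -> CoherenceVector:
    """Per-cell cosine similarity between the two splits' velocity vectors."""
    A1, A2 = union_align(V1, V2)
    vals = _row_cosines(A1.velocities, A2.velocities)
    return CoherenceVector(vals, A1.cell_ids, kind="replicate")


def local_coherence(V: VelocityResult, graph: NeighborGraph) -> CoherenceVector:
    """Per-cell mean cosine similarity to neighbors, after gene-mean centering."""
    if len(graph.neighbor_sets) != len(V.cell_ids):
        raise ValueError("graph size must match number of cells")
    C = V.velocities - V.velocities.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(C, axis=1)
    unit = np.zeros_like(C)
    nz = norms > 0
    unit[nz] = C[nz] / norms[nz, None]
    vals = np.full(len(V.cell_ids), np.nan)
    for i, ne in enumerate(graph.neighbor_sets):
        if ne.size == 0:
            logger.warning("cell %s has no neighbors; local coherence undefined", i)
            continue
        if not nz[i]:
            continue
        ne_ok = ne[nz[ne]]
        if ne_ok.size == 0:
            continue
        vals[i] = float(np.mean(unit[ne_ok] @ unit[i]))
    return CoherenceVector(np.clip(vals, -1, 1), V.cell_ids, kind="local")


def shuffled_pair_null(
    V1: VelocityResult, V2: VelocityResult, n_perm: int, seed: int
) -> np.ndarray:
    """Null distribution of median coherence under shuffled cell pairing.

    Element 0 is the observed (identity-pairing) median; elements 1..n_perm
    are medians after randomly permuting the cell rows of ``V2``, breaking
    the cell correspondence while keeping both velocity fields intact.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    A1, A2 = union_align(V1, V2)
    rng = np.random.default_rng(seed)
    n = len(A1.cell_ids)
    medians = np.empty(n_perm + 1)
    for b in range(n_perm + 1):
        perm = np.arange(n) if b == 0 else rng.permutation(n)
        vals = _row_cosines(A1.velocities, A2.velocities[perm])
        medians[b] = np.nanmedian(vals)
    return medians


def build_knn_graph(X: CountMatrix, k: int = 30, n_pcs: int = 30) -> NeighborGraph:
    """kNN graph on principal components of log1p-normalized counts.

    Computed once from the full (unsplit) spliced matrix so that both splits
    are scored against the same neighborhood structure.
    """
    n = X.n_cells
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    emb = _pca_embed(normalize_library(X), n_pcs)
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    sets = []
    for i in range(n):
        ne = idx[i][idx[i] != i][:k]
        sets.append(ne)
    return NeighborGraph(sets, k=k)


def summarize_coherence(theta: CoherenceVector) -> dict:
    """Median, mean and count over the non-missing coherence values."""
    vals = theta.values[~np.isnan(theta.values)]
    if vals.size == 0:
        raise ValueError("all coherence values are missing; nothing to summarize")
    return {
        "median": float(np.median(vals)),
        "mean": float(np.mean(vals)),
        "n": int(vals.size),
        "kind": theta.kind,
    }
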