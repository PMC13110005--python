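"""Negative binomial count splitting via Dirichlet-multinomial thinning.

Given counts ``X_ij ~ NB(mu_ij, gamma_j)`` and estimated shapes
``gamma_hat_j``, each entry is divided as

    (X1_ij, X2_ij) | X_ij = x  ~  DirichletMultinomial(x, gamma_hat_j/2, gamma_hat_j/2)

which for two categories is a beta-binomial: draw ``p ~ Beta(g/2, g/2)``,
then ``X1 ~ Binomial(x, p)`` and ``X2 = x - X1``.  With the true shapes the
two splits are independent and each is marginally ``NB(mu/2, gamma/2)``; the
Poisson sentinel (``gamma = inf``) degenerates to ``Binomial(x, 1/2)``.

Randomness discipline: each (layer, gene) pair gets its own counter-derived
substream of the master seed, so the result is reproducible regardless of
iteration order and stable under adding genes or layers.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .containers import CountMatrix, SplitPair
from .dispersion import DispersionEstimates, estimate_overdispersion

__all__ = ["draw_dirichlet_multinomial", "split_counts", "split_dataset"]

_LAYER_STREAM = {"spliced": 0, "unspliced": 1}


def _gene_rng(seed: int, layer_index: int, gene_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(layer_index, gene_index))
    return np.random.default_rng(ss)


def draw_dirichlet_multinomial(
    x: int, a1: float, a2: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Split a single count ``x`` into two parts.

    ``x1 ~ BetaBinomial(x, a1, a2)`` and the pair ``(x1, x - x1)`` follows the
    two-category Dirichlet-multinomial.  Passing ``inf`` for both parameters
    selects the Poisson limit ``x1 ~ Binomial(x, 1/2)``.
    """
    if x < 0:
        raise ValueError("count must be non-negative")
    if x == 0:
        return 0, 0
    if np.isinf(a1) or np.isinf(a2):
        if not (np.isinf(a1) and np.isinf(a2)):
            raise ValueError("sentinel parameters must be given for both categories")
        x1 = int(rng.binomial(x, 0.5))
    else:
        if a1 <= 0 or a2 <= 0:
            raise ValueError("Dirichlet parameters must be positive")
        p = rng.beta(a1, a2)
        x1 = int(rng.binomial(x, p))
    return x1, x - x1


def _split_column(x: np.ndarray, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorized beta-binomial split of the nonzero counts of one gene."""
    if np.isinf(gamma):
        return rng.binomial(x, 0.5)
    p = rng.beta(gamma / 2.0, gamma / 2.0, size=x.shape)
    return rng.binomial(x, p)


def split_counts(X: CountMatrix, disp: DispersionEstimates, seed: int) -> SplitPair:
    """Split a count matrix into two independent NB replicates.

    Only nonzero entries are sampled; sparse inputs stay sparse.  The result
    is deterministic given ``(X, disp, seed)`` and satisfies
    ``split1 + split2 == X`` exactly.
    """
    if not X.gene_ids.equals(disp.gene_ids):
        raise ValueError("dispersion estimates are not aligned to the matrix genes")
    layer_index = _LAYER_STREAM.get(X.layer_name, 7)

    M = X.counts
    if sp.issparse(M):
        M = M.tocsc()
        data1 = np.zeros_like(M.data)
        for j in range(X.n_genes):
            lo, hi = M.indptr[j], M.indptr[j + 1]
            if hi == lo:
                continue
            rng = _gene_rng(seed, layer_index, j)
            data1[lo:hi] = _split_column(M.data[lo:hi], disp.gamma_hat[j], rng)
        S1 = sp.csc_matrix((data1, M.indices.copy(), M.indptr.copy()), shape=M.shape)
        S2 = sp.csc_matrix(
            (M.data - data1, M.indices.copy(), M.indptr.copy()), shape=M.shape
        )
        S1.eliminate_zeros()
        S2.eliminate_zeros()
        S1, S2 = S1.tocsr(), S2.tocsr()
    else:
        S1 = np.zeros_like(M)
        for j in range(X.n_genes):
            col = M[:, j]
            nz = np.flatnonzero(col)
            if nz.size == 0:
                continue
            rng = _gene_rng(seed, layer_index, j)
            S1[nz, j] = _split_column(col[nz], disp.gamma_hat[j], rng)
        S2 = M - S1

    mk = lambda S: CountMatrix(S, X.gene_ids, X.cell_ids, X.layer_name)
    return SplitPair(mk(S1), mk(S2), seed=seed, gamma_used=disp.gamma_hat.copy())


def split_dataset(
    spliced: CountMatrix,
    unspliced: CountMatrix,
    seed: int,
    bounds: tuple[float, float] | None = None,
) -> tuple[SplitPair, SplitPair]:
    """Estimate dispersions and split both layers of a velocity dataset.

    The spliced and unspliced matrices are fitted independently; per-layer
    randomness derives deterministically from the master ``seed``.
    """
    if not spliced.cell_ids.equals(unspliced.cell_ids):
        raise ValueError("spliced and unspliced layers must share cells")
    kwargs = {} if bounds is None else {"bounds": bounds}
    disp_s = estimate_overdispersion(spliced, **kwargs)
    disp_u = estimate_overdispersion(unspliced, **kwargs)
    return (
        split_counts(spliced, disp_s, seed),
        split_counts(unspliced, disp_u, seed),
    )
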