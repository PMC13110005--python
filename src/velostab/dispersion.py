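"""Per-gene negative binomial overdispersion estimation.

The count model is ``X_ij ~ NB(mu_j, gamma_j)`` with mean ``mu_j`` and
variance ``mu_j + mu_j**2 / gamma_j``; ``gamma_j -> inf`` recovers the
Poisson.  The estimator is an intercept-only Gamma-Poisson fit: the mean is
profiled out as the per-gene sample mean, and the shape ``gamma_j`` is
maximized by one-dimensional likelihood optimization in ``log gamma``.

Genes whose fit indicates no overdispersion (sample variance <= sample mean,
or the optimizer escaping to the upper bound) receive the Poisson sentinel
``inf`` and are later split with Binomial(x, 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .containers import POISSON_SENTINEL, CountMatrix

__all__ = ["DispersionEstimates", "estimate_overdispersion", "nb_loglik"]

DEFAULT_BOUNDS = (1e-3, 1e6)


@dataclass
class DispersionEstimates:
    """Per-gene NB shape estimates aligned to a source matrix."""

    gamma_hat: np.ndarray
    mu_hat: np.ndarray
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float)
        self.mu_hat = np.asarray(self.mu_hat, dtype=float)
        self.gene_ids = pd.Index(self.gene_ids)
        if not (len(self.gamma_hat) == len(self.mu_hat) == len(self.gene_ids)):
            raise ValueError("estimate arrays and gene_ids must be aligned")
        finite = self.gamma_hat[np.isfinite(self.gamma_hat)]
        if finite.size and finite.min() <= 0:
            raise ValueError("gamma_hat must be positive or inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "mu_hat": self.mu_hat, "gamma_hat": self.gamma_hat}
        )


def nb_loglik(gamma: float, values: np.ndarray, multiplicities: np.ndarray, mu: float) -> float:
    """NB log-likelihood at shape ``gamma`` for grouped counts.

    ``values``/``multiplicities`` give the distinct observed counts and how
    often each occurs — sparse columns collapse to a handful of groups plus a
    single zero-count term, which keeps the per-gene optimization cheap.
    """
    if mu <= 0:
        return 0.0
    x = values
    w = multiplicities
    ll = (
        gammaln(x + gamma)
        - gammaln(gamma)
        - gammaln(x + 1.0)
        + gamma * np.log(gamma / (gamma + mu))
        + x * np.log(mu / (gamma + mu))
    )
    return float(np.dot(w, ll))


def _fit_gene(values: np.ndarray, multiplicities: np.ndarray, n: int, bounds) -> tuple[float, float]:
    """Return (mu_hat, gamma_hat) for one gene from grouped counts."""
    total = float(np.dot(values, multiplicities))
    mu = total / n
    if mu == 0.0:
        return 0.0, POISSON_SENTINEL
    mean_sq = float(np.dot(values.astype(float) ** 2, multiplicities)) / n
    var = (mean_sq - mu**2) * n / max(n - 1, 1)
    # Method-of-moments screen: no detectable overdispersion -> Poisson.
    if var <= mu:
        return mu, POISSON_SENTINEL
    lo, hi = bounds
    res = minimize_scalar(
        lambda lg: -nb_loglik(np.exp(lg), values, multiplicities, mu),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    gamma = float(np.exp(res.x))
    gamma = min(max(gamma, lo), hi)
    # Hitting the upper bound means the likelihood keeps improving toward the
    # Poisson limit; report the sentinel instead of a meaningless huge value.
    if gamma >= hi * (1 - 1e-6):
        return mu, POISSON_SENTINEL
    return mu, gamma


def estimate_overdispersion(
    X: CountMatrix, bounds: tuple[float, float] = DEFAULT_BOUNDS
) -> DispersionEstimates:
    """Estimate per-gene NB overdispersion from an integer count matrix.

    Parameters
    ----------
    X
        Validated count matrix with at least 2 cells.
    bounds
        Positive search interval for ``gamma``; estimates are clamped to it
        and the upper bound maps to the Poisson sentinel.

    Returns
    -------
    DispersionEstimates
        ``gamma_hat`` (``inf`` = Poisson), ``mu_hat`` (sample mean), aligned
        to ``X.gene_ids``.
    """
    if X.n_cells < 2:
        raise ValueError("overdispersion estimation needs at least 2 cells")
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must be a positive increasing interval")

    n = X.n_cells
    gamma_hat = np.empty(X.n_genes)
    mu_hat = np.empty(X.n_genes)
    M = X.counts
    sparse = sp.issparse(M)
    if sparse:
        M = M.tocsc()
    for j in range(X.n_genes):
        if sparse:
            col = M.data[M.indptr[j] : M.indptr[j + 1]]
        else:
            col = M[:, j]
            col = col[col != 0]
        values, mult = np.unique(col, return_counts=True)
        n_zero = n - int(mult.sum())
        if n_zero:
            values = np.concatenate(([0], values)).astype(float)
            mult = np.concatenate(([n_zero], mult)).astype(float)
        else:
            values = values.astype(float)
            mult = mult.astype(float)
        mu_hat[j], gamma_hat[j] = _fit_gene(values, mult, n, bounds)
    return DispersionEstimates(gamma_hat, mu_hat, X.gene_ids)
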