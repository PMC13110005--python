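"""Synthetic spliced/unspliced counts along a one-dimensional kinetic trajectory.

Each kinetic gene follows the standard two-species splicing ODE

    du/dt = alpha - beta * u        (transcription, splicing)
    ds/dt = beta * u - gamma_ss * s (splicing, degradation)

integrated in closed form from u(0) = s(0) = 0: an induction phase
(alpha > 0) up to a switch time, then repression (alpha = 0) continuing from
the switch-point state.  Cells sit at latent times drawn uniformly on [0, 1]
and the ground-truth velocity is ds/dt = beta*u - gamma_ss*s evaluated at
each cell's time.  Observed counts are NB(mu, gamma_nb) around the kinetic
means scaled by a per-cell library factor, with gene-specific overdispersion
known by construction.

Noise genes reuse kinetic-gene mean profiles with cell order permuted
independently per gene: their marginal sparsity and u-vs-s relation match
kinetic genes (the confounders control-gene matching adjusts for), but they
carry no coordinated trajectory signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .containers import CountMatrix

__all__ = ["TrajectoryParams", "SyntheticDataset", "simulate_kinetics", "sample_counts", "make_dataset"]


@dataclass
class TrajectoryParams:
    """Parameters of the synthetic trajectory; defaults are desk-scale.

    Rates are per unit latent time.  ``gamma_nb`` holds NB shapes for all
    (kinetic + noise) genes; ``inf`` entries sample Poisson counts.
    """

    n_cells: int = 500
    kinetic_genes: int = 100
    noise_genes: int = 200
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    gamma_ss: np.ndarray | None = None
    latent_times: np.ndarray | None = None
    switch_time: float = 0.6
    library_scale: np.ndarray | None = None
    gamma_nb: np.ndarray | None = None
    mean_scale: float = 20.0
    master_seed: int = 0

    def realized(self) -> "TrajectoryParams":
        """Fill unset fields from seeded defaults and validate."""
        rng = np.random.default_rng(
            np.random.SeedSequence(self.master_seed, spawn_key=(0,))
        )
        p = TrajectoryParams(**{**self.__dict__})
        kg, ng, n = p.kinetic_genes, p.noise_genes, p.n_cells
        if p.alpha is None:
            p.alpha = np.exp(rng.uniform(np.log(1.0), np.log(4.0), kg))
        if p.beta is None:
            p.beta = np.exp(rng.uniform(np.log(0.8), np.log(3.0), kg))
        if p.gamma_ss is None:
            p.gamma_ss = np.exp(rng.uniform(np.log(0.3), np.log(1.5), kg))
        if p.latent_times is None:
            p.latent_times = rng.uniform(0.0, 1.0, n)
        if p.library_scale is None:
            p.library_scale = np.exp(rng.normal(0.0, 0.3, n))
        if p.gamma_nb is None:
            p.gamma_nb = np.exp(rng.uniform(np.log(1.0), np.log(20.0), kg + ng))
        for name in ("alpha", "beta", "gamma_ss", "library_scale"):
            arr = np.asarray(getattr(p, name), dtype=float)
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be positive")
            setattr(p, name, arr)
        if not 0 < p.switch_time < 1:
            raise ValueError("switch_time must lie in (0, 1)")
        return p


@dataclass
class SyntheticDataset:
    spliced: CountMatrix
    unspliced: CountMatrix
    true_velocity: np.ndarray
    cell_stage_labels: pd.Series
    params: TrajectoryParams
    u_mean: np.ndarray = field(repr=False, default=None)
    s_mean: np.ndarray = field(repr=False, default=None)

    @property
    def kinetic_gene_ids(self) -> pd.Index:
        return self.spliced.gene_ids[: self.params.kinetic_genes]

    @property
    def noise_gene_ids(self) -> pd.Index:
        return self.spliced.gene_ids[self.params.kinetic_genes :]


def _induction(t, alpha, beta, gamma):
    """u(t), s(t) for induction from zero initial conditions."""
    u = (alpha / beta) * (-np.expm1(-beta * t))
    close = np.abs(gamma - beta) < 1e-8
    safe = np.where(close, 1.0, gamma - beta)
    s_generic = (alpha / gamma) * (-np.expm1(-gamma * t)) + (alpha / safe) * (
        np.exp(-gamma * t) - np.exp(-beta * t)
    )
    # analytic limit of the cross term as beta -> gamma
    s_limit = (alpha / gamma) * (-np.expm1(-gamma * t)) - alpha * t * np.exp(-gamma * t)
    return u, np.where(close, s_limit, s_generic)


def _repression(tau, u0, s0, beta, gamma):
    """u, s a time ``tau`` after switching transcription off at state (u0, s0)."""
    u = u0 * np.exp(-beta * tau)
    close = np.abs(gamma - beta) < 1e-8
    safe = np.where(close, 1.0, gamma - beta)
    s_generic = s0 * np.exp(-gamma * tau) + (beta * u0 / safe) * (
        np.exp(-beta * tau) - np.exp(-gamma * tau)
    )
    s_limit = s0 * np.exp(-gamma * tau) + beta * u0 * tau * np.exp(-gamma * tau)
    return u, np.where(close, s_limit, s_generic)


def simulate_kinetics(params: TrajectoryParams):
    """Closed-form kinetic means and ground-truth velocity for kinetic genes.

    Returns ``(u_mean, s_mean, true_velocity)`` of shape
    ``(n_cells, kinetic_genes)``; velocity is ``beta*u - gamma_ss*s``.
    """
    p = params.realized()
    t = np.asarray(p.latent_times)[:, None]
    a, b, g = p.alpha[None, :], p.beta[None, :], p.gamma_ss[None, :]
    t0 = p.switch_time

    u_ind, s_ind = _induction(np.minimum(t, t0), a, b, g)
    u0, s0 = _induction(np.full_like(t, t0), a, b, g)
    u_rep, s_rep = _repression(np.maximum(t - t0, 0.0), u0, s0, b, g)
    on = t < t0
    u = np.where(on, u_ind, u_rep)
    s = np.where(on, s_ind, s_rep)
    v = b * u - g * s
    return u, s, v


def sample_counts(u_mean: np.ndarray, s_mean: np.ndarray, params: TrajectoryParams) -> SyntheticDataset:
    """Draw NB counts around the kinetic means and append permuted noise genes."""
    p = params.realized()
    if not (np.all(np.isfinite(u_mean)) and np.all(np.isfinite(s_mean))):
        raise ValueError("kinetic means must be finite")
    if np.min(u_mean) < 0 or np.min(s_mean) < 0:
        raise ValueError("kinetic means must be non-negative")
    n, kg, ng = p.n_cells, p.kinetic_genes, p.noise_genes
    rng = np.random.default_rng(np.random.SeedSequence(p.master_seed, spawn_key=(1,)))

    # Noise genes: kinetic mean profiles with cells permuted per gene.
    src = rng.integers(0, kg, size=ng)
    u_noise = np.empty((n, ng))
    s_noise = np.empty((n, ng))
    for j in range(ng):
        perm = rng.permutation(n)
        u_noise[:, j] = u_mean[perm, src[j]]
        s_noise[:, j] = s_mean[perm, src[j]]

    u_all = np.concatenate([u_mean, u_noise], axis=1) * p.mean_scale
    s_all = np.concatenate([s_mean, s_noise], axis=1) * p.mean_scale
    lib = np.asarray(p.library_scale)[:, None]
    mu_u = u_all * lib
    mu_s = s_all * lib

    def draw(mu: np.ndarray, stream: int) -> np.ndarray:
        r = np.random.default_rng(
            np.random.SeedSequence(p.master_seed, spawn_key=(2, stream))
        )
        out = np.empty(mu.shape, dtype=np.int64)
        for j in range(mu.shape[1]):
            gam = p.gamma_nb[j]
            m = mu[:, j]
            if np.isinf(gam):
                out[:, j] = r.poisson(m)
            else:
                prob = gam / (gam + np.maximum(m, 0))
                out[:, j] = r.negative_binomial(gam, prob)
        return out

    gene_ids = pd.Index(
        [f"kin_{j:04d}" for j in range(kg)] + [f"noise_{j:04d}" for j in range(ng)]
    )
    cell_ids = pd.Index([f"cell_{i:05d}" for i in range(n)])
    spliced = CountMatrix(draw(mu_s, 0), gene_ids, cell_ids, "spliced")
    unspliced = CountMatrix(draw(mu_u, 1), gene_ids, cell_ids, "unspliced")

    # latent-time terciles by rank (robust to ties)
    order = scipy.stats.rankdata(p.latent_times, method="ordinal") - 1
    tercile = (order * 3 // n).astype(int)
    stages = pd.Series(
        np.array(["early", "mid", "late"])[tercile], index=cell_ids, name="stage"
    )
    _, _, v = simulate_kinetics(p)
    return SyntheticDataset(
        spliced=spliced,
        unspliced=unspliced,
        true_velocity=v * p.mean_scale,
        cell_stage_labels=stages,
        params=p,
        u_mean=u_all,
        s_mean=s_all,
    )


def make_dataset(
    n_cells: int = 500,
    kinetic_genes: int = 100,
    noise_genes: int = 200,
    master_seed: int = 0,
    **kwargs,
) -> SyntheticDataset:
    """One-call generation of the default synthetic dataset."""
    params = TrajectoryParams(
        n_cells=n_cells,
        kinetic_genes=kinetic_genes,
        noise_genes=noise_genes,
        master_seed=master_seed,
        **kwargs,
    ).realized()
    u, s, _ = simulate_kinetics(params)
    return sample_counts(u, s, params)
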