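"""Matched non-informative control gene selection.

The signal-to-random score contrasts replicate coherence on a set of
biologically informative genes against a control set that looks like it in
every respect the velocity machinery is sensitive to — spliced sparsity,
unspliced sparsity and the steady-state R^2 — but carries no biology.  The
construction mirrors chromVAR-style background matching: each of the three
features is cut into four equal-count (quartile) bins, giving 4^3 = 64
possible groups; each informative gene draws controls from its own bin, or
failing that from the nearest non-empty bin by Euclidean distance on the
integer bin coordinates.  The control set is by default twice the size of
the informative set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .containers import CountMatrix
from .velocity import steady_state_r2

__all__ = [
    "GeneFeatures",
    "MatchResult",
    "compute_gene_features",
    "assign_bins",
    "match_noninformative",
    "N_BINS_PER_FEATURE",
]

N_BINS_PER_FEATURE = 4


@dataclass
class GeneFeatures:
    """Per-gene matching features and (optionally) their bin coordinates."""

    gene_ids: pd.Index
    sparsity_spliced: np.ndarray
    sparsity_unspliced: np.ndarray
    r2: np.ndarray
    bin_coords: np.ndarray | None = None  # (n_genes, 3) ints in 0..3

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        for name in ("sparsity_spliced", "sparsity_unspliced", "r2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.gene_ids),):
                raise ValueError(f"{name} must align with gene_ids")
            setattr(self, name, arr)
        for name in ("sparsity_spliced", "sparsity_unspliced"):
            arr = getattr(self, name)
            if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class MatchResult:
    informative: list[str]
    matched: list[str]
    match_map: dict[str, list[str]]
    seed: int
    bin_distances: dict[str, list[float]] = field(default_factory=dict)


def _zero_fraction(X: CountMatrix) -> np.ndarray:
    import scipy.sparse as sp

    M = X.counts
    if sp.issparse(M):
        nnz = M.getnnz(axis=0)
    else:
        nnz = np.count_nonzero(M, axis=0)
    return 1.0 - nnz / X.n_cells


def compute_gene_features(
    spliced: CountMatrix,
    unspliced: CountMatrix,
    r2: pd.Series | None = None,
) -> GeneFeatures:
    """Zero-fractions of both layers plus the steady-state R^2 per gene.

    ``r2`` may be supplied externally (e.g. from an upstream velocity tool);
    otherwise it is computed from the built-in steady-state fit.
    """
    if not spliced.cell_ids.equals(unspliced.cell_ids):
        raise ValueError("layers must share cells")
    if not spliced.gene_ids.equals(unspliced.gene_ids):
        raise ValueError("layers must share genes")
    if r2 is None:
        r2 = steady_state_r2(spliced, unspliced)
    else:
        missing = spliced.gene_ids.difference(pd.Index(r2.index))
        if len(missing):
            raise ValueError(f"r2 missing for genes: {list(missing[:5])}")
        r2 = r2.reindex(spliced.gene_ids)
    return GeneFeatures(
        gene_ids=spliced.gene_ids,
        sparsity_spliced=_zero_fraction(spliced),
        sparsity_unspliced=_zero_fraction(unspliced),
        r2=np.asarray(r2, dtype=float),
    )


def _quartile_bins(values: np.ndarray) -> np.ndarray:
    """Equal-count bins 0..3; ties (and NaNs, ranked last) broken by rank."""
    n = len(values)
    v = np.where(np.isnan(values), np.inf, values)
    if len(np.unique(v)) < N_BINS_PER_FEATURE:
        warnings.warn(
            "fewer than 4 distinct feature values; bins are degenerate "
            "(ties broken by rank)",
            stacklevel=3,
        )
    ranks = scipy.stats.rankdata(v, method="ordinal")  # 1..n, ties by position
    return ((ranks - 1) * N_BINS_PER_FEATURE // n).astype(int)


def assign_bins(features: GeneFeatures) -> GeneFeatures:
    """Discretize each feature into quartile bins over all genes."""
    coords = np.column_stack(
        [
            _quartile_bins(features.sparsity_spliced),
            _quartile_bins(features.sparsity_unspliced),
            _quartile_bins(features.r2),
        ]
    )
    return GeneFeatures(
        gene_ids=features.gene_ids,
        sparsity_spliced=features.sparsity_spliced,
        sparsity_unspliced=features.sparsity_unspliced,
        r2=features.r2,
        bin_coords=coords,
    )


def match_noninformative(
    features: GeneFeatures,
    informative: list[str],
    ratio: int = 2,
    seed: int = 0,
) -> MatchResult:
    """Draw a matched control set ``ratio`` times the informative size.

    Informative genes are visited ``ratio`` times in a seeded-shuffled order;
    each visit samples one eligible gene (not informative, not yet matched)
    uniformly from the informative gene's own bin, falling back to the
    nearest non-empty bin by Euclidean distance on bin coordinates (distance
    ties broken uniformly at random).

    Raises a shortage error if fewer than ``ratio * len(informative)``
    eligible genes exist overall.
    """
    if features.bin_coords is None:
        features = assign_bins(features)
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    info_idx = features.gene_ids.get_indexer(pd.Index(informative))
    if (info_idx < 0).any():
        bad = [g for g, i in zip(informative, info_idx) if i < 0][:5]
        raise KeyError(f"informative genes absent from the universe: {bad}")
    info_set = set(informative)

    n_needed = ratio * len(informative)
    eligible = [g for g in features.gene_ids if g not in info_set]
    if len(eligible) < n_needed:
        raise ValueError(
            f"cannot draw {n_needed} controls: only {len(eligible)} eligible "
            f"genes (deficit {n_needed - len(eligible)})"
        )

    rng = np.random.default_rng(seed)
    coords = features.bin_coords
    # bin -> mutable list of eligible gene positions
    by_bin: dict[tuple[int, int, int], list[int]] = {}
    pos_of = {g: i for i, g in enumerate(features.gene_ids)}
    for g in eligible:
        i = pos_of[g]
        by_bin.setdefault(tuple(coords[i]), []).append(i)

    match_map: dict[str, list[str]] = {g: [] for g in informative}
    bin_distances: dict[str, list[float]] = {g: [] for g in informative}
    matched: list[str] = []

    order = list(informative)
    for _round in range(ratio):
        rng.shuffle(order)
        for g in order:
            home = tuple(coords[pos_of[g]])
            candidates = by_bin.get(home)
            if candidates:
                chosen_bin, dist = home, 0.0
            else:
                nonempty = [b for b, lst in by_bin.items() if lst]
                dists = np.array(
                    [np.linalg.norm(np.subtract(b, home)) for b in nonempty]
                )
                dmin = dists.min()
                tied = [b for b, d in zip(nonempty, dists) if d == dmin]
                chosen_bin = tied[int(rng.integers(len(tied)))]
                dist = float(dmin)
            lst = by_bin[chosen_bin]
            pick = lst.pop(int(rng.integers(len(lst))))
            gene = features.gene_ids[pick]
            matched.append(gene)
            match_map[g].append(gene)
            bin_distances[g].append(dist)

    return MatchResult(
        informative=list(informative),
        matched=matched,
        match_map=match_map,
        seed=seed,
        bin_distances=bin_distances,
    )
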