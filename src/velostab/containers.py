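"""Core data containers shared across the package.

The central object is :class:`CountMatrix`, a thin validated wrapper around a
cells x genes non-negative integer matrix (dense or scipy sparse) with stable
cell and gene identifiers.  Everything downstream — dispersion estimation,
count splitting, velocity estimation, coherence — consumes and produces these
containers rather than bare arrays, so identifier alignment can always be
checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "SplitPair",
    "VelocityResult",
    "CoherenceVector",
    "MISSING",
]

#: Sentinel for undefined per-cell coherence values (zero-norm vectors etc.).
MISSING = np.nan

#: Sentinel for "no overdispersion" (Poisson limit) in dispersion estimates.
POISSON_SENTINEL = np.inf


def _as_index(ids: Sequence[str], what: str) -> pd.Index:
    idx = pd.Index(np.asarray(ids, dtype=object))
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dup}")
    return idx


@dataclass
class CountMatrix:
    """Cells x genes non-negative integer count matrix.

    Parameters
    ----------
    counts
        ``(n_cells, n_genes)`` array or scipy sparse matrix.  Entries must be
        non-negative and integer-valued (floats within 1e-6 of an integer are
        accepted and rounded; anything else is rejected, which guards against
        accidentally feeding normalized data into the NB machinery).
    gene_ids, cell_ids
        Ordered, duplicate-free identifiers matching the matrix dimensions.
    layer_name
        Free-form label, conventionally ``"spliced"`` or ``"unspliced"``.
    """

    counts: sp.spmatrix | np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    layer_name: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = _as_index(self.gene_ids, "gene_ids")
        self.cell_ids = _as_index(self.cell_ids, "cell_ids")
        X = self.counts
        if sp.issparse(X):
            X = X.tocsr()
        else:
            X = np.asarray(X)
            if X.ndim != 2:
                raise ValueError("counts must be 2-dimensional")
        if X.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {X.shape} does not match "
                f"({len(self.cell_ids)} cells, {len(self.gene_ids)} genes)"
            )
        data = X.data if sp.issparse(X) else X
        if data.size:
            if np.min(data) < 0:
                raise ValueError("counts must be non-negative")
            if not np.issubdtype(np.asarray(data).dtype, np.integer):
                rounded = np.rint(data)
                if np.max(np.abs(data - rounded)) > 1e-6:
                    raise ValueError(
                        "counts must be integer-valued (is this matrix "
                        "already normalized?)"
                    )
                if sp.issparse(X):
                    X = X.copy()
                    X.data = rounded.astype(np.int64)
                else:
                    X = rounded.astype(np.int64)
        self.counts = X

    # -- basic queries -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_cells, self.n_genes)

    def dense(self) -> np.ndarray:
        """Counts as a dense float ndarray (copy)."""
        X = self.counts
        return np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)

    def column(self, j: int) -> np.ndarray:
        """Dense 1-D counts of gene column ``j``."""
        X = self.counts
        if sp.issparse(X):
            return np.asarray(X[:, j].todense()).ravel()
        return np.asarray(X[:, j]).ravel()

    # -- subsetting ----------------------------------------------------

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        idx = self.gene_ids.get_indexer(pd.Index(gene_ids))
        if (idx < 0).any():
            missing = list(pd.Index(gene_ids)[idx < 0][:5])
            raise KeyError(f"genes not present: {missing}")
        return CountMatrix(
            self.counts[:, idx], pd.Index(gene_ids), self.cell_ids, self.layer_name
        )

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        mask = np.asarray(mask_or_ids)
        if mask.dtype == bool:
            keep = np.flatnonzero(mask)
        else:
            keep = self.cell_ids.get_indexer(pd.Index(mask_or_ids))
            if (keep < 0).any():
                raise KeyError("unknown cell ids in subset request")
        return CountMatrix(
            self.counts[keep, :], self.gene_ids, self.cell_ids[keep], self.layer_name
        )


@dataclass
class SplitPair:
    """Two count-splitting replicates that sum entry-wise to the source."""

    split1: CountMatrix
    split2: CountMatrix
    seed: int
    gamma_used: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        a, b = self.split1, self.split2
        if not a.gene_ids.equals(b.gene_ids) or not a.cell_ids.equals(b.cell_ids):
            raise ValueError("split halves must share identifiers")


@dataclass
class VelocityResult:
    """Per-cell velocity vectors over a named gene (or embedding-axis) subset."""

    velocities: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    space_tag: str = "gene"

    def __post_init__(self) -> None:
        self.gene_ids = _as_index(self.gene_ids, "gene_ids")
        self.cell_ids = _as_index(self.cell_ids, "cell_ids")
        V = np.asarray(self.velocities, dtype=float)
        if V.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("velocity matrix shape does not match identifiers")
        if not np.all(np.isfinite(V)):
            raise ValueError("velocities must be finite")
        self.velocities = V


@dataclass
class CoherenceVector:
    """Per-cell coherence values in [-1, 1]; NaN marks undefined cells."""

    values: np.ndarray
    cell_ids: pd.Index
    kind: str = "replicate"

    def __post_init__(self) -> None:
        self.cell_ids = _as_index(self.cell_ids, "cell_ids")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.cell_ids),):
            raise ValueError("values length must match cell_ids")
        ok = v[~np.isnan(v)]
        if ok.size and (ok.min() < -1 - 1e-9 or ok.max() > 1 + 1e-9):
            raise ValueError("coherence values must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0, out=v, where=~np.isnan(v))

    @property
    def n_valid(self) -> int:
        return int(np.sum(~np.isnan(self.values)))
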