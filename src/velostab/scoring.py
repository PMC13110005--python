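"""Signal-to-random coherence score and robustness diagnostics.

The score compares mean replicate coherence on an informative gene set with
that on matched non-informative controls over B independently seeded runs.
Each run performs (1) a fresh count split, (2) a fresh control-gene draw and
(3) two velocity fits, one per split and gene set.  With per-seed means
theta_info_b and theta_ninfo_b, the score is the Welch-style statistic

    (mean(info) - mean(ninfo)) / sqrt(var(info)/B + var(ninfo)/B)

with sample variances (denominator B-1).  It is a model-selection heuristic,
not a p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .coherence import replicate_coherence, summarize_coherence
from .containers import CountMatrix, CoherenceVector
from .countsplit import split_counts
from .dispersion import estimate_overdispersion
from .genematch import assign_bins, compute_gene_features, match_noninformative
from .velocity import VelocityMethod

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreResult",
    "SeedRobustnessResult",
    "signal_to_random_score",
    "run_score_experiment",
    "seed_robustness",
    "missing_celltype_experiment",
]


@dataclass
class ScoreResult:
    info_means: np.ndarray
    ninfo_means: np.ndarray
    B: int
    score: float
    per_seed_details: list[dict] = field(default_factory=list)


@dataclass
class SeedRobustnessResult:
    pairwise_r: np.ndarray
    p_values: np.ndarray
    alpha: float
    n_significant_positive: int
    pairs: list[tuple[int, int]] = field(default_factory=list)


def signal_to_random_score(info_means, ninfo_means) -> float:
    """Welch-style standardized difference of per-seed mean coherences."""
    a = np.asarray(info_means, dtype=float)
    b = np.asarray(ninfo_means, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length arrays with B >= 2 entries")
    B = a.size
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    denom = np.sqrt(va / B + vb / B)
    if denom == 0:
        raise ZeroDivisionError(
            "both per-seed variances are zero; the score is undefined"
        )
    return float((a.mean() - b.mean()) / denom)


def _component_seed(master_seed: int, b: int, component: str) -> int:
    """Stable sub-seed for (master seed, run index, component name)."""
    key = tuple(component.encode())
    ss = np.random.SeedSequence(master_seed, spawn_key=(b, *key))
    return int(ss.generate_state(1)[0] % (2**31))


def _mean_coherence(theta: CoherenceVector) -> float:
    vals = theta.values[~np.isnan(theta.values)]
    if vals.size == 0:
        raise ValueError("coherence undefined for every cell")
    return float(vals.mean())


def run_score_experiment(
    spliced: CountMatrix,
    unspliced: CountMatrix,
    method: VelocityMethod,
    informative: list[str],
    B: int = 5,
    master_seed: int = 0,
    ratio: int = 2,
) -> ScoreResult:
    """Compute the signal-to-random coherence score over B seeded runs.

    Dispersion estimates and gene features are deterministic in the data and
    are computed once; splitting, control matching and (for stochastic
    methods) the velocity fits are re-randomized per seed.  Seeds that fail
    inside any component are excluded with a warning and the effective B is
    reported.
    """
    disp_s = estimate_overdispersion(spliced)
    disp_u = estimate_overdispersion(unspliced)
    features = assign_bins(compute_gene_features(spliced, unspliced))

    info_means, ninfo_means, details = [], [], []
    for b in range(B):
        try:
            seed_split = _component_seed(master_seed, b, "split")
            seed_match = _component_seed(master_seed, b, "match")
            pair_s = split_counts(spliced, disp_s, seed_split)
            pair_u = split_counts(unspliced, disp_u, seed_split)
            match = match_noninformative(features, informative, ratio, seed_match)

            means = {}
            for set_name, genes in (("info", informative), ("ninfo", match.matched)):
                V1 = method.fit(
                    pair_s.split1.subset_genes(genes),
                    pair_u.split1.subset_genes(genes),
                )
                V2 = method.fit(
                    pair_s.split2.subset_genes(genes),
                    pair_u.split2.subset_genes(genes),
                )
                means[set_name] = _mean_coherence(replicate_coherence(V1, V2))
        except Exception as err:  # noqa: BLE001 — any component failure skips the seed
            warnings.warn(f"seed {b} failed and is excluded: {err}", stacklevel=2)
            continue
        info_means.append(means["info"])
        ninfo_means.append(means["ninfo"])
        details.append(
            {
                "b": b,
                "seed_split": seed_split,
                "seed_match": seed_match,
                "n_informative": len(informative),
                "n_matched": len(match.matched),
            }
        )

    info_arr = np.asarray(info_means)
    ninfo_arr = np.asarray(ninfo_means)
    score = signal_to_random_score(info_arr, ninfo_arr)
    return ScoreResult(
        info_means=info_arr,
        ninfo_means=ninfo_arr,
        B=len(info_means),
        score=score,
        per_seed_details=details,
    )


def seed_robustness(
    theta_by_seed: list[CoherenceVector],
    alpha: float = 0.05,
    uncentered: bool = False,
) -> SeedRobustnessResult:
    """Pairwise positivity tests of coherence correlations across seeds.

    All B(B-1)/2 pairs of per-cell coherence vectors are correlated over the
    cells non-missing in both; one-sided Pearson tests (H1: r > 0) are
    Bonferroni-corrected by the number of evaluated pairs.  ``uncentered``
    replaces Pearson's r by sum(x*y)/sqrt(sum(x^2)*sum(y^2)) (no mean
    subtraction), with the p-value from the same test machinery applied to
    the raw products.
    """
    B = len(theta_by_seed)
    if B < 2:
        raise ValueError("need at least 2 seeds")
    cell_ids = theta_by_seed[0].cell_ids
    for t in theta_by_seed[1:]:
        if not t.cell_ids.equals(cell_ids):
            raise ValueError("coherence vectors must be cell-aligned")

    pairs = [(i, j) for i in range(B) for j in range(i + 1, B)]
    rs, ps = [], []
    for i, j in pairs:
        x = theta_by_seed[i].values
        y = theta_by_seed[j].values
        ok = ~np.isnan(x) & ~np.isnan(y)
        x, y = x[ok], y[ok]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            logger.warning("pair (%d, %d) has zero variance; excluded", i, j)
            rs.append(np.nan)
            ps.append(np.nan)
            continue
        if uncentered:
            r = float(np.dot(x, y) / np.sqrt(np.dot(x, x) * np.dot(y, y)))
            # one-sided t approximation on the uncentered correlation
            df = x.size - 2
            with np.errstate(divide="ignore"):
                t = r * np.sqrt(df / max(1e-300, 1 - r * r))
            p = float(scipy.stats.t.sf(t, df))
        else:
            res = scipy.stats.pearsonr(x, y, alternative="greater")
            r, p = float(res.statistic), float(res.pvalue)
        rs.append(r)
        ps.append(p)

    rs = np.asarray(rs)
    ps = np.asarray(ps)
    evaluated = ~np.isnan(ps)
    n_pairs = int(evaluated.sum())
    threshold = alpha / max(n_pairs, 1)
    n_sig = int(np.sum((ps[evaluated] < threshold) & (rs[evaluated] > 0)))
    return SeedRobustnessResult(
        pairwise_r=rs,
        p_values=ps,
        alpha=alpha,
        n_significant_positive=n_sig,
        pairs=pairs,
    )


def missing_celltype_experiment(
    spliced: CountMatrix,
    unspliced: CountMatrix,
    labels: pd.Series | np.ndarray,
    removed: str,
    method: VelocityMethod,
    seed: int = 0,
) -> dict:
    """Replicate coherence with and without one (intermediate) cell type.

    The labeled cells are dropped from both layers; the gene universe is
    kept unchanged (genes may become all-zero).  Returns both coherence
    summaries and the difference of medians (reduced minus full).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != spliced.n_cells:
        raise ValueError("labels must align with cells")
    if removed not in set(labels.tolist()):
        raise ValueError(f"label {removed!r} not present among cells")

    def coherence_summary(s: CountMatrix, u: CountMatrix) -> dict:
        disp_s = estimate_overdispersion(s)
        disp_u = estimate_overdispersion(u)
        pair_s = split_counts(s, disp_s, seed)
        pair_u = split_counts(u, disp_u, seed)
        V1 = method.fit(pair_s.split1, pair_u.split1)
        V2 = method.fit(pair_s.split2, pair_u.split2)
        return summarize_coherence(replicate_coherence(V1, V2))

    full = coherence_summary(spliced, unspliced)
    keep = labels != removed
    reduced = coherence_summary(spliced.subset_cells(keep), unspliced.subset_cells(keep))
    return {
        "full": full,
        "reduced": reduced,
        "removed": removed,
        "n_removed": int((~keep).sum()),
        "median_difference": reduced["median"] - full["median"],
    }
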