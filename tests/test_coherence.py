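"""Replicate/local coherence: oracles, invariances, null behavior, kNN graph."""

import numpy as np
import pandas as pd
import pytest

from velostab.coherence import (
    NeighborGraph,
    build_knn_graph,
    local_coherence,
    replicate_coherence,
    shuffled_pair_null,
    summarize_coherence,
    union_align,
)
from velostab.containers import CoherenceVector, CountMatrix, VelocityResult

from conftest import count_matrix


def vres(M, genes=None, cells=None):
    M = np.atleast_2d(np.asarray(M, dtype=float))
    n, p = M.shape
    return VelocityResult(
        M,
        pd.Index(genes if genes is not None else [f"g{j}" for j in range(p)]),
        pd.Index(cells if cells is not None else [f"c{i}" for i in range(n)]),
    )


def brute_replicate(V1, V2):
    """Naive per-cell dot/norm loop over the union of gene ids."""
    union = sorted(set(V1.gene_ids) | set(V2.gene_ids))
    out = []
    for i in range(len(V1.cell_ids)):
        a = np.array([
            V1.velocities[i, list(V1.gene_ids).index(g)] if g in set(V1.gene_ids) else 0.0
            for g in union
        ])
        b = np.array([
            V2.velocities[i, list(V2.gene_ids).index(g)] if g in set(V2.gene_ids) else 0.0
            for g in union
        ])
        na, nb = np.sqrt((a * a).sum()), np.sqrt((b * b).sum())
        out.append(np.nan if na == 0 or nb == 0 else float(a @ b) / (na * nb))
    return np.array(out)


def brute_local(V, graph):
    """Naive double loop with per-cell gene-mean centering."""
    C = np.array([row - row.mean() for row in V.velocities])
    out = []
    for i in range(len(V.cell_ids)):
        ci = C[i]
        if np.linalg.norm(ci) == 0:
            out.append(np.nan)
            continue
        sims = []
        for k in graph.neighbor_sets[i]:
            ck = C[k]
            if np.linalg.norm(ck) == 0:
                continue
            sims.append(ck @ ci / (np.linalg.norm(ck) * np.linalg.norm(ci)))
        out.append(np.mean(sims) if sims else np.nan)
    return np.array(out)


class TestUnionAlign:
    def test_identical_gene_sets_unchanged_up_to_order(self, rng):
        V1 = vres(rng.standard_normal((4, 3)), genes=["b", "a", "c"])
        V2 = vres(rng.standard_normal((4, 3)), genes=["b", "a", "c"])
        A1, A2 = union_align(V1, V2)
        assert list(A1.gene_ids) == ["a", "b", "c"]
        np.testing.assert_allclose(A1.velocities[:, 1], V1.velocities[:, 0])

    def test_disjoint_gene_sets_zero_padded(self, rng):
        V1 = vres(rng.standard_normal((2, 3)), genes=["a", "b", "c"])
        V2 = vres(rng.standard_normal((2, 4)), genes=["d", "e", "f", "g"])
        A1, A2 = union_align(V1, V2)
        assert len(A1.gene_ids) == 7 and len(A2.gene_ids) == 7
        assert np.all(A1.velocities[:, A1.gene_ids.get_indexer(["d", "e", "f", "g"])] == 0)
        assert np.all(A2.velocities[:, A2.gene_ids.get_indexer(["a", "b", "c"])] == 0)

    def test_empty_gene_set_becomes_all_zero(self, rng):
        V1 = vres(rng.standard_normal((3, 2)), genes=["a", "b"])
        V2 = vres(np.zeros((3, 0)), genes=[])
        A1, A2 = union_align(V1, V2)
        assert np.all(A2.velocities == 0)
        assert A2.velocities.shape == (3, 2)

    def test_cell_mismatch_raises(self, rng):
        V1 = vres(rng.standard_normal((3, 2)))
        V2 = vres(rng.standard_normal((3, 2)), cells=["x", "y", "z"])
        with pytest.raises(ValueError):
            union_align(V1, V2)


class TestReplicateCoherence:
    def test_self_similarity_is_one_and_negation_minus_one(self, rng):
        V = vres(rng.standard_normal((6, 5)))
        Vneg = vres(-V.velocities)
        np.testing.assert_allclose(replicate_coherence(V, V).values, 1.0)
        np.testing.assert_allclose(replicate_coherence(V, Vneg).values, -1.0)

    def test_disjoint_supports_give_zero(self, rng):
        V1 = vres(rng.standard_normal((4, 2)) + 3, genes=["a", "b"])
        V2 = vres(rng.standard_normal((4, 2)) + 3, genes=["c", "d"])
        np.testing.assert_allclose(replicate_coherence(V1, V2).values, 0.0, atol=1e-15)

    def test_zero_norm_cell_gets_missing(self, rng):
        M = rng.standard_normal((3, 4))
        M[1] = 0.0
        theta = replicate_coherence(vres(M), vres(rng.standard_normal((3, 4))))
        assert np.isnan(theta.values[1])
        assert not np.isnan(theta.values[[0, 2]]).any()

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 7))
            p1 = int(rng.integers(1, 5))
            p2 = int(rng.integers(1, 5))
            genes = [f"g{j}" for j in range(6)]
            V1 = vres(rng.standard_normal((n, p1)), genes=list(rng.choice(genes, p1, replace=False)))
            V2 = vres(rng.standard_normal((n, p2)), genes=list(rng.choice(genes, p2, replace=False)))
            got = replicate_coherence(V1, V2).values
            want = brute_replicate(V1, V2)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_symmetry_and_scale_invariance(self, rng):
        V1 = vres(rng.standard_normal((8, 6)))
        V2 = vres(rng.standard_normal((8, 6)))
        t12 = replicate_coherence(V1, V2).values
        t21 = replicate_coherence(V2, V1).values
        np.testing.assert_allclose(t12, t21, atol=1e-14)
        scales = rng.uniform(0.1, 10, size=8)[:, None]
        V2s = vres(V2.velocities * scales)
        np.testing.assert_allclose(replicate_coherence(V1, V2s).values, t12, atol=1e-12)

    def test_bounded_on_randomized_inputs(self, rng):
        # 10^4 random cell pairs in one vectorized sweep
        V1 = vres(rng.standard_normal((10_000, 7)) * 100)
        V2 = vres(rng.standard_normal((10_000, 7)) / 100)
        vals = replicate_coherence(V1, V2).values
        assert np.nanmin(vals) >= -1.0 and np.nanmax(vals) <= 1.0

    def test_null_mean_shrinks_with_dimension(self, rng):
        means = []
        for p in (10, 100, 1000):
            V1 = vres(rng.standard_normal((300, p)))
            V2 = vres(rng.standard_normal((300, p)))
            means.append(abs(np.nanmean(replicate_coherence(V1, V2).values)))
        assert means[2] < means[0]
        assert means[2] < 0.05


class TestLocalCoherence:
    def test_shared_vector_gives_one(self):
        v = np.array([1.0, 2.0, 3.0])
        V = vres(np.tile(v, (5, 1)))
        graph = NeighborGraph([np.array([j for j in range(5) if j != i]) for i in range(5)], k=4)
        np.testing.assert_allclose(local_coherence(V, graph).values, 1.0)

    def test_constant_row_gets_missing(self, rng):
        M = rng.standard_normal((4, 3))
        M[2] = 5.0  # constant across genes -> centered vector is 0
        graph = NeighborGraph([np.array([j for j in range(4) if j != i]) for i in range(4)], k=3)
        theta = local_coherence(vres(M), graph)
        assert np.isnan(theta.values[2])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 8))
            p = int(rng.integers(2, 6))
            V = vres(rng.standard_normal((n, p)))
            sets = [
                rng.choice([j for j in range(n) if j != i], size=min(2, n - 1), replace=False)
                for i in range(n)
            ]
            graph = NeighborGraph(sets, k=2)
            np.testing.assert_allclose(
                local_coherence(V, graph).values, brute_local(V, graph), atol=1e-12
            )

    def test_empty_neighbor_set_gives_missing(self, rng):
        V = vres(rng.standard_normal((3, 4)))
        graph = NeighborGraph([np.array([1]), np.array([], dtype=int), np.array([0])], k=1)
        theta = local_coherence(V, graph)
        assert np.isnan(theta.values[1])


class TestShuffledNull:
    def test_identity_permutation_reproduces_observed(self, rng):
        V1 = vres(rng.standard_normal((50, 10)))
        V2 = vres(rng.standard_normal((50, 10)))
        observed = np.nanmedian(replicate_coherence(V1, V2).values)
        medians = shuffled_pair_null(V1, V2, n_perm=3, seed=0)
        assert medians[0] == pytest.approx(observed, abs=1e-12)
        assert len(medians) == 4

    def test_isotropic_null_concentrates_near_zero(self, rng):
        V1 = vres(rng.standard_normal((200, 100)))
        V2 = vres(rng.standard_normal((200, 100)))
        medians = shuffled_pair_null(V1, V2, n_perm=20, seed=1)
        assert np.max(np.abs(medians)) < 0.1

    def test_deterministic_given_seed(self, rng):
        V1 = vres(rng.standard_normal((30, 5)))
        V2 = vres(rng.standard_normal((30, 5)))
        m1 = shuffled_pair_null(V1, V2, n_perm=2, seed=7)
        m2 = shuffled_pair_null(V1, V2, n_perm=2, seed=7)
        np.testing.assert_array_equal(m1, m2)

    def test_invalid_n_perm(self, rng):
        V = vres(rng.standard_normal((5, 3)))
        with pytest.raises(ValueError):
            shuffled_pair_null(V, V, n_perm=0, seed=0)


class TestKnnGraph:
    def test_collinear_cells_pick_nearer_endpoint(self):
        # equal-total cells at positions 0, 1, 10 along one gene axis, so
        # library normalization does not distort the line
        X = count_matrix(np.array([[0, 10], [1, 9], [10, 0]]))
        graph = build_knn_graph(X, k=1, n_pcs=1)
        assert graph.neighbor_sets[1][0] == 0

    def test_full_graph_when_k_is_n_minus_one(self, rng):
        X = count_matrix(rng.integers(0, 20, size=(6, 4)))
        graph = build_knn_graph(X, k=5, n_pcs=2)
        for i, ne in enumerate(graph.neighbor_sets):
            assert set(ne) == set(range(6)) - {i}

    def test_duplicate_cells_are_mutual_neighbors(self, rng):
        base = rng.integers(0, 20, size=(5, 4))
        X = count_matrix(np.vstack([base, base[:1]]))  # cell 5 duplicates cell 0
        graph = build_knn_graph(X, k=1, n_pcs=2)
        assert graph.neighbor_sets[5][0] == 0
        assert graph.neighbor_sets[0][0] == 5

    def test_k_too_large_raises(self, rng):
        X = count_matrix(rng.integers(0, 5, size=(4, 3)))
        with pytest.raises(ValueError):
            build_knn_graph(X, k=4)


class TestSummaries:
    def test_median_over_non_missing(self):
        theta = CoherenceVector(
            np.array([0.2, np.nan, 0.6, 0.8]), pd.Index(list("abcd"))
        )
        s = summarize_coherence(theta)
        assert s["median"] == pytest.approx(0.6)
        assert s["n"] == 3

    @pytest.mark.parametrize(
        "values,median", [([1.0, 1.0, 1.0], 1.0), ([-1.0, 0.0, 1.0], 0.0)]
    )
    def test_simple_medians(self, values, median):
        theta = CoherenceVector(np.array(values), pd.Index(list("abc")))
        assert summarize_coherence(theta)["median"] == pytest.approx(median)

    def test_all_missing_raises(self):
        theta = CoherenceVector(np.array([np.nan, np.nan]), pd.Index(list("ab")))
        with pytest.raises(ValueError):
            summarize_coherence(theta)
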