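import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmscoex.network import (
    AdjacencyMatrix,
    SimilarityMatrix,
    adjacency,
    pick_soft_threshold,
    scale_free_fit,
    similarity,
    topological_overlap,
)
from pmscoex.preprocess import ExpressionMatrix, UnitState


def log_matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=genes, columns=[f"S{j}" for j in range(values.shape[1])])
    return ExpressionMatrix(df, unit_state=UnitState.LOG2_RPKM_PLUS1)


def naive_pearson(x, y):
    """Two-pass textbook correlation, independent of numpy.corrcoef."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def naive_tom(A):
    """Triple-loop scalar TOM, the oracle for the matrix implementation."""
    n = A.shape[0]
    W = A.copy()
    np.fill_diagonal(W, 0.0)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(W[i, u] * W[u, j] for u in range(n) if u not in (i, j))
            ki = sum(W[i, u] for u in range(n) if u != i)
            kj = sum(W[j, u] for u in range(n) if u != j)
            denom = min(ki, kj) + 1 - W[i, j]
            T[i, j] = (l + W[i, j]) / denom if denom > 0 else 0.0
    return T


class TestSimilarity:
    def test_anticorrelated_pair_both_modes(self):
        # centered profiles [1,0,-1] and [-1,1,0] have cor exactly -0.5
        x = np.array([2.0, 1.0, 0.0])
        y = np.array([0.0, 2.0, 1.0])
        assert naive_pearson(x, y) == pytest.approx(-0.5)
        M = log_matrix(np.vstack([x, y]))
        assert similarity(M, "unsigned_abs").S[0, 1] == pytest.approx(0.5)
        assert similarity(M, "signed_shift").S[0, 1] == pytest.approx(0.25)

    def test_self_similarity_is_one(self):
        M = log_matrix(np.random.default_rng(0).uniform(0, 4, (3, 10)))
        for mode in ("unsigned_abs", "signed_shift"):
            assert np.allclose(np.diag(similarity(M, mode).S), 1.0)

    def test_matches_naive_two_pass_loop(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 5, (10, 30))
        S = similarity(log_matrix(X)).S
        for i in range(10):
            for j in range(10):
                assert S[i, j] == pytest.approx(abs(naive_pearson(X[i], X[j])), abs=1e-12)

    def test_zero_variance_gene_named(self):
        X = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="G0"):
            similarity(log_matrix(X))


class TestAdjacency:
    def test_power_values(self):
        S = SimilarityMatrix(
            np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 1.0], [0.0, 1.0, 1.0]]),
            "unsigned_abs",
            ["A", "B", "C"],
        )
        A = adjacency(S, 9)
        assert A.A[0, 1] == 0.001953125  # 0.5^9 exactly
        assert A.A[1, 2] == 1.0
        assert A.A[0, 2] == 0.0

    def test_invalid_beta(self):
        S = SimilarityMatrix(np.eye(2), "unsigned_abs", ["A", "B"])
        with pytest.raises(ValueError, match="positive integer"):
            adjacency(S, 0)


class TestScaleFreeFit:
    def test_exact_power_law_fits_well(self):
        # inverse-CDF sample from p(k) proportional to k^-2 on {1..100}
        rng = np.random.default_rng(20231026)
        support = np.arange(1, 101)
        pmf = support.astype(float) ** -2.0
        pmf /= pmf.sum()
        k = rng.choice(support, size=5000, p=pmf).astype(float)
        fit = scale_free_fit(k)
        assert not fit.degenerate
        assert fit.slope < 0
        assert fit.r2_signed >= 0.8

    def test_constant_connectivity_degenerate(self):
        fit = scale_free_fit(np.full(50, 3.0))
        assert fit.degenerate and fit.r2_signed == 0.0

    def test_inverted_law_yields_negative_signed_r2(self):
        # frequency increasing with k: p(k) proportional to k
        rng = np.random.default_rng(7)
        support = np.arange(1, 101)
        pmf = support / support.sum()
        k = rng.choice(support, size=5000, p=pmf).astype(float)
        fit = scale_free_fit(k)
        assert fit.slope > 0
        assert fit.r2_signed < 0


class TestPickSoftThreshold:
    def test_mean_connectivity_monotone_and_matches_bruteforce(self, benchmark_run):
        report = benchmark_run.soft_threshold
        mean_k = report.table["mean_k"].to_numpy()
        assert (np.diff(mean_k) <= 1e-9).all()
        # brute-force mean connectivity at beta = 1 and beta = 6
        M = benchmark_run.expression
        X = M.values.to_numpy()
        S = np.abs(np.corrcoef(X))
        np.fill_diagonal(S, 1.0)
        for beta in (1, 6):
            A = S**beta
            k = A.sum(axis=1) - 1.0
            row = report.table[report.table["beta"] == beta].iloc[0]
            assert row["mean_k"] == pytest.approx(k.mean(), rel=1e-9)

    def test_identity_similarity_uses_fallback_with_flag(self):
        S = SimilarityMatrix(np.eye(30), "unsigned_abs", [f"G{i}" for i in range(30)])
        report = pick_soft_threshold(S)
        assert report.fallback_used
        assert report.chosen_beta == 9
        assert report.table["degenerate"].all()

    def test_single_candidate_meeting_target(self, benchmark_run):
        M = benchmark_run.expression
        S = similarity(M)
        full = pick_soft_threshold(S, target_r2=0.8)
        forced = pick_soft_threshold(S, candidates=[9], target_r2=0.0)
        assert forced.chosen_beta == 9
        assert full.chosen_beta <= 20

    def test_descending_candidates_rejected(self):
        S = SimilarityMatrix(np.eye(3), "unsigned_abs", ["A", "B", "C"])
        with pytest.raises(ValueError, match="ascending"):
            pick_soft_threshold(S, candidates=[3, 2, 1])


class TestTopologicalOverlap:
    def test_unit_triangle_overlap_is_one(self):
        A = AdjacencyMatrix(np.ones((3, 3)), 1, ["A", "B", "C"])
        T = topological_overlap(A).T
        assert np.allclose(T, 1.0)

    def test_three_node_path(self):
        W = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 1.0], [0.0, 1.0, 1.0]])
        T = topological_overlap(AdjacencyMatrix(W, 1, ["A", "B", "C"])).T
        assert T[0, 2] == pytest.approx(0.5)  # (l=1) / (min k + 1 - a) = 1/2
        assert T[0, 1] == pytest.approx((0 + 1) / (1 + 1 - 1))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(12)
        S = rng.uniform(0, 1, (12, 12))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        A = AdjacencyMatrix(S**4, 4, [f"G{i}" for i in range(12)])
        T = topological_overlap(A).T
        np.testing.assert_allclose(T, naive_tom(A.A), atol=1e-12)


class TestProperties:
    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10_000))
    def test_tom_entries_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        S = rng.uniform(0, 1, (n, n))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        T = topological_overlap(AdjacencyMatrix(S**3, 3, [f"G{i}" for i in range(n)])).T
        assert (T >= 0).all() and (T <= 1).all()
        assert np.allclose(T, T.T)
        assert np.allclose(np.diag(T), 1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 5, (9, 40))
        perm = rng.permutation(9)
        M = log_matrix(X)
        Mp = log_matrix(X[perm], genes=[f"G{i}" for i in perm])
        S, Sp = similarity(M).S, similarity(Mp).S
        np.testing.assert_allclose(Sp, S[np.ix_(perm, perm)], atol=1e-12)
        T = topological_overlap(adjacency(similarity(M), 5)).T
        Tp = topological_overlap(adjacency(similarity(Mp), 5)).T
        np.testing.assert_allclose(Tp, T[np.ix_(perm, perm)], atol=1e-12)

    def test_adjacency_strictly_decreasing_in_beta(self):
        rng = np.random.default_rng(4)
        S = rng.uniform(0.05, 0.95, (6, 6))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        sim = SimilarityMatrix(S, "unsigned_abs", [f"G{i}" for i in range(6)])
        off = ~np.eye(6, dtype=bool)
        prev = adjacency(sim, 1).A
        for beta in (2, 4, 8):
            nxt = adjacency(sim, beta).A
            assert (nxt[off] < prev[off]).all()
            prev = nxt
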