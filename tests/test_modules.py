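import numpy as np
import pandas as pd
import pytest

from pmscoex.modules import (
    GREY_LABEL,
    ModulePartition,
    assign_colors,
    cut_modules,
    hierarchical_cluster,
    merge_close_modules,
    module_eigengenes,
    module_membership,
)
from pmscoex.preprocess import ExpressionMatrix, UnitState
from pmscoex.simulate import ModulePlan, SyntheticSpec, simulate_expression


def log_matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=genes, columns=[f"S{j}" for j in range(values.shape[1])])
    return ExpressionMatrix(df, unit_state=UnitState.LOG2_RPKM_PLUS1)


def block_dissimilarity(block_sizes, within=0.1, between=0.9):
    n = sum(block_sizes)
    D = np.full((n, n), between)
    start = 0
    for size in block_sizes:
        D[start : start + size, start : start + size] = within
        start += size
    np.fill_diagonal(D, 0.0)
    return D


class TestHierarchicalCluster:
    def test_two_block_heights(self):
        D = block_dissimilarity([2, 2])
        d = hierarchical_cluster(D, ["A", "B", "C", "D"])
        heights = sorted(d.heights)
        assert heights[0] == pytest.approx(0.1)
        assert heights[1] == pytest.approx(0.1)
        assert heights[2] == pytest.approx(0.9)

    def test_two_leaves_single_merge(self):
        d = hierarchical_cluster(np.array([[0.0, 0.4], [0.4, 0.0]]), ["A", "B"])
        assert len(d.Z) == 1 and d.heights[0] == pytest.approx(0.4)

    def test_all_zero_dissimilarity(self):
        d = hierarchical_cluster(np.zeros((5, 5)), [f"G{i}" for i in range(5)])
        assert np.allclose(d.heights, 0.0)

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 0.5], [0.2, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cluster(D, ["A", "B"])


@pytest.fixture(scope="module")
def noiseless_blocks():
    # 3 planted blocks of 40 genes with loading ~ 1 (rank-1 modules)
    spec = SyntheticSpec(
        n_samples=50,
        modules=tuple(ModulePlan(40, (0.999, 1.0)) for _ in range(3)),
        n_background=0,
        n_near_zero=0,
        set_plants=(),
        hub_plants=(),
        seed=11,
    )
    M, truth = simulate_expression(spec)
    X = np.log2(M.values.to_numpy() + 1.0)
    C = np.abs(np.corrcoef(X))
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    dendro = hierarchical_cluster((D + D.T) / 2, M.gene_ids)
    return dendro, truth


class TestCutModules:
    def test_recovers_three_blocks_no_grey(self, noiseless_blocks):
        dendro, truth = noiseless_blocks
        part = cut_modules(dendro, min_module_size=30)
        assert part.n_modules == 3
        assert sorted(part.module_sizes.values()) == [40, 40, 40]
        assert int((part.labels == GREY_LABEL).sum()) == 0
        for m in range(3):
            found = {int(part.labels[g]) for g in truth.module_genes(m)}
            assert len(found) == 1

    def test_min_size_dominates(self, noiseless_blocks):
        dendro, _ = noiseless_blocks
        part = cut_modules(dendro, min_module_size=50)
        assert part.n_modules == 0
        assert (part.labels == GREY_LABEL).all()

    def test_static_cut_height_zero_all_grey(self, noiseless_blocks):
        dendro, _ = noiseless_blocks
        part = cut_modules(dendro, method="static", cut_height=0.0, min_module_size=2)
        assert (part.labels == GREY_LABEL).all()

    def test_static_cut_out_of_range(self, noiseless_blocks):
        dendro, _ = noiseless_blocks
        with pytest.raises(ValueError, match="outside"):
            cut_modules(dendro, method="static", cut_height=dendro.max_height + 1)


class TestEigengenes:
    def test_identical_profiles_rank_one(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        M = log_matrix(np.tile(profile, (10, 1)))
        part = ModulePartition(pd.Series(1, index=M.values.index))
        eig = module_eigengenes(M, part)
        assert eig.explained_variance[1] == pytest.approx(1.0)
        e = eig.ME.loc[1].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(e, z / np.linalg.norm(z), atol=1e-12)

    def test_exactly_negated_pair(self):
        x = np.array([1.0, 2.0, 4.0, 0.0, 3.0])
        M = log_matrix(np.vstack([x, x.max() - x]))  # second gene = negated profile
        part = ModulePartition(pd.Series(1, index=M.values.index))
        eig = module_eigengenes(M, part)
        assert eig.explained_variance[1] == pytest.approx(1.0)

    def test_sign_aligned_with_mean_profile(self, benchmark_run):
        M = benchmark_run.expression
        eig = benchmark_run.eigengenes
        part = benchmark_run.partition
        for mod in part.module_ids:
            X = M.values.loc[part.members(mod)].to_numpy()
            Xz = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
            mean_profile = Xz.mean(axis=0)
            assert float(eig.ME.loc[mod] @ mean_profile) >= 0

    def test_latent_factor_recovery_high_loading(self):
        spec = SyntheticSpec(
            n_samples=200,
            modules=(ModulePlan(30, (0.9, 0.9)),),
            n_background=0,
            n_near_zero=0,
            set_plants=(),
            hub_plants=(),
            seed=3,
        )
        M, truth = simulate_expression(spec)
        X = np.log2(M.values.to_numpy() + 1.0)
        Ml = ExpressionMatrix(
            pd.DataFrame(X, index=M.values.index, columns=M.values.columns),
            unit_state=UnitState.LOG2_RPKM_PLUS1,
        )
        part = ModulePartition(pd.Series(1, index=Ml.values.index))
        eig = module_eigengenes(Ml, part)
        r = np.corrcoef(eig.ME.loc[1], truth.factors.loc[0])[0, 1]
        assert r**2 >= 0.95

    def test_sign_stability_under_gene_flip(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(1, 5, (8, 30))
        M = log_matrix(X)
        part = ModulePartition(pd.Series(1, index=M.values.index))
        e1 = module_eigengenes(M, part).ME.loc[1].to_numpy()
        Xf = X.copy()
        Xf[3] = Xf[3].max() + Xf[3].min() - Xf[3]  # reflect one gene
        e2 = module_eigengenes(log_matrix(Xf), part).ME.loc[1].to_numpy()
        # same eigengene up to the documented mean-profile sign alignment
        assert abs(abs(e1 @ e2) - 1.0) < 0.05


class TestMerging:
    def _matrix_with_modules(self, profiles, genes_per=5, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for m, p in enumerate(profiles, start=1):
            for _ in range(genes_per):
                rows.append(p + noise * rng.standard_normal(len(p)))
                labels.append(m)
        M = log_matrix(np.array(rows) - np.min(rows))
        part = ModulePartition(pd.Series(labels, index=M.values.index))
        return M, part

    def test_identical_eigengenes_merge(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 4, 40)
        M, part = self._matrix_with_modules([p, p], noise=0.01, seed=1)
        eig = module_eigengenes(M, part)
        merged, _ = merge_close_modules(M, part, eig)
        assert merged.n_modules == 1

    def test_uncorrelated_eigengenes_kept(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(100), rng.standard_normal(100)
        b = b - (b @ a) / (a @ a) * a  # orthogonalize: cor(ME) ~ 0
        M, part = self._matrix_with_modules([a, b], noise=0.01, seed=2)
        eig = module_eigengenes(M, part)
        merged, _ = merge_close_modules(M, part, eig)
        assert merged.n_modules == 2

    def test_three_highly_correlated_modules_fuse_to_one(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(200)
        profiles = [base + 0.32 * rng.standard_normal(200) for _ in range(3)]
        # construct so all pairwise eigengene correlations are ~0.9
        M, part = self._matrix_with_modules(profiles, genes_per=6, noise=0.01, seed=3)
        eig = module_eigengenes(M, part)
        E = eig.ME.to_numpy()
        cors = np.corrcoef(E)[np.triu_indices(3, 1)]
        assert (cors > 0.85).all()
        merged, _ = merge_close_modules(M, part, eig)
        # oracle: exhaustive pairwise merging of modules with 1-cor < 0.25
        assert merged.n_modules == 1

    def test_module_count_never_increases(self, benchmark_run):
        part = benchmark_run.partition
        eig = benchmark_run.eigengenes
        M = benchmark_run.expression
        merged, _ = merge_close_modules(M, part, eig, merge_cut_height=0.9)
        assert merged.n_modules <= part.n_modules


class TestMembershipAndColors:
    def test_gene_equal_to_eigengene_has_kme_one(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 4, 50)
        M = log_matrix(np.tile(p, (6, 1)))
        part = ModulePartition(pd.Series(1, index=M.values.index))
        eig = module_eigengenes(M, part)
        kme = module_membership(M, eig)
        assert np.allclose(kme[1], 1.0)

    def test_noise_gene_low_kme(self):
        rng = np.random.default_rng(6)
        p = rng.standard_normal(500)
        rows = np.vstack([np.tile(p, (5, 1)), rng.standard_normal((1, 500))])
        M = log_matrix(rows - rows.min())
        part = ModulePartition(pd.Series([1] * 5 + [GREY_LABEL], index=M.values.index))
        eig = module_eigengenes(M, part)
        kme = module_membership(M, eig)
        assert abs(kme.loc["G5", 1]) < 0.2  # null |cor| at n=500

    def test_color_order_and_ties(self):
        labels = pd.Series(
            [1] * 4 + [2] * 6 + [3] * 4 + [GREY_LABEL],
            index=[f"B{i:02d}" for i in range(4)]
            + [f"C{i:02d}" for i in range(6)]
            + [f"A{i:02d}" for i in range(4)]
            + ["ZZZ"],
        )
        part = assign_colors(ModulePartition(labels))
        assert part.color_of_module(2) == "turquoise"  # largest
        # size tie between modules 1 and 3 -> smallest member symbol wins
        assert part.color_of_module(3) == "blue"
        assert part.color_of_module(1) == "brown"
        assert part.color_of("ZZZ") == "grey"

    def test_overflow_color_names(self):
        labels = pd.Series(
            np.repeat(np.arange(1, 56), 2), index=[f"G{i}" for i in range(110)]
        )
        part = assign_colors(ModulePartition(labels))
        names = {part.color_of_module(m) for m in part.module_ids}
        assert "turquoise" in names
        assert any(n.startswith("module_5") for n in names)
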