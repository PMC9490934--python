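import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncnet import network
from lncnet.network import (
    MatrixError,
    average_linkage,
    correlation_matrix,
    hybrid_tree_cut,
    module_eigengenes,
    pick_soft_threshold,
    scale_free_fit,
    soft_adjacency,
    topological_overlap,
)


def _frame(a, prefix="g"):
    idx = [f"{prefix}{i}" for i in range(a.shape[0])]
    return pd.DataFrame(a, index=idx, columns=idx)


def _random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return _frame(a)


class TestCorrelation:
    def test_duplicate_and_negated_genes(self, toy_expression):
        cor = correlation_matrix(toy_expression)
        assert cor.loc["g0", "g1"] == pytest.approx(1.0, abs=1e-4)
        assert cor.loc["g2", "g3"] == pytest.approx(-1.0)

    def test_matches_two_pass_oracle(self, rng):
        x = rng.normal(size=(10, 8))
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(10)],
                            columns=[f"s{j}" for j in range(8)])
        cor = correlation_matrix(expr).to_numpy()
        # naive two-pass covariance / sigma oracle
        oracle = np.empty((10, 10))
        for i in range(10):
            for j in range(10):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                oracle[i, j] = (xi * xj).sum() / np.sqrt(
                    (xi**2).sum() * (xj**2).sum()
                )
        np.testing.assert_allclose(cor, oracle, atol=1e-12)

    def test_zero_variance_gene_reported(self, toy_expression):
        bad = toy_expression.copy()
        bad.loc["g5"] = 3.0
        with pytest.raises(MatrixError, match="g5"):
            correlation_matrix(bad)


class TestSoftAdjacency:
    def test_power_and_unsigned(self):
        cor = _frame(np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert soft_adjacency(cor, 2).iloc[0, 1] == pytest.approx(0.81)
        neg = _frame(np.array([[1.0, -0.9], [-0.9, 1.0]]))
        assert soft_adjacency(neg, 2).iloc[0, 1] == pytest.approx(0.81)

    def test_beta_one_is_absolute_value(self, rng):
        cor = _frame(np.clip((lambda a: (a + a.T) / 2)(
            rng.uniform(-1, 1, (5, 5))), -1, 1))
        np.fill_diagonal(cor.values, 1.0)
        out = soft_adjacency(cor, 1)
        np.testing.assert_allclose(out.to_numpy(), np.abs(cor.to_numpy()))

    def test_bad_beta(self):
        with pytest.raises(MatrixError):
            soft_adjacency(_frame(np.eye(2)), 0)

    def test_raising_beta_sharpens(self, rng):
        cor = _random_adjacency(rng, 12)  # entries in [0,1], usable as |r|
        a2 = soft_adjacency(cor, 2).to_numpy()
        a5 = soft_adjacency(cor, 5).to_numpy()
        off = ~np.eye(12, dtype=bool)
        assert (a5[off] <= a2[off] + 1e-15).all()


class TestScaleFreeFit:
    def test_exact_power_law_gives_one(self):
        # block-diagonal weighted graph: 20 nodes with k=1 (10 disjoint
        # edges), 10 with k=2 (a 10-cycle), 5 with k=4 (K5): frequencies
        # 20/10/5 at k = 1/2/4 are exactly log-log collinear (slope -1)
        n = 35
        a = np.zeros((n, n))
        for i in range(0, 20, 2):
            a[i, i + 1] = a[i + 1, i] = 1.0
        cyc = list(range(20, 30))
        for u, v in zip(cyc, cyc[1:] + cyc[:1]):
            a[u, v] = a[v, u] = 1.0
        for u in range(30, 35):
            for v in range(30, 35):
                if u != v:
                    a[u, v] = 1.0
        np.fill_diagonal(a, 1.0)
        fit = scale_free_fit(_frame(a), n_bins=10)
        assert fit.signed_r2 == pytest.approx(1.0, abs=1e-12)

    def test_regular_graph_degenerate(self):
        a = np.full((6, 6), 0.5)
        np.fill_diagonal(a, 1.0)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = scale_free_fit(_frame(a))
        assert fit.signed_r2 == 0.0

    def test_preferential_attachment_graph_fits(self):
        import networkx as nx

        g = nx.barabasi_albert_graph(200, 2, seed=1)
        a = nx.to_numpy_array(g)
        np.fill_diagonal(a, 1.0)
        fit = scale_free_fit(_frame(a))
        assert fit.signed_r2 > 0.7


class TestPickSoftThreshold:
    def test_override_bypasses_selection(self, default_dataset):
        expr = default_dataset.expression.iloc[:150]
        cor = correlation_matrix(expr)
        beta, table = pick_soft_threshold(cor, powers=range(1, 8), override=18)
        assert beta == 18
        assert len(table) == 7

    def test_choice_consistent_with_reported_table(self, default_dataset):
        expr = default_dataset.expression.iloc[:300]
        cor = correlation_matrix(expr)
        beta, table = pick_soft_threshold(cor, r2_cut=0.85)
        reaching = table.index[table["signed_r2"] >= 0.85]
        if len(reaching):
            assert beta == reaching[0]
        else:
            assert beta == table["signed_r2"].idxmax()

    def test_mean_connectivity_decreases_with_beta(self, default_dataset):
        cor = correlation_matrix(default_dataset.expression.iloc[:100])
        _, table = pick_soft_threshold(cor, powers=range(1, 10))
        k = table["mean_connectivity"].to_numpy()
        assert (np.diff(k) < 0).all()

    def test_empty_powers(self, toy_expression):
        cor = correlation_matrix(toy_expression)
        with pytest.raises(MatrixError):
            pick_soft_threshold(cor, powers=[])


class TestTopologicalOverlap:
    def test_hand_example_complete(self):
        a = _frame(np.array(
            [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]))
        tom = topological_overlap(a)
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_example_single_edge(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.5
        np.fill_diagonal(a, 1.0)
        tom = topological_overlap(_frame(a))
        # (l + a) / (min(k) + 1 - a) = (0 + 0.5) / (0.5 + 1 - 0.5)
        assert tom.iloc[0, 1] == pytest.approx(0.5)

    def test_matches_triple_loop_oracle(self, rng):
        adj = _random_adjacency(rng, 30)
        tom = topological_overlap(adj).to_numpy()
        a = adj.to_numpy().copy()
        np.fill_diagonal(a, 0.0)
        n = 30
        oracle = np.eye(n)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                oracle[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
        np.testing.assert_allclose(tom, oracle, atol=1e-10)

    def test_rejects_asymmetric(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(MatrixError):
            topological_overlap(_frame(a))

    @given(st.integers(0, 10_000))
    @settings(max_examples=20)
    def test_range_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        tom = topological_overlap(_random_adjacency(rng, 8)).to_numpy()
        assert ((tom >= 0) & (tom <= 1 + 1e-12)).all()
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)


class TestAverageLinkage:
    def test_hand_upgma(self):
        d = np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]])
        dend = average_linkage(_frame(d))
        np.testing.assert_allclose(dend.heights, [0.1, 0.5])
        assert set(dend.merges[0, :2].astype(int)) == {0, 1}

    def test_two_genes(self):
        d = np.array([[0, 0.3], [0.3, 0]])
        dend = average_linkage(_frame(d))
        assert dend.merges.shape == (1, 4)
        assert dend.heights[0] == pytest.approx(0.3)

    def test_monotone_heights_on_random_input(self, rng):
        d = rng.uniform(0.1, 1, size=(20, 20))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dend = average_linkage(_frame(d))
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_nan_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(MatrixError):
            average_linkage(_frame(d))


def _block_tom(n_blocks=2, size=50, intra=0.8, inter=0.05):
    n = n_blocks * size
    tom = np.full((n, n), inter)
    for b in range(n_blocks):
        s = slice(b * size, (b + 1) * size)
        tom[s, s] = intra
    np.fill_diagonal(tom, 1.0)
    d = 1 - tom
    np.fill_diagonal(d, 0.0)
    return _frame(d)


class TestHybridTreeCut:
    def test_two_planted_blocks_recovered_perfectly(self):
        dis = _block_tom()
        dend = average_linkage(dis)
        mods = hybrid_tree_cut(dend, dis, min_module_size=30)
        assert mods.sizes() == {"M1": 50, "M2": 50}
        first = set(mods.labels.iloc[:50])
        second = set(mods.labels.iloc[50:])
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_all_noise_yields_no_modules(self, rng):
        n = 120
        tom = rng.uniform(0, 0.02, size=(n, n))
        tom = (tom + tom.T) / 2
        np.fill_diagonal(tom, 1.0)
        d = 1 - tom
        np.fill_diagonal(d, 0.0)
        dis = _frame(d)
        dend = average_linkage(dis)
        mods = hybrid_tree_cut(dend, dis, min_module_size=30)
        assert mods.modules == []
        assert (mods.labels == network.UNASSIGNED).all()

    def test_order_invariance_up_to_relabeling(self, rng):
        dis = _block_tom(size=40)
        perm = rng.permutation(dis.index)
        dis_p = dis.loc[perm, perm]
        mods_a = hybrid_tree_cut(average_linkage(dis), dis, min_module_size=30)
        mods_b = hybrid_tree_cut(average_linkage(dis_p), dis_p, min_module_size=30)
        from sklearn.metrics import adjusted_rand_score

        joint = pd.concat(
            [mods_a.labels.rename("a"), mods_b.labels.rename("b")], axis=1
        )
        assert adjusted_rand_score(joint["a"], joint["b"]) == pytest.approx(1.0)

    def test_min_module_size_validation(self):
        dis = _block_tom()
        dend = average_linkage(dis)
        with pytest.raises(MatrixError):
            hybrid_tree_cut(dend, dis, min_module_size=1)


class TestEigengenes:
    def _modules(self, labels, index):
        return network.ModuleAssignment(
            labels=pd.Series(labels, index=index), min_module_size=2,
            cut_height=0.5,
        )

    def test_identical_profiles(self, rng):
        profile = rng.normal(size=8)
        expr = pd.DataFrame(
            np.tile(profile, (4, 1)) + np.outer(rng.normal(size=4), np.zeros(8)),
            index=list("abcd"), columns=[f"s{i}" for i in range(8)],
        )
        eig = module_eigengenes(expr, self._modules(["M1"] * 4, expr.index))
        assert eig.variance_explained["M1"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        cos = np.dot(eig.eigengenes.loc["M1"], z / np.linalg.norm(z))
        assert abs(cos) == pytest.approx(1.0, abs=1e-12)

    def test_sign_convention_non_negative_with_mean_profile(self, rng):
        v = rng.normal(size=10)
        expr = pd.DataFrame(
            np.tile(-v, (3, 1)) + rng.normal(0, 0.01, size=(3, 10)),
            index=list("xyz"), columns=[f"s{i}" for i in range(10)],
        )
        modules = self._modules(["M1"] * 3, expr.index)
        eig = module_eigengenes(expr, modules)
        z = expr.sub(expr.mean(1), axis=0).div(expr.std(1), axis=0)
        assert np.corrcoef(eig.eigengenes.loc["M1"], z.mean(0))[0, 1] >= 0

    def test_matches_svd_oracle(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(20, 12)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(12)],
        )
        eig = module_eigengenes(expr, self._modules(["M1"] * 20, expr.index))
        z = ((expr.to_numpy() - expr.to_numpy().mean(1, keepdims=True))
             / expr.to_numpy().std(1, keepdims=True))
        # independent oracle: leading eigenvector of the sample Gram matrix
        w, v = np.linalg.eigh(z.T @ z)
        lead = v[:, -1]
        cos = abs(np.dot(eig.eigengenes.loc["M1"].to_numpy(), lead))
        assert cos > 1 - 1e-10

    def test_eigengene_maximality(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(15, 10)),
            index=[f"g{i}" for i in range(15)],
            columns=[f"s{i}" for i in range(10)],
        )
        eig = module_eigengenes(expr, self._modules(["M1"] * 15, expr.index))
        z = ((expr.to_numpy() - expr.to_numpy().mean(1, keepdims=True))
             / expr.to_numpy().std(1, keepdims=True))

        def score(v):
            v = v / np.linalg.norm(v)
            return ((z @ v) ** 2).sum()

        best = score(eig.eigengenes.loc["M1"].to_numpy())
        rand = rng.normal(size=(1000, 10))
        assert all(score(v) <= best + 1e-9 for v in rand)
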