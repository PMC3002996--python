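import numpy as np
import pandas as pd
import pytest

from acetdyn import assoc


def _changes(A: np.ndarray, E: np.ndarray, days=(1, 3, 5), profiles=None):
    genes = [f"g{i}" for i in range(A.shape[0])]
    Adf = pd.DataFrame(A, index=genes, columns=list(days))
    Edf = pd.DataFrame(E, index=genes, columns=list(days))
    deltas = profiles or {
        d: pd.DataFrame(np.tile(A[:, [k]], (1, 14)), index=genes,
                        columns=[f"bin_{j + 1:02d}" for j in range(14)])
        for k, d in enumerate(days)
    }
    return assoc.ChangeMatrices(acet_mean=Adf, acet_median=Adf.copy(), expr=Edf,
                                delta_profiles=deltas, days=tuple(days))


class TestBuildChanges:
    def _binned(self, values_by_gene_day):
        idx = pd.MultiIndex.from_tuples(values_by_gene_day.keys(),
                                        names=["gene_id", "day"])
        return pd.DataFrame(list(values_by_gene_day.values()), index=idx,
                            columns=[f"bin_{k + 1:02d}" for k in range(14)])

    def _expr(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "day", "replicate",
                                           "expression"])

    def test_constant_expression_gives_zero_changes(self):
        binned = self._binned({("gA", 0): np.ones(14), ("gA", 5): np.ones(14)})
        expr = self._expr([("gA", 0, 1, 3.0), ("gA", 0, 2, 3.0),
                           ("gA", 5, 1, 3.0), ("gA", 5, 2, 3.0)])
        ch = assoc.build_changes(binned, expr)
        assert np.allclose(ch.expr.to_numpy(), 0)
        assert np.allclose(ch.acet_mean.to_numpy(), 0)

    def test_hand_example_replicate_average_then_difference(self):
        prof0 = np.zeros(14)
        prof5 = np.zeros(14)
        prof5[:3] = 4.0  # skewed: mean 12/14, median 0
        binned = self._binned({("gA", 0): prof0, ("gA", 5): prof5})
        expr = self._expr([("gA", 0, 1, 3.0), ("gA", 0, 2, 5.0),
                           ("gA", 5, 1, 6.0), ("gA", 5, 2, 8.0)])
        ch = assoc.build_changes(binned, expr)
        assert ch.expr.loc["gA", 5] == pytest.approx(3.0)  # mean 7 - mean 4
        assert ch.acet_mean.loc["gA", 5] == pytest.approx(12 / 14)
        assert ch.acet_median.loc["gA", 5] == pytest.approx(0.0)

    def test_gene_missing_day0_excluded_and_counted(self):
        binned = self._binned({("gA", 0): np.ones(14), ("gA", 5): np.ones(14),
                               ("gB", 0): np.ones(14), ("gB", 5): np.ones(14)})
        expr = self._expr([("gA", 0, 1, 3.0), ("gA", 5, 1, 4.0),
                           ("gB", 5, 1, 4.0)])  # gB lacks day 0
        ch = assoc.build_changes(binned, expr)
        assert list(ch.expr.index) == ["gA"]
        assert ch.n_dropped == 1


class TestCorrelationMatrix:
    def test_perfectly_coupled_diagonal(self):
        rng = np.random.default_rng(20)
        A = rng.normal(size=(200, 3))
        rep = assoc.correlation_matrix(_changes(A, A.copy()))
        assert np.allclose(np.diag(rep.matrix.to_numpy(dtype=float)), 1.0)
        rep_neg = assoc.correlation_matrix(_changes(A, -A))
        assert np.allclose(np.diag(rep_neg.matrix.to_numpy(dtype=float)), -1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(21)
        A = rng.normal(size=(10000, 3))
        E = rng.normal(size=(10000, 3))
        rep = assoc.correlation_matrix(_changes(A, E))
        assert np.abs(rep.matrix.to_numpy(dtype=float)).max() < 0.03

    def test_zero_variance_column_flagged_nan(self):
        A = np.random.default_rng(22).normal(size=(50, 3))
        E = A.copy()
        A[:, 0] = 1.0
        rep = assoc.correlation_matrix(_changes(A, E))
        assert np.isnan(rep.matrix.loc[1, 1])
        assert not np.isnan(rep.matrix.loc[3, 3])

    def test_spearman_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(23)
        A = rng.normal(size=(100, 3))
        E = A + rng.normal(size=(100, 3))
        rep = assoc.correlation_matrix(_changes(A, E), method="spearman")
        expected = stats.spearmanr(A[:, 2], E[:, 1]).statistic
        assert rep.matrix.loc[5, 3] == pytest.approx(expected)


class TestPermutationSignificance:
    def test_strong_coupling_gives_extreme_p(self):
        rng = np.random.default_rng(24)
        z = rng.normal(size=(5000, 3))
        E = 0.35 * z + rng.normal(scale=0.5, size=(5000, 3))
        rep = assoc.permutation_significance(_changes(z, E), n_perm=1000, seed=0)
        assert rep.permutation_p.loc[5, 5] == pytest.approx(1 / 1001)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(25)
        from scipy import stats
        ps = []
        for seed in range(40):
            A = rng.normal(size=(300, 1))
            E = rng.normal(size=(300, 1))
            rep = assoc.permutation_significance(
                _changes(A, E, days=(5,),
                         profiles={5: pd.DataFrame(np.tile(A, (1, 14)))}),
                n_perm=199, seed=seed)
            ps.append(rep.permutation_p.loc[5, 5])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_permutations_rejected(self):
        A = np.random.default_rng(26).normal(size=(50, 3))
        with pytest.raises(ValueError, match="n_perm"):
            assoc.permutation_significance(_changes(A, A), n_perm=0)


class TestCca:
    def test_expression_equal_to_one_bin(self):
        rng = np.random.default_rng(27)
        X = rng.normal(size=(500, 14))
        y = X[:, 7].copy()
        a, rho = assoc.cca_1d(X, y)
        assert rho == pytest.approx(1.0, abs=1e-9)
        direction = np.abs(a) / np.abs(a).max()
        assert direction[7] == pytest.approx(1.0)
        assert np.all(direction[np.arange(14) != 7] < 1e-6)

    def test_null_rho_small(self):
        rng = np.random.default_rng(28)
        X = rng.normal(size=(10000, 14))
        y = rng.normal(size=10000)
        _, rho = assoc.cca_1d(X, y)
        assert rho < 0.08

    def test_rho_at_least_mean_summary_correlation(self):
        rng = np.random.default_rng(29)
        X = rng.normal(size=(300, 14))
        y = X.mean(axis=1) + rng.normal(scale=0.5, size=300)
        _, rho = assoc.cca_1d(X, y)
        r_mean = abs(np.corrcoef(X.mean(axis=1), y)[0, 1])
        assert rho >= r_mean - 1e-12

    def test_rho_squared_equals_regression_r2(self):
        # independent oracle: R^2 of the least-squares fit of y on the bins
        rng = np.random.default_rng(30)
        X = rng.normal(size=(400, 14))
        y = X @ rng.normal(size=14) + rng.normal(size=400)
        _, rho = assoc.cca_1d(X, y)
        Xd = np.column_stack([np.ones(400), X])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ beta
        r2 = 1 - resid.var() / y.var()
        assert rho**2 == pytest.approx(r2, abs=1e-10)

    def test_unit_variance_canonical_variate(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(300, 14))
        y = X @ rng.normal(size=14) + rng.normal(size=300)
        a, _ = assoc.cca_1d(X, y)
        variate = (X - X.mean(0)) @ a
        assert variate.var(ddof=1) == pytest.approx(1.0, rel=1e-9)


class TestShrinkagePcor:
    def test_matches_direct_inversion_with_zero_shrinkage(self):
        # closed-form oracle: partial correlations from the inverse covariance
        rng = np.random.default_rng(32)
        cov = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=4000)
        res = assoc.shrinkage_pcor(X, shrinkage=0.0)
        S = np.corrcoef(X, rowvar=False)
        omega = np.linalg.inv(S)
        d = np.sqrt(np.diag(omega))
        expected = -omega / np.outer(d, d)
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(res.pcor, expected, atol=1e-6)

    def test_iid_null_pcors_small(self):
        rng = np.random.default_rng(33)
        X = rng.normal(size=(5000, 10))
        res = assoc.shrinkage_pcor(X)
        off = res.pcor[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_ar1_chain_adjacency_dominates(self):
        # brute-force oracle: the generating precision matrix is tridiagonal
        rng = np.random.default_rng(34)
        n, p, phi = 5000, 12, 0.7
        X = np.zeros((n, p))
        X[:, 0] = rng.normal(size=n)
        for k in range(1, p):
            X[:, k] = phi * X[:, k - 1] + rng.normal(size=n)
        res = assoc.shrinkage_pcor(X)
        adj = np.abs(np.diag(res.pcor, k=1))
        non_adj = np.abs(res.pcor[np.triu_indices(p, k=2)])
        assert adj.min() > 0.3
        assert non_adj.max() < 0.1

    def test_underdetermined_without_shrinkage_rejected(self):
        X = np.random.default_rng(35).normal(size=(10, 20))
        with pytest.raises(ValueError, match="shrinkage"):
            assoc.shrinkage_pcor(X, shrinkage=0.0)

    def test_symmetric_unit_diagonal(self):
        X = np.random.default_rng(36).normal(size=(100, 8))
        res = assoc.shrinkage_pcor(X)
        assert np.allclose(res.pcor, res.pcor.T)
        assert np.allclose(np.diag(res.pcor), 1.0)
        assert np.all(np.abs(res.pcor) <= 1 + 1e-12)


class TestPcorEdges:
    def test_near_zero_pcors_give_empty_graph(self):
        rng = np.random.default_rng(37)
        X = rng.normal(size=(500, 8))
        res = assoc.shrinkage_pcor(X)
        edges = assoc.pcor_edges(res, significance_cutoff=0.01)
        assert len(edges) <= 1  # essentially nothing survives BH

    def test_ar1_edge_recovery(self):
        rng = np.random.default_rng(38)
        n, p, phi = 5000, 12, 0.7
        X = np.zeros((n, p))
        X[:, 0] = rng.normal(size=n)
        for k in range(1, p):
            X[:, k] = phi * X[:, k - 1] + rng.normal(size=n)
        res = assoc.shrinkage_pcor(X)
        edges = assoc.pcor_edges(res, significance_cutoff=0.05)
        found = {tuple(sorted((a, b))) for a, b in zip(edges.var_a, edges.var_b)}
        truth = {(f"v{k}", f"v{k + 1}") for k in range(p - 1)}
        tp = len(found & truth)
        precision = tp / max(len(found), 1)
        recall = tp / len(truth)
        assert precision >= 0.9
        assert recall >= 0.9

    def test_lowering_cutoff_never_adds_edges(self):
        rng = np.random.default_rng(39)
        X = rng.normal(size=(300, 6)) @ rng.normal(size=(6, 6))
        res = assoc.shrinkage_pcor(X)
        loose = assoc.pcor_edges(res, significance_cutoff=0.2)
        tight = assoc.pcor_edges(res, significance_cutoff=0.01)
        pairs = lambda e: {(a, b) for a, b in zip(e.var_a, e.var_b)}
        assert pairs(tight) <= pairs(loose)

    def test_graph_object(self):
        rng = np.random.default_rng(40)
        X = np.zeros((2000, 3))
        X[:, 0] = rng.normal(size=2000)
        X[:, 1] = 0.8 * X[:, 0] + rng.normal(size=2000)
        X[:, 2] = rng.normal(size=2000)
        edges = assoc.pcor_edges(assoc.shrinkage_pcor(X))
        g = assoc.edge_graph(edges)
        assert g.has_edge("v0", "v1")
        assert not g.has_edge("v0", "v2")


class TestGroupDifference:
    def test_identical_groups_zero_matrix(self):
        X = np.random.default_rng(41).normal(size=(200, 5))
        res = assoc.shrinkage_pcor(X)
        diff = assoc.group_difference(res, res)
        assert np.allclose(diff.to_numpy(), 0)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(42)
        a = assoc.shrinkage_pcor(rng.normal(size=(200, 5)))
        b = assoc.shrinkage_pcor(rng.normal(size=(200, 5)))
        d1 = assoc.group_difference(a, b).to_numpy()
        d2 = assoc.group_difference(b, a).to_numpy()
        assert np.allclose(d1, -d2)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(43)
        a = assoc.shrinkage_pcor(rng.normal(size=(100, 4)))
        b = assoc.shrinkage_pcor(
            pd.DataFrame(rng.normal(size=(100, 4)), columns=list("wxyz")))
        with pytest.raises(ValueError, match="labels"):
            assoc.group_difference(a, b)


class TestStackProfiles:
    def test_labels_and_shape(self, small_changes):
        stacked = assoc.stack_profiles(small_changes)
        assert stacked.shape[1] == 14 * len(small_changes.days)
        assert stacked.columns[0] == f"d{small_changes.days[0]}_b01"

    def test_increasing_diagonal_on_simulated_data(self, small_changes):
        rep = assoc.correlation_matrix(small_changes)
        diag = np.diag(rep.matrix.to_numpy(dtype=float))
        n = len(small_changes.expr)
        tol = 2 / np.sqrt(n)
        assert all(b >= a - tol for a, b in zip(diag, diag[1:]))
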