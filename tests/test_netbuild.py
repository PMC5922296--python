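import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import modscape as msc
from modscape.netbuild import _scale_free_r2


def _manual_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den


class TestCorrelation:
    def test_matches_manual_pearson(self):
        x = np.array([[1.0, 2.0, 4.0, 3.0], [2.0, 1.0, 5.0, 2.0], [9.0, 7.0, 2.0, 1.0]])
        expr = msc.ExpressionDataset(x, ["a", "b", "c"], list("wxyz"))
        r = msc.correlation_matrix(expr)
        for i in range(3):
            for j in range(3):
                expected = 1.0 if i == j else _manual_pearson(x[i], x[j])
                assert abs(r[i, j] - expected) < 1e-12

    def test_identical_and_negated_profiles(self):
        base = np.array([1.0, 2.0, 3.0, 5.0])
        x = np.vstack([base, base, -base])
        r = msc.correlation_matrix(msc.ExpressionDataset(x, ["a", "b", "c"], list("wxyz")))
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_gene_named(self):
        x = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="flat"):
            msc.correlation_matrix(msc.ExpressionDataset(x, ["flat", "ok"], list("abc")))


class TestAdjacency:
    def test_soft_threshold_values(self):
        corr = np.array([[1.0, 0.5, -0.5], [0.5, 1.0, 1.0], [-0.5, 1.0, 1.0]])
        a_u = msc.adjacency(corr, 6, "unsigned")
        a_s = msc.adjacency(corr, 6, "signed_hybrid")
        assert a_u[0, 1] == pytest.approx(0.5**6)   # 0.015625
        assert a_u[0, 2] == pytest.approx(0.5**6)
        assert a_s[0, 2] == 0.0                     # negative r clipped
        assert a_s[1, 2] == pytest.approx(1.0)
        assert np.all(np.diag(a_u) == 0)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            msc.adjacency(np.eye(2), 6, "signed")


class TestTopologicalOverlap:
    def test_fully_connected_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = msc.topological_overlap(a)
        # (1 + 1) / (2 + 1 - 1) = 1 off-diagonal
        assert np.allclose(tom, 1.0)

    def test_isolated_nodes(self):
        tom = msc.topological_overlap(np.zeros((2, 2)))
        assert tom[0, 1] == 0.0 and tom[0, 0] == 1.0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(42)
        r = np.clip(rng.uniform(-1, 1, size=(20, 20)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        a = msc.adjacency(r, 3, "unsigned")
        tom = msc.topological_overlap(a)
        k = a.sum(axis=0)
        for i in range(20):
            for j in range(20):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(20))
                expected = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert abs(tom[i, j] - expected) < 1e-12

    def test_symmetric_unit_interval(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((30, 10))
        expr = msc.ExpressionDataset(x, [f"g{i}" for i in range(30)], [f"s{j}" for j in range(10)])
        tom = msc.topological_overlap(msc.adjacency(msc.correlation_matrix(expr), 6, "signed_hybrid"))
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestSoftPower:
    def test_single_candidate(self, small_expr):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = msc.pick_soft_power(small_expr, candidates=[6])
        assert scan.chosen_power == 6

    def test_fallback_when_threshold_unmet(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((300, 30))
        expr = msc.ExpressionDataset(x, [f"g{i}" for i in range(300)], [f"s{j}" for j in range(30)])
        with pytest.warns(UserWarning, match="falling back"):
            scan = msc.pick_soft_power(expr, candidates=[1])  # power 1 never scale-free here
        assert scan.chosen_power == 6 and not scan.threshold_met
        assert scan.table["r_squared"].between(0, 1).all()

    def test_planted_data_meets_threshold_with_smallest_power(self):
        data = msc.generate(msc.standard_scenarios()["trait_calibration"])
        scan = msc.pick_soft_power(data.expr)
        assert scan.threshold_met
        passing = scan.table[scan.table.r_squared >= scan.r2_threshold]
        assert scan.chosen_power == int(passing["power"].iloc[0])


class TestEigengenes:
    def test_copies_of_one_profile(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal(10)
        x = np.vstack([f, f, f]) + 8
        expr = msc.ExpressionDataset(x, ["a", "b", "c"], [f"s{j}" for j in range(10)])
        eig = msc.module_eigengenes(expr, pd.Series([1, 1, 1], index=["a", "b", "c"]))
        r = np.corrcoef(eig.loc[1], f)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10
        assert eig.loc[1].std(ddof=1) == pytest.approx(1.0)
        assert eig.loc[1].mean() == pytest.approx(0.0, abs=1e-12)

    def test_orientation_mean_kme_positive(self, mini_data, mini_modules):
        for mid in mini_modules.module_ids:
            members = mini_modules.members(mid)
            assert mini_modules.kme.loc[members, mid].mean() > 0

    def test_balanced_pair_tie_broken_by_first_gene(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal(12)
        x = np.vstack([f, -f]) + 8
        expr = msc.ExpressionDataset(x, ["aaa", "bbb"], [f"s{j}" for j in range(12)])
        eig = msc.module_eigengenes(expr, pd.Series([1, 1], index=["aaa", "bbb"]))
        # orientation follows the lexicographically first member, "aaa"
        assert np.corrcoef(eig.loc[1], f)[0, 1] > 0

    def test_eigengene_tracks_latent_factor(self, mini_data):
        eig = msc.module_eigengenes(mini_data.expr, mini_data.truth.assignments)
        for mid in [1, 2, 3]:
            r = np.corrcoef(eig.loc[mid], mini_data.truth.factors.loc[mid])[0, 1]
            assert r >= 0.95


class TestKme:
    def test_gene_equal_to_eigengene(self):
        rng = np.random.default_rng(4)
        f = rng.standard_normal(10)
        x = np.vstack([f, f + 0.05 * rng.standard_normal(10), rng.standard_normal(10)]) + 8
        expr = msc.ExpressionDataset(x, ["a", "b", "c"], [f"s{j}" for j in range(10)])
        eig = msc.module_eigengenes(expr, pd.Series([1, 1, 0], index=["a", "b", "c"]))
        kme_r, kme_p, kme_q = msc.kme(expr, eig)
        assert kme_r.loc["a", 1] > 0.99
        assert kme_p.loc["a", 1] < 1e-6
        assert (kme_q.loc[:, 1] >= kme_p.loc[:, 1] - 1e-15).all()

    def test_p_matches_t_reference(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((5, 12)) + 8
        expr = msc.ExpressionDataset(x, [f"g{i}" for i in range(5)], [f"s{j}" for j in range(12)])
        eig = msc.module_eigengenes(expr, pd.Series([1] * 5, index=expr.gene_ids))
        kme_r, kme_p, _ = msc.kme(expr, eig)
        for g in expr.gene_ids:
            r_val, p_ref = stats.pearsonr(x[expr.gene_ids.index(g)], eig.loc[1])
            assert kme_r.loc[g, 1] == pytest.approx(r_val, abs=1e-10)
            assert kme_p.loc[g, 1] == pytest.approx(p_ref, abs=1e-10)

    def test_too_few_samples(self):
        expr = msc.ExpressionDataset(np.array([[1.0, 2.0], [2.0, 1.0]]), ["a", "b"], ["s1", "s2"])
        with pytest.raises(ValueError):
            msc.kme(expr, pd.DataFrame([[1.0, -1.0]], index=[1], columns=["s1", "s2"]))


class TestDetectModules:
    def test_recovers_planted_modules(self, recovery_detection):
        data, ms = recovery_detection
        from modscape.benchmark import adjusted_rand_index
        ari = adjusted_rand_index(data.truth.assignments.to_numpy(), ms.assignments.to_numpy())
        assert ari >= 0.9
        assert list(ms.module_sizes.index) == sorted(ms.module_sizes.index)
        assert ms.module_sizes.is_monotonic_decreasing
        assert (ms.module_sizes >= 30).all()

    def test_noise_leaves_genes_unassigned(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((1000, 60)) + 8
        expr = msc.ExpressionDataset(x, [f"g{i}" for i in range(1000)], [f"s{j}" for j in range(60)])
        ms = msc.detect_modules(expr, power=6)
        assert (ms.assignments == 0).mean() >= 0.95

    def test_highly_correlated_modules_merge(self):
        rng = np.random.default_rng(6)
        n = 60
        f1 = rng.standard_normal(n)
        f2 = 0.95 * f1 + np.sqrt(1 - 0.95**2) * rng.standard_normal(n)
        lam = 0.9
        block = lambda f, size: lam * f[None, :] + np.sqrt(1 - lam**2) * rng.standard_normal((size, n))
        x = np.vstack([block(f1, 40), block(f2, 40), rng.standard_normal((120, n))]) + 8
        expr = msc.ExpressionDataset(x, [f"g{i}" for i in range(200)], [f"s{j}" for j in range(n)])
        ms = msc.detect_modules(expr, power=6, min_size=20, merge_threshold=0.25)
        planted = ms.assignments.iloc[:80]
        modules_used = planted[planted > 0].unique()
        assert len(modules_used) == 1

    def test_sample_permutation_invariance(self, mini_data):
        expr = mini_data.expr
        ms1 = msc.detect_modules(expr, power=6)
        perm = np.random.default_rng(0).permutation(expr.n_samples)
        shuffled = msc.ExpressionDataset(expr.values[:, perm], expr.gene_ids,
                                         [expr.sample_ids[i] for i in perm])
        ms2 = msc.detect_modules(shuffled, power=6)
        assert ms1.assignments.equals(ms2.assignments)

    def test_fewer_genes_than_min_size_warns(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((10, 12)) + 8
        expr = msc.ExpressionDataset(x, [f"g{i}" for i in range(10)], [f"s{j}" for j in range(12)])
        with pytest.warns(UserWarning, match="min_size"):
            ms = msc.detect_modules(expr, power=6, min_size=30)
        assert (ms.assignments == 0).all()


class TestDriversAndExport:
    def test_driver_ranking_tracks_loadings(self, mini_data, mini_modules):
        drivers = msc.driver_genes(mini_modules, 1, n=10)
        lam = mini_data.truth.loadings
        members = mini_modules.members(1)
        ranked_kme = mini_modules.kme.loc[members, 1]
        rho = stats.spearmanr(ranked_kme, lam.loc[members]).statistic
        assert rho >= 0.8
        assert drivers[0] == ranked_kme.idxmax()

    def test_driver_contracts(self, mini_modules):
        with pytest.raises(KeyError):
            msc.driver_genes(mini_modules, 99)
        with pytest.raises(ValueError):
            msc.driver_genes(mini_modules, 3, n=10_000)

    def test_subnetwork_tables_consistent(self, mini_data, mini_modules):
        corr = msc.correlation_matrix(mini_data.expr)
        tom = pd.DataFrame(msc.topological_overlap(msc.adjacency(corr, 6, "signed_hybrid")),
                           index=mini_data.expr.gene_ids, columns=mini_data.expr.gene_ids)
        nodes, edges = msc.export_subnetwork(mini_modules, tom, 1, top_n=10)
        assert len(nodes) == 10 and len(edges) == 45  # C(10, 2)
        for _, row in nodes.iterrows():
            assert row["kme"] == mini_modules.kme.loc[row["gene"], 1]
        for _, e in edges.head(5).iterrows():
            assert e["tom"] == pytest.approx(tom.loc[e["gene_i"], e["gene_j"]])
            assert e["tom"] == pytest.approx(tom.loc[e["gene_j"], e["gene_i"]])

    def test_subnetwork_small_module_warns(self, mini_data, mini_modules):
        corr = msc.correlation_matrix(mini_data.expr)
        tom = msc.topological_overlap(msc.adjacency(corr, 6, "signed_hybrid"))
        with pytest.warns(UserWarning, match="exporting all"):
            nodes, _ = msc.export_subnetwork(mini_modules, tom, 3, top_n=100)
        assert len(nodes) == mini_modules.module_sizes[3]
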