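import itertools

import numpy as np
import pandas as pd
import pytest

import modscape as msc


class TestHypergeomOverlap:
    def test_exact_enumeration_small_case(self):
        # N=10, |A|=5, |B|=4, overlap 4: p = C(5,4)*C(5,0)/C(10,4) = 5/210
        universe = [f"u{i}" for i in range(10)]
        set_a = universe[:5]
        set_b = universe[:4]
        res = msc.hypergeom_overlap(set_a, set_b, universe)
        assert res.k == 4
        assert res.p == pytest.approx(5 / 210, abs=1e-12)
        # full enumeration over all C(10,4) draws of B
        count = sum(1 for draw in itertools.combinations(universe, 4)
                    if len(set(draw) & set(set_a)) >= 4)
        assert res.p == pytest.approx(count / 210, abs=1e-12)

    def test_disjoint_sets_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        res = msc.hypergeom_overlap(universe[:3], universe[5:8], universe)
        assert res.k == 0 and res.p == 1.0

    def test_identical_maximal_sets(self):
        universe = [f"u{i}" for i in range(6)]
        res = msc.hypergeom_overlap(universe, universe, universe)
        assert res.k == 6 and res.p == pytest.approx(1.0)

    def test_symmetry_and_universe_clipping(self):
        universe = [f"u{i}" for i in range(12)]
        a = universe[:6] + ["outside1"]
        b = universe[3:9] + ["outside2"]
        r1 = msc.hypergeom_overlap(a, b, universe)
        r2 = msc.hypergeom_overlap(b, a, universe)
        assert r1.p == r2.p and r1.k == r2.k == 3
        assert r1.dropped_a == 1 and r1.dropped_b == 1

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            msc.hypergeom_overlap(["a"], ["a"], [])


def _ranked(n=100, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.standard_normal(n))[::-1] * 2
    return pd.Series(scores, index=[f"g{i:03d}" for i in range(n)])


def _es_loop(scores, order, members, weight):
    """Independent O(n) running-sum oracle."""
    hits = [g in set(members) for g in order]
    n, nh = len(order), sum(hits)
    if nh == n:
        return 1.0
    denom = sum(abs(scores[g]) ** weight for g, h in zip(order, hits) if h)
    run, best = 0.0, 0.0
    for g, h in zip(order, hits):
        run += (abs(scores[g]) ** weight / denom) if h else -1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


class TestGseaPreranked:
    def test_top_genes_strongly_enriched(self):
        scores = _ranked()
        res = msc.gsea_preranked(scores, list(scores.index[:5]), n_perm=200, seed=1)
        assert res.es > 0.9
        assert res.nes > 1.0
        assert res.p <= 0.05

    def test_whole_list_degenerate_convention(self):
        scores = _ranked(20)
        res = msc.gsea_preranked(scores, list(scores.index), n_perm=50, seed=0)
        assert res.es == 1.0

    def test_es_matches_running_sum_oracle(self):
        rng = np.random.default_rng(7)
        scores = _ranked(60, seed=7)
        order = list(scores.index)
        for _ in range(10):
            members = list(rng.choice(order, size=int(rng.integers(3, 20)), replace=False))
            res = msc.gsea_preranked(scores, members, weight=1.0, n_perm=5, seed=0)
            assert res.es == pytest.approx(_es_loop(scores, order, members, 1.0), abs=1e-12)

    def test_weight_zero_invariant_to_monotone_transform(self):
        scores = _ranked(50, seed=3)
        members = list(scores.index[10:18])
        res1 = msc.gsea_preranked(scores, members, weight=0.0, n_perm=20, seed=4)
        transformed = pd.Series(np.exp(scores.to_numpy() / 3), index=scores.index)
        res2 = msc.gsea_preranked(transformed, members, weight=0.0, n_perm=20, seed=4)
        assert res1.es == pytest.approx(res2.es, abs=1e-12)

    def test_disjoint_set_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            msc.gsea_preranked(_ranked(20), ["nope"], n_perm=10, seed=0)

    def test_fixed_seed_reproducible(self):
        scores = _ranked(80, seed=5)
        members = list(scores.index[:10])
        r1 = msc.gsea_preranked(scores, members, n_perm=100, seed=6)
        r2 = msc.gsea_preranked(scores, members, n_perm=100, seed=6)
        assert (r1.es, r1.nes, r1.p, r1.q) == (r2.es, r2.nes, r2.p, r2.q)


class TestSsgsea:
    def _expr(self, seed=0, n=20, s=3):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, s)) + 8
        return msc.ExpressionDataset(x, [f"g{i:02d}" for i in range(n)],
                                     [f"s{j}" for j in range(s)])

    def test_identical_samples_identical_scores(self):
        expr = self._expr()
        col = expr.values[:, 0]
        expr_same = msc.ExpressionDataset(np.column_stack([col, col]),
                                          expr.gene_ids, ["a", "b"])
        sets = msc.GeneSetCollection({"s1": expr.gene_ids[:5], "s2": expr.gene_ids[8:14]})
        scores = msc.ssgsea(expr_same, sets)
        assert np.allclose(scores.loc["a"], scores.loc["b"])

    def test_top_set_outscores_bottom_set(self):
        expr = self._expr(seed=2, s=1)
        order = np.argsort(-expr.values[:, 0])
        top = [expr.gene_ids[i] for i in order[:5]]
        bottom = [expr.gene_ids[i] for i in order[-5:]]
        scores = msc.ssgsea(expr, msc.GeneSetCollection({"top": top, "bottom": bottom}))
        assert scores.iloc[0]["top"] > scores.iloc[0]["bottom"]

    def test_shift_invariance_per_sample(self):
        expr = self._expr(seed=4)
        shifted = msc.ExpressionDataset(expr.values + np.array([1.0, -2.0, 0.5]),
                                        expr.gene_ids, expr.sample_ids)
        sets = msc.GeneSetCollection({"s": expr.gene_ids[3:9]})
        s1 = msc.ssgsea(expr, sets, normalize=False)
        s2 = msc.ssgsea(shifted, sets, normalize=False)
        assert np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_matches_per_rank_oracle(self):
        expr = self._expr(seed=6, n=20, s=2)
        sets = msc.GeneSetCollection({"A": expr.gene_ids[:6], "B": expr.gene_ids[10:17]})
        scores = msc.ssgsea(expr, sets, alpha=0.25, normalize=False)
        n = expr.n_genes
        for sj, sample in enumerate(expr.sample_ids):
            col = expr.values[:, sj]
            order = sorted(range(n), key=lambda i: (-col[i], expr.gene_ids[i]))
            for name, members in sets.sets.items():
                hit = [expr.gene_ids[i] in set(members) for i in order]
                nh = sum(hit)
                hw = [(n - j) ** 0.25 if hit[j] else 0.0 for j in range(n)]
                tot = sum(hw)
                es = cum_h = cum_m = 0.0
                for j in range(n):
                    cum_h += hw[j] / tot
                    cum_m += (0.0 if hit[j] else 1.0) / (n - nh)
                    es += cum_h - cum_m
                assert scores.loc[sample, name] == pytest.approx(es, abs=1e-12)

    def test_missing_set_rejected(self):
        expr = self._expr()
        with pytest.raises(ValueError, match="no genes"):
            msc.ssgsea(expr, msc.GeneSetCollection({"s": ["absent"]}))


class TestModuleConservation:
    @pytest.fixture(scope="class")
    @staticmethod
    def two_species():
        data = msc.generate(msc.standard_scenarios()["two_species"])
        # "human" ranking: epidermis-vs-blood mean difference in the second
        # dataset, gene symbols upper-cased
        t = data.design2.table
        epi = [i for i, s in enumerate(data.expr2.sample_ids) if t.loc[s, "tissue"] == "epidermis"]
        blood = [i for i, s in enumerate(data.expr2.sample_ids) if t.loc[s, "tissue"] == "blood"]
        diff = data.expr2.values[:, epi].mean(axis=1) - data.expr2.values[:, blood].mean(axis=1)
        ranked = pd.Series(diff, index=[g.upper() for g in data.expr2.gene_ids])
        modules = msc.GeneSetCollection({
            f"M{m}": list(data.truth.assignments.index[data.truth.assignments == m])
            for m in range(1, 7)})
        return data, ranked, modules

    def test_conserved_epidermis_module_enriched(self, two_species):
        data, ranked, modules = two_species
        mapping = {g: g.upper() for g in data.expr.gene_ids}
        res = msc.module_conservation_test(modules, ranked, mapping, n_perm=200, seed=0)
        # module 5 is the epidermis-linked one; it must surface at the top
        assert res.loc["M5", "nes"] > 0
        assert res.loc["M5", "q"] < 0.25

    def test_scrambled_mapping_is_negative_control(self, two_species):
        data, ranked, modules = two_species
        rng = np.random.default_rng(8)
        genes = list(data.expr.gene_ids)
        shuffled = rng.permutation(genes)
        mapping = {g: s.upper() for g, s in zip(genes, shuffled)}
        res = msc.module_conservation_test(modules, ranked, mapping, n_perm=200, seed=0)
        # the conserved-module signal disappears: the epidermis module no longer
        # stands out and enrichment magnitudes sit near the null scale
        assert res.loc["M5", "q"] > 0.25
        assert res["q"].median() > 0.25
        assert abs(res["nes"]).median() < 1.5

    def test_empty_mapping_skips_everything(self, two_species):
        _, ranked, modules = two_species
        with pytest.warns(UserWarning) as record:
            res = msc.module_conservation_test(modules, ranked, {"x": "Y"}, n_perm=10, seed=0)
        assert res.empty
        assert len(record) == len(modules.sets)
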