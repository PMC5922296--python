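"""End-to-end benchmark routines on the standard synthetic scenarios.

Each function regenerates its inputs from the named preset (reseeded from a
master seed), runs the corresponding pipeline stage and measures a summary
quantity: module-recovery ARI, module-trait detection power and null
calibration, preservation Z behavior, modDE calibration/discrimination,
oracle agreement for the closed-form primitives, MDS geometry and
determinism.  The problem sizes are the presets' study conditions scaled to
single-workstation runtimes; tests and the reproduction script both call
these routines so that reported numbers always come from a fresh run of the
package itself.
"""
from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionDataset, GeneSetCollection
from .enrichment import gsea_preranked, hypergeom_overlap, ssgsea
from .modde import modde
from .netbuild import adjacency, correlation_matrix, detect_modules, kme, module_eigengenes, topological_overlap
from .preservation import module_preservation
from .synthdata import SynthConfig, generate, standard_scenarios
from .traitmap import binary_traits, classical_mds, module_trait_matrix


def _child_seeds(master_seed: int, n: int, stream: int) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), int(stream)]))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _reseed(config: SynthConfig, seed: int) -> SynthConfig:
    return dataclasses.replace(config, seed=seed)


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index between two labelings."""
    from sklearn.metrics import adjusted_rand_score
    return float(adjusted_rand_score(labels_a, labels_b))


# ---------------------------------------------------------------------------
# module recovery


def recovery_ari(master_seed: int, n_seeds: int = 20) -> dict:
    """Mean ARI of detect_modules against planted truth on the recovery preset."""
    base = standard_scenarios()["recovery"]
    aris, counts = [], []
    for s in _child_seeds(master_seed, n_seeds, stream=1):
        data = generate(_reseed(base, s))
        ms = detect_modules(data.expr, power=6, mode="signed_hybrid")
        aris.append(adjusted_rand_index(data.truth.assignments.to_numpy(),
                                        ms.assignments.to_numpy()))
        counts.append(len(ms.module_ids))
    return {"mean_ari": float(np.mean(aris)), "aris": aris,
            "mean_module_count": float(np.mean(counts)), "n_seeds": n_seeds,
            "n_genes": base.n_genes, "n_samples": base.n_samples}


# ---------------------------------------------------------------------------
# module-trait calibration


def trait_power(master_seed: int, n_seeds: int = 50) -> dict:
    """Fraction of seeds where a planted tissue-linked module reaches -log10 p > 2."""
    base = standard_scenarios()["trait_calibration"]
    hits = 0
    for s in _child_seeds(master_seed, n_seeds, stream=2):
        data = generate(_reseed(base, s))
        eig = module_eigengenes(data.expr, data.truth.assignments)
        traits = binary_traits(data.design)
        mt = module_trait_matrix(eig, traits)
        # module 5 of the preset is the epidermis-linked one
        if mt.neglogp.loc[5, "tissue:epidermis"] > 2.0:
            hits += 1
    return {"detection_rate": hits / n_seeds, "n_seeds": n_seeds,
            "effect": 2.0, "n_samples": base.n_samples}


def trait_null_uniformity(master_seed: int, n_seeds: int = 30) -> dict:
    """KS uniformity of pooled module-trait p-values under zero trait effect."""
    base = standard_scenarios()["trait_null"]
    pooled = []
    for s in _child_seeds(master_seed, n_seeds, stream=3):
        data = generate(_reseed(base, s))
        eig = module_eigengenes(data.expr, data.truth.assignments)
        traits = binary_traits(data.design)
        mt = module_trait_matrix(eig, traits)
        pooled.append(mt.p.to_numpy().ravel())
    pooled_arr = np.concatenate(pooled)
    ks = stats.kstest(pooled_arr, "uniform")
    return {"ks_p": float(ks.pvalue), "n_pvalues": int(pooled_arr.size), "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# preservation


def preservation_behavior(master_seed: int, n_seeds: int = 20, n_perm: int = 200) -> dict:
    """Self-preservation Z and scrambled-module Z across reseeded preset runs.

    Self-preservation (dataset against itself) is measured once; the
    scrambled/preserved split in the independent second dataset is measured
    per seed.
    """
    base = standard_scenarios()["preservation"]
    seeds = _child_seeds(master_seed, n_seeds, stream=4)

    data0 = generate(_reseed(base, seeds[0]))
    truth_ms = _truth_moduleset(data0.expr, data0.truth.assignments)
    self_res = module_preservation(data0.expr, data0.expr, truth_ms, n_perm=n_perm, seed=seeds[0])
    self_min_z = float(self_res.z_summary.min())

    scrambled_z, preserved_z = [], []
    for s in seeds:
        data = generate(_reseed(base, s))
        ms = _truth_moduleset(data.expr, data.truth.assignments)
        res = module_preservation(data.expr, data.expr2, ms, n_perm=n_perm, seed=s)
        for mid, keep in data.truth.preserved.items():
            z = float(res.z_summary.loc[mid])
            (preserved_z if keep else scrambled_z).append(z)
    scrambled_arr = np.asarray(scrambled_z)
    return {"self_min_z_summary": self_min_z,
            "scrambled_below_2_rate": float((scrambled_arr < 2.0).mean()),
            "scrambled_median_z": float(np.median(scrambled_arr)),
            "preserved_median_z": float(np.median(preserved_z)),
            "n_seeds": n_seeds, "n_perm": n_perm}


def _truth_moduleset(expr: ExpressionDataset, assignments: pd.Series):
    """Build a ModuleSet from known assignments (eigengenes + kME computed)."""
    from .netbuild import ModuleSet
    eig = module_eigengenes(expr, assignments)
    kme_r, kme_p, kme_q = kme(expr, eig)
    sizes = assignments[assignments > 0].value_counts().sort_index()
    return ModuleSet(assignments, eig, kme_r, kme_p, kme_q, sizes, {})


# ---------------------------------------------------------------------------
# modDE


def modde_null_calibration(master_seed: int, n_seeds: int = 50, n_perm: int = 399) -> dict:
    """Type-I error and p uniformity of the modDE consistency test under the null."""
    base = standard_scenarios()["modde_null"]
    pvals = []
    for s in _child_seeds(master_seed, n_seeds, stream=5):
        data = generate(_reseed(base, s))
        # modules and kME are defined on the unperturbed reference experiment
        ms = _truth_moduleset(data.expr2, data.truth.assignments)
        res = modde(ms, data.expr, data.design, ("control", "perturbed"),
                    n_perm=n_perm, seed=s)
        pvals.append(res.table["p_consistency"].to_numpy())
    p = np.concatenate(pvals)
    ks = stats.kstest(p, "uniform")
    return {"type1_at_005": float((p <= 0.05).mean()), "ks_p": float(ks.pvalue),
            "n_tests": int(p.size), "n_perm": n_perm}


def modde_discrimination(master_seed: int, n_perm_coherent: int = 10000,
                         n_seeds_incoherent: int = 20, n_perm_incoherent: int = 999) -> dict:
    """Coherent vs incoherent perturbation: the defining modDE separation.

    The coherent latent shift must be called significant by the consistency
    test; the magnitude-matched random-direction shift must not, while still
    showing an excess of DE genes.
    """
    scen = standard_scenarios()
    seeds = _child_seeds(master_seed, n_seeds_incoherent, stream=6)

    data = generate(_reseed(scen["modde_coherent"], seeds[0]))
    ms = _truth_moduleset(data.expr2, data.truth.assignments)
    res = modde(ms, data.expr, data.design, ("control", "perturbed"),
                n_perm=n_perm_coherent, seed=seeds[0])
    coherent_p = float(res.table.loc[1, "p_consistency"])
    coherent_excess_p = float(res.table.loc[1, "p_excess"])

    inc_p, inc_excess = [], []
    for s in seeds:
        d = generate(_reseed(scen["modde_incoherent"], s))
        m = _truth_moduleset(d.expr2, d.truth.assignments)
        r = modde(m, d.expr, d.design, ("control", "perturbed"),
                  n_perm=n_perm_incoherent, seed=s)
        inc_p.append(float(r.table.loc[1, "p_consistency"]))
        inc_excess.append(float(r.table.loc[1, "p_excess"]))
    return {"coherent_p": coherent_p, "coherent_excess_p": coherent_excess_p,
            "incoherent_median_p": float(np.median(inc_p)),
            "incoherent_median_excess_p": float(np.median(inc_excess)),
            "n_perm_coherent": n_perm_coherent, "n_seeds_incoherent": n_seeds_incoherent}


# ---------------------------------------------------------------------------
# oracle equivalence


def tom_oracle_error(master_seed: int, n_genes: int = 40, n_samples: int = 12) -> dict:
    """Max |TOM - brute-force triple-loop oracle| on a random instance."""
    rng = np.random.default_rng(master_seed)
    x = rng.standard_normal((n_genes, n_samples))
    expr = ExpressionDataset(x, [f"g{i}" for i in range(n_genes)],
                             [f"s{j}" for j in range(n_samples)])
    adj = adjacency(correlation_matrix(expr), 6, "signed_hybrid")
    tom = topological_overlap(adj)
    k = adj.sum(axis=0)
    err = 0.0
    for i in range(n_genes):
        for j in range(n_genes):
            if i == j:
                expected = 1.0
            else:
                shared = sum(adj[i, u] * adj[u, j] for u in range(n_genes))
                expected = (shared + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
            err = max(err, abs(tom[i, j] - expected))
    return {"max_abs_error": float(err), "n_genes": n_genes}


def hypergeom_oracle_error(max_universe: int = 15) -> dict:
    """Max |p - exhaustive enumeration| over all universes N <= max_universe.

    The oracle enumerates every subset of the universe by bitmask and counts
    draws whose overlap with a fixed reference set reaches each threshold.
    """
    err = 0.0
    n_checked = 0
    for n_universe in range(1, max_universe + 1):
        universe = [f"u{i}" for i in range(n_universe)]
        masks = np.arange(1 << n_universe, dtype=np.int64)
        popcount = np.array([bin(m).count("1") for m in masks])
        for size_a in range(n_universe + 1):
            amask = (1 << size_a) - 1
            overlap = np.array([bin(m & amask).count("1") for m in masks])
            for size_b in range(n_universe + 1):
                draws = popcount == size_b
                n_draws = int(draws.sum())
                set_a = universe[:size_a]
                for k in range(min(size_a, size_b) + 1):
                    oracle = float((overlap[draws] >= k).sum()) / n_draws
                    # realize an actual overlap of exactly k to exercise the API
                    set_b = universe[:k] + universe[size_a:size_a + size_b - k]
                    if len(set_b) != size_b:
                        continue
                    res = hypergeom_overlap(set_a, set_b, universe)
                    assert res.k == k
                    err = max(err, abs(res.p - oracle))
                    n_checked += 1
    return {"max_abs_error": float(err), "n_checked": n_checked}


def _es_oracle(scores: np.ndarray, hits: np.ndarray, weight: float) -> float:
    """Independent step-by-step running-sum ES (plain Python loop)."""
    n = len(scores)
    nh = int(hits.sum())
    if nh == n:
        return 1.0
    denom = sum(abs(scores[i]) ** weight for i in range(n) if hits[i])
    running, best = 0.0, 0.0
    for i in range(n):
        if hits[i]:
            running += (abs(scores[i]) ** weight / denom) if denom > 0 else 1.0 / nh
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


def gsea_oracle_error(master_seed: int, n_cases: int = 25, list_size: int = 60) -> dict:
    """Max |ES - independent running-sum oracle| over random preranked cases."""
    rng = np.random.default_rng(master_seed)
    err = 0.0
    for _ in range(n_cases):
        scores = pd.Series(np.sort(rng.standard_normal(list_size))[::-1],
                           index=[f"g{i}" for i in range(list_size)])
        size = int(rng.integers(3, 15))
        members = list(rng.choice(scores.index, size=size, replace=False))
        res = gsea_preranked(scores, members, weight=1.0, n_perm=10, seed=0)
        order = sorted(scores.index, key=lambda g: (-scores[g], g))
        hits = np.array([g in set(members) for g in order])
        oracle = _es_oracle(scores.loc[order].to_numpy(), hits, 1.0)
        err = max(err, abs(res.es - oracle))
    return {"max_abs_error": float(err), "n_cases": n_cases}


def ssgsea_oracle_error(master_seed: int, n_genes: int = 20, n_samples: int = 2) -> dict:
    """Max |ssGSEA score - per-rank summation oracle| on a small instance."""
    rng = np.random.default_rng(master_seed)
    x = rng.standard_normal((n_genes, n_samples)) + 8.0
    genes = [f"g{i:02d}" for i in range(n_genes)]
    expr = ExpressionDataset(x, genes, [f"s{j}" for j in range(n_samples)])
    sets = GeneSetCollection({"A": genes[:6], "B": genes[10:17]})
    scores = ssgsea(expr, sets, alpha=0.25, normalize=False)
    err = 0.0
    for s_idx, s in enumerate(expr.sample_ids):
        col = x[:, s_idx]
        order = sorted(range(n_genes), key=lambda i: (-col[i], genes[i]))
        for name, members in sets.sets.items():
            hit = [genes[i] in set(members) for i in order]
            nh = sum(hit)
            hw = [(n_genes - j) ** 0.25 if hit[j] else 0.0 for j in range(n_genes)]
            tot = sum(hw)
            es, cum_h, cum_m = 0.0, 0.0, 0.0
            for j in range(n_genes):
                cum_h += hw[j] / tot
                cum_m += (0 if hit[j] else 1) / (n_genes - nh)
                es += cum_h - cum_m
            err = max(err, abs(scores.loc[s, name] - es))
    return {"max_abs_error": float(err), "n_genes": n_genes}


# ---------------------------------------------------------------------------
# geometry and determinism


def mds_geometry_error(master_seed: int, n_points: int = 12, n_dims: int = 2) -> dict:
    """Max pairwise-distance discrepancy when embedding exactly planar points."""
    rng = np.random.default_rng(master_seed)
    pts = rng.standard_normal((n_points, n_dims)) * 3.0
    # expression whose top-variance Euclidean distances equal the planar ones
    x = np.zeros((50, n_points))
    x[:n_dims] = pts.T
    x[n_dims:] = 5.0
    x[n_dims:] += rng.standard_normal((50 - n_dims, 1)) * 1e-6  # break zero variance
    expr = ExpressionDataset(x + 8.0, [f"g{i}" for i in range(50)],
                             [f"s{j}" for j in range(n_points)])
    coords = classical_mds(expr, n_dims=n_dims, distance="euclidean_topvar", top_k=50)
    d_in = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    c = coords.to_numpy()
    d_out = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
    return {"max_abs_error": float(np.abs(d_in - d_out).max()), "n_points": n_points}


def determinism_check(master_seed: int) -> dict:
    """Bitwise reproducibility of seeded stages; reorder invariance of detection."""
    scen = standard_scenarios()
    cfg = dataclasses.replace(scen["preservation"], seed=master_seed % (2**31 - 1),
                              n_genes=700,
                              modules=scen["preservation"].modules[:3],
                              second_dataset=[True, False, True])
    d1, d2 = generate(cfg), generate(cfg)
    same_data = np.array_equal(d1.expr.values, d2.expr.values) and \
        np.array_equal(d1.expr2.values, d2.expr2.values)

    ms = _truth_moduleset(d1.expr, d1.truth.assignments)
    r1 = module_preservation(d1.expr, d1.expr2, ms, n_perm=50, seed=7)
    r2 = module_preservation(d1.expr, d1.expr2, ms, n_perm=50, seed=7)
    same_pres = r1.stats.equals(r2.stats)

    m1 = modde(ms, d1.expr, d1.design, ("syn", "allo"), n_perm=99, seed=7)
    m2 = modde(ms, d1.expr, d1.design, ("syn", "allo"), n_perm=99, seed=7)
    same_modde = m1.table.equals(m2.table)

    det1 = detect_modules(d1.expr, power=6)
    perm = np.random.default_rng(0).permutation(d1.expr.n_samples)
    shuffled = ExpressionDataset(d1.expr.values[:, perm],
                                 d1.expr.gene_ids,
                                 [d1.expr.sample_ids[i] for i in perm])
    det2 = detect_modules(shuffled, power=6)
    reorder_invariant = det1.assignments.equals(det2.assignments)

    ok = bool(same_data and same_pres and same_modde and reorder_invariant)
    return {"all_deterministic": ok, "seeded_reproducible": bool(same_data and same_pres and same_modde),
            "reorder_invariant": bool(reorder_invariant), "n_checks": 4}
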