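"""Cross-dataset module preservation via permutation Z statistics.

For each module defined in a reference dataset, two observed statistics are
computed in an independent test dataset: a density statistic (mean
intramodular adjacency among the module's genes in the test data) and a
connectivity statistic (Pearson correlation between the intramodular
connectivity vectors, kIM, computed in reference vs test data over shared
module genes).  A null distribution comes from random gene sets of identical
size drawn from the genes shared by both datasets, excluding the module
under test.  Z = (observed - null mean) / null sd, and
Z_summary = (Z_density + Z_connectivity) / 2.  The composite is a
two-component simplification of the classic median-based statistic family;
the 2 / 10 threshold semantics are kept: Z_summary < 2 not preserved,
>= 10 strongly preserved.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .dataio import ExpressionDataset
from .netbuild import ModuleSet, adjacency, correlation_matrix

WEAK_THRESHOLD = 2.0
STRONG_THRESHOLD = 10.0


@dataclasses.dataclass
class PreservationResult:
    """Per-module preservation statistics with permutation provenance."""

    stats: pd.DataFrame  # indexed by module id
    n_perm: int
    seed: int
    power: int
    mode: str

    @property
    def z_summary(self) -> pd.Series:
        return self.stats["z_summary"]


def _density(adj: np.ndarray, idx: np.ndarray) -> float:
    """Mean off-diagonal adjacency among the given genes (diag already 0)."""
    m = idx.size
    if m < 2:
        return float("nan")
    sub = adj[np.ix_(idx, idx)]
    return float(sub.sum() / (m * (m - 1)))


def _kim(adj: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Intramodular connectivity: row sums within the gene set."""
    return adj[np.ix_(idx, idx)].sum(axis=0)


def _kim_corr(adj_ref: np.ndarray, adj_test: np.ndarray, idx: np.ndarray) -> float:
    a = _kim(adj_ref, idx)
    b = _kim(adj_test, idx)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def module_preservation(ref_expr: ExpressionDataset, test_expr: ExpressionDataset,
                        ref_moduleset: ModuleSet, power: int = 6, mode: str = "signed_hybrid",
                        n_perm: int = 200, seed: int = 0,
                        min_overlap: float = 0.5) -> PreservationResult:
    """Permutation Z preservation statistics for every reference module.

    Modules whose gene overlap with the test dataset falls below
    ``min_overlap`` of their size are flagged not evaluable; modules with a
    zero-spread null are flagged degenerate (Z omitted).  Module 0
    (unassigned genes) is excluded.  Results are reproducible for a fixed
    seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    shared = [g for g in ref_expr.gene_ids if g in set(test_expr.gene_ids)]
    pos = {g: i for i, g in enumerate(shared)}
    ref_sub = ref_expr.subset_genes(shared)
    test_sub = test_expr.subset_genes(shared)
    adj_ref = adjacency(correlation_matrix(ref_sub), power, mode)
    adj_test = adjacency(correlation_matrix(test_sub), power, mode)

    rng = np.random.default_rng(seed)
    assignments = ref_moduleset.assignments
    rows = []
    for mid in sorted(int(m) for m in assignments.unique() if int(m) > 0):
        members = list(assignments.index[assignments == mid])
        in_shared = np.array([pos[g] for g in members if g in pos], dtype=int)
        row: dict = {"module": mid, "size": len(members), "n_shared": int(in_shared.size),
                     "evaluable": True, "degenerate": False}
        if in_shared.size < max(2, min_overlap * len(members)):
            row.update(evaluable=False, z_density=np.nan, z_connectivity=np.nan, z_summary=np.nan)
            rows.append(row)
            continue
        dens_obs = _density(adj_test, in_shared)
        conn_obs = _kim_corr(adj_ref, adj_test, in_shared)
        pool = np.setdiff1d(np.arange(len(shared)), in_shared)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for b in range(n_perm):
            draw = rng.choice(pool, size=in_shared.size, replace=False)
            null_d[b] = _density(adj_test, draw)
            null_c[b] = _kim_corr(adj_ref, adj_test, draw)
        row.update(density_obs=dens_obs, connectivity_obs=conn_obs,
                   density_null_mean=float(np.nanmean(null_d)),
                   density_null_sd=float(np.nanstd(null_d, ddof=1)),
                   connectivity_null_mean=float(np.nanmean(null_c)),
                   connectivity_null_sd=float(np.nanstd(null_c, ddof=1)))
        zs = {}
        for name, obs, nulls in (("z_density", dens_obs, null_d),
                                 ("z_connectivity", conn_obs, null_c)):
            sd = np.nanstd(nulls, ddof=1)
            if not np.isfinite(sd) or sd == 0 or not np.isfinite(obs):
                row["degenerate"] = True
                zs[name] = np.nan
            else:
                zs[name] = (obs - np.nanmean(nulls)) / sd
        row.update(zs)
        row["z_summary"] = (zs["z_density"] + zs["z_connectivity"]) / 2.0
        rows.append(row)
    stats = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame()
    return PreservationResult(stats, n_perm, seed, power, mode)


def classify_preservation(result: PreservationResult, weak: float = WEAK_THRESHOLD,
                          strong: float = STRONG_THRESHOLD) -> pd.Series:
    """Label modules: not_preserved (< weak), weak_to_moderate, strong (>= strong)."""
    labels = {}
    for mid, row in result.stats.iterrows():
        z = row.get("z_summary", np.nan)
        if not row.get("evaluable", True) or not np.isfinite(z):
            labels[mid] = "not_evaluable"
        elif z < weak:
            labels[mid] = "not_preserved"
        elif z < strong:
            labels[mid] = "weak_to_moderate"
        else:
            labels[mid] = "strong"
    return pd.Series(labels, name="preservation")
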