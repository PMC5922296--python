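"""Weighted coexpression network construction and module detection.

Pipeline: Pearson correlation -> soft-thresholded adjacency -> topological
overlap (TOM) -> average-linkage clustering of 1 - TOM with a simplified
dynamic-hybrid tree cut -> eigengenes, kME, eigengene-based module merging,
driver-gene ranking and hub-subnetwork export.

The signed-hybrid adjacency (negative correlations clipped to zero) is the
default: it prevents anti-correlated tissue programs from fusing into one
module.  The classic unsigned |r|^beta network is available for fidelity to
older conventions.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._stats import bh_adjust, corr_pvalues, rowwise_pearson
from .dataio import ExpressionDataset

log = logging.getLogger(__name__)

DEFAULT_POWER = 6
MODES = ("unsigned", "signed_hybrid")


@dataclasses.dataclass
class SoftPowerScan:
    """Scale-free-topology scan over candidate soft-threshold powers."""

    table: pd.DataFrame  # columns: power, r_squared, mean_connectivity
    chosen_power: int
    r2_threshold: float
    threshold_met: bool


@dataclasses.dataclass
class ModuleSet:
    """Gene->module assignments with eigengenes and kME statistics.

    Module ids are positive integers ordered by descending size; 0 collects
    unassigned genes.  Eigengenes are mean-0, unit-variance sample profiles
    oriented so the mean member kME is positive.
    """

    assignments: pd.Series            # gene_id -> module id (int)
    eigengenes: pd.DataFrame          # module id x sample
    kme: pd.DataFrame                 # gene x module, Pearson r
    kme_p: pd.DataFrame
    kme_q: pd.DataFrame
    module_sizes: pd.Series           # module id -> size (excludes module 0)
    params: dict = dataclasses.field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return list(self.eigengenes.index)

    def members(self, module_id: int) -> list[str]:
        if module_id not in set(self.assignments.values):
            raise KeyError(f"unknown module {module_id}")
        return list(self.assignments.index[self.assignments == module_id])


# ---------------------------------------------------------------------------


def correlation_matrix(expr: ExpressionDataset) -> np.ndarray:
    """Gene x gene Pearson correlation of log2 expression profiles."""
    if expr.n_samples < 3:
        raise ValueError("correlation requires >= 3 samples")
    sd = expr.values.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance gene {expr.gene_ids[zero[0]]!r}; filter before correlating")
    r = np.corrcoef(expr.values)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def adjacency(corr: np.ndarray, power: float, mode: str = "signed_hybrid") -> np.ndarray:
    """Soft-thresholded adjacency: |r|^b (unsigned) or r^b for r>0 (signed hybrid).

    The diagonal is zeroed so that row sums are connectivities.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if power < 1:
        raise ValueError("power must be >= 1")
    if mode == "unsigned":
        a = np.abs(corr) ** power
    else:
        a = np.where(corr > 0, corr, 0.0) ** power
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off the
    diagonal, TOM_ii = 1, with k the connectivity (row sum of the
    zero-diagonal adjacency).
    """
    a = np.asarray(adj, dtype=float)
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    tom = (tom + tom.T) / 2.0
    np.clip(tom, 0.0, 1.0, out=tom)
    np.fill_diagonal(tom, 1.0)
    return tom


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of the binned connectivity distribution.

    Positive slopes (not scale-free) score 0, mirroring the signed
    scale-free-fit index convention.
    """
    k = connectivity[connectivity > 0]
    if k.size < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    slope = np.polyfit(x, y, 1)[0]
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return r2 if slope < 0 else 0.0


def pick_soft_power(expr: ExpressionDataset, candidates: Sequence[int] = tuple(range(1, 21)),
                    r2_threshold: float = 0.8, mode: str = "signed_hybrid") -> SoftPowerScan:
    """Scan candidate powers for approximate scale-free topology.

    Chooses the smallest candidate whose fit R^2 meets ``r2_threshold``;
    falls back to power 6 with a warning when the threshold is never met.
    """
    if expr.n_genes < 50:
        warnings.warn(f"soft-power scan on only {expr.n_genes} genes is unreliable")
    corr = correlation_matrix(expr)
    rows = []
    for beta in candidates:
        a = adjacency(corr, beta, mode)
        k = a.sum(axis=0)
        rows.append({"power": int(beta), "r_squared": _scale_free_r2(k),
                     "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    passing = table[table["r_squared"] >= r2_threshold]
    if len(passing):
        chosen = int(passing["power"].iloc[0])
        met = True
    else:
        chosen = DEFAULT_POWER
        met = False
        warnings.warn(
            f"scale-free fit R^2 never reached {r2_threshold}; "
            f"falling back to default power {DEFAULT_POWER}")
    return SoftPowerScan(table, chosen, r2_threshold, met)


# ---------------------------------------------------------------------------
# eigengenes and kME


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def _eigengene(values: np.ndarray, member_genes: list[str]) -> np.ndarray:
    """First principal component of the standardized member expression,
    scaled to mean 0 / unit variance and sign-oriented so mean member
    correlation is positive (ties broken by the lexicographically first
    member's loading)."""
    xs = _standardize_rows(values)
    if xs.shape[0] == 1:
        e = xs[0].copy()
    else:
        _, _, vt = np.linalg.svd(xs, full_matrices=False)
        e = vt[0]
    e = e - e.mean()
    sd = e.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate eigengene (constant across samples)")
    e = e / sd
    member_r = rowwise_pearson(values, e[None, :])[:, 0]
    sign = np.sign(np.nansum(member_r))
    if sign == 0:
        first = int(np.argmin(np.asarray(member_genes, dtype=object)))
        sign = np.sign(member_r[first]) or 1.0
    return e * sign


def module_eigengenes(expr: ExpressionDataset, assignments: pd.Series) -> pd.DataFrame:
    """Eigengene (first PC) per module; module x sample, unit variance."""
    assignments = assignments.reindex(expr.gene_ids)
    if assignments.isna().any():
        raise ValueError("assignments missing for some genes in the dataset")
    rows = {}
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    for mid in sorted({int(m) for m in assignments.unique() if int(m) > 0}):
        members = list(assignments.index[assignments == mid])
        idx = [gene_pos[g] for g in members]
        rows[mid] = _eigengene(expr.values[idx], members)
    return pd.DataFrame(rows, index=expr.sample_ids).T


def kme(expr: ExpressionDataset, eigengenes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene x module correlation (kME) with two-sided p and per-module BH q."""
    n = expr.n_samples
    if n <= 2:
        raise ValueError("kME requires more than 2 samples")
    if list(eigengenes.columns) != list(expr.sample_ids):
        eigengenes = eigengenes[expr.sample_ids]
    sd = expr.values.std(axis=1, ddof=1)
    if (sd == 0).any():
        g = expr.gene_ids[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"zero-variance gene {g!r} in kME computation")
    r = rowwise_pearson(expr.values, eigengenes.to_numpy())
    p = corr_pvalues(r, n)
    q = np.column_stack([bh_adjust(p[:, j]) for j in range(p.shape[1])]) if p.size else p
    idx, cols = expr.gene_ids, list(eigengenes.index)
    return (pd.DataFrame(r, index=idx, columns=cols),
            pd.DataFrame(p, index=idx, columns=cols),
            pd.DataFrame(q, index=idx, columns=cols))


# ---------------------------------------------------------------------------
# tree cutting


def _recursive_split(diss: np.ndarray, idx: np.ndarray, min_size: int, depth: int) -> list[np.ndarray]:
    """Binary-split a branch while both children stay above min_size."""
    if depth <= 0 or idx.size < 2 * min_size:
        return [idx]
    sub = diss[np.ix_(idx, idx)]
    z = linkage(squareform(sub, checks=False), method="average")
    lab = fcluster(z, 2, criterion="maxclust")
    left, right = idx[lab == 1], idx[lab == 2]
    if min(left.size, right.size) < min_size:
        return [idx]
    return (_recursive_split(diss, left, min_size, depth - 1)
            + _recursive_split(diss, right, min_size, depth - 1))


def detect_modules(expr: ExpressionDataset, power: int = DEFAULT_POWER, mode: str = "signed_hybrid",
                   min_size: int = 30, cut_height: float = 0.995, deep_split: int = 2,
                   merge_threshold: float = 0.25, seed: int | None = None,
                   reassign_kme: float = 0.4) -> ModuleSet:
    """Detect coexpression modules by clustering the TOM dissimilarity.

    Average-linkage clustering of 1 - TOM is cut with a simplified
    dynamic-hybrid procedure: a static cut at ``cut_height``, recursive
    binary branch splitting up to ``deep_split`` levels, assignment of stray
    genes to the module of maximal kME when that kME exceeds
    ``reassign_kme``, and iterative merging of modules whose eigengene
    correlation exceeds ``1 - merge_threshold``.  The result is
    deterministic; ``seed`` is recorded for provenance only.
    """
    params = dict(power=power, mode=mode, min_size=min_size, cut_height=cut_height,
                  deep_split=deep_split, merge_threshold=merge_threshold, seed=seed,
                  reassign_kme=reassign_kme)
    n = expr.n_genes
    if min(min_size, cut_height, deep_split + 1, merge_threshold) <= 0:
        raise ValueError("tree-cut parameters must be positive")
    if n < min_size:
        warnings.warn(f"{n} genes < min_size {min_size}: all genes left unassigned")
        return _finalize(expr, np.zeros(n, dtype=int), params)

    corr = correlation_matrix(expr)
    tom = topological_overlap(adjacency(corr, power, mode))
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)

    z = linkage(squareform(diss, checks=False), method="average")
    static = fcluster(z, t=cut_height, criterion="distance")

    branches: list[np.ndarray] = []
    for lab in np.unique(static):
        branches.extend(_recursive_split(diss, np.flatnonzero(static == lab), min_size, deep_split))

    assign = np.zeros(n, dtype=int)
    next_id = 1
    for br in branches:
        if br.size >= min_size:
            assign[br] = next_id
            next_id += 1

    # PAM-like membership stage: the branch cores define eigengenes, then every
    # gene joins the module of maximal kME provided it clears the threshold.
    # This pulls stray branch members in and expels genes a branch absorbed
    # through chance correlation with its latent profile.
    if next_id > 1:
        eig = module_eigengenes(expr, pd.Series(assign, index=expr.gene_ids))
        r = rowwise_pearson(expr.values, eig.to_numpy())
        best = np.argmax(r, axis=1)
        best_r = r[np.arange(n), best]
        assign = np.where(best_r > reassign_kme, np.asarray(eig.index)[best], 0)
        # modules shrunk below min_size dissolve into unassigned
        ids, counts = np.unique(assign[assign > 0], return_counts=True)
        for mid in ids[counts < min_size]:
            assign[assign == mid] = 0

    # iterative eigengene-based merging
    while len(np.unique(assign[assign > 0])) >= 2:
        series = pd.Series(assign, index=expr.gene_ids)
        eig = module_eigengenes(expr, series)
        me = eig.to_numpy()
        r = rowwise_pearson(me, me)
        np.fill_diagonal(r, -np.inf)
        i, j = np.unravel_index(np.argmax(r), r.shape)
        if r[i, j] < 1.0 - merge_threshold:
            break
        keep, drop = sorted((int(eig.index[i]), int(eig.index[j])))
        assign[assign == drop] = keep

    return _finalize(expr, assign, params)


def _finalize(expr: ExpressionDataset, assign: np.ndarray, params: dict) -> ModuleSet:
    """Relabel modules 1..k by descending size and compute eigengenes/kME."""
    ids, counts = np.unique(assign[assign > 0], return_counts=True)
    order = np.argsort(-counts, kind="stable")
    relabel = {int(old): rank + 1 for rank, old in enumerate(ids[order])}
    final = np.array([relabel.get(int(a), 0) for a in assign], dtype=int)
    assignments = pd.Series(final, index=expr.gene_ids, name="module")
    if (final > 0).any():
        eig = module_eigengenes(expr, assignments)
        kme_r, kme_p, kme_q = kme(expr, eig)
        sizes = assignments[assignments > 0].value_counts().sort_index()
    else:
        eig = pd.DataFrame(index=pd.Index([], dtype=int), columns=expr.sample_ids, dtype=float)
        empty = pd.DataFrame(index=expr.gene_ids, dtype=float)
        kme_r, kme_p, kme_q = empty, empty.copy(), empty.copy()
        sizes = pd.Series(dtype=int)
    return ModuleSet(assignments, eig, kme_r, kme_p, kme_q, sizes, params)


# ---------------------------------------------------------------------------
# driver genes and subnetwork export


def driver_genes(moduleset: ModuleSet, module_id: int, n: int = 10) -> list[str]:
    """Top-n module members by kME to their own module (putative drivers)."""
    members = moduleset.members(module_id)
    if module_id not in moduleset.kme.columns:
        raise KeyError(f"no kME column for module {module_id}")
    if n > len(members):
        raise ValueError(f"requested {n} drivers but module {module_id} has {len(members)} members")
    scores = moduleset.kme.loc[members, module_id]
    ranked = sorted(members, key=lambda g: (-scores[g], g))
    return ranked[:n]


def export_subnetwork(moduleset: ModuleSet, tom: np.ndarray | pd.DataFrame, module_id: int,
                      top_n: int = 100) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables (Cytoscape-ready) for a module's top hub genes.

    Nodes carry kME and its FDR q; edges carry the TOM weight between every
    pair of selected genes.
    """
    members = moduleset.members(module_id)
    if isinstance(tom, pd.DataFrame):
        tom_df = tom
    else:
        tom_df = pd.DataFrame(np.asarray(tom), index=moduleset.assignments.index,
                              columns=moduleset.assignments.index)
    if top_n > len(members):
        warnings.warn(f"module {module_id} has {len(members)} members < top_n {top_n}; exporting all")
        top_n = len(members)
    scores = moduleset.kme.loc[members, module_id]
    chosen = sorted(members, key=lambda g: (-scores[g], g))[:top_n]
    nodes = pd.DataFrame({
        "gene": chosen,
        "kme": [moduleset.kme.loc[g, module_id] for g in chosen],
        "q": [moduleset.kme_q.loc[g, module_id] for g in chosen],
    })
    edges = []
    for a in range(len(chosen)):
        for b in range(a + 1, len(chosen)):
            gi, gj = chosen[a], chosen[b]
            edges.append((gi, gj, float(tom_df.loc[gi, gj])))
    edge_df = pd.DataFrame(edges, columns=["gene_i", "gene_j", "tom"])
    return nodes, edge_df
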