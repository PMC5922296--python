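"""Module-trait association, module classification, eigengene network, MDS.

Traits are 0/1 sample indicators (tissue, condition, configured tissue
groups); module eigengenes are correlated against them with point-biserial
Pearson r and exact t-based p-values, mirroring the r / -log10(p)
module-trait heatmap convention.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._stats import corr_pvalues, rowwise_pearson
from .dataio import ExpressionDataset, TraitDesign


@dataclasses.dataclass
class ModuleTraitMatrix:
    """Per module x trait: Pearson r, two-sided p and -log10(p)."""

    r: pd.DataFrame
    p: pd.DataFrame

    @property
    def neglogp(self) -> pd.DataFrame:
        return -np.log10(self.p)

    @property
    def modules(self) -> list:
        return list(self.r.index)

    @property
    def traits(self) -> list[str]:
        return list(self.r.columns)


@dataclasses.dataclass
class EigengeneNetwork:
    """Pairwise module-eigengene correlations with a layout adjacency."""

    edges: pd.DataFrame          # module_i, module_j, r, p
    adjacency: pd.DataFrame      # module x module, ((1 + r)/2)^2


def binary_traits(design: TraitDesign, grouping_config: Mapping[str, Sequence[str]] | None = None
                  ) -> pd.DataFrame:
    """Build the 0/1 trait indicator matrix (samples x traits).

    One column per tissue (``tissue:<name>``) and condition
    (``condition:<name>``), plus one per configured tissue group
    (``group:<name>``), e.g. SLO = {spleen, LN, ...} vs target organs.
    """
    table = design.table
    known_tissues = set(table["tissue"].astype(str))
    cols: dict[str, np.ndarray] = {}
    for t in sorted(known_tissues):
        cols[f"tissue:{t}"] = (table["tissue"].astype(str) == t).to_numpy().astype(int)
    for c in sorted(set(table["condition"].astype(str))):
        cols[f"condition:{c}"] = (table["condition"].astype(str) == c).to_numpy().astype(int)
    for gname, tissues in (grouping_config or {}).items():
        unknown = sorted(set(map(str, tissues)) - known_tissues)
        if unknown:
            raise ValueError(f"group {gname!r} references unknown tissue(s): {unknown}")
        cols[f"group:{gname}"] = table["tissue"].astype(str).isin(set(map(str, tissues))).to_numpy().astype(int)
    return pd.DataFrame(cols, index=table.index)


def module_trait_matrix(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> ModuleTraitMatrix:
    """Correlate each module eigengene with each binary trait.

    Point-biserial Pearson r with two-sided p from the exact t transform.
    Constant trait columns yield r = 0, p = 1 with a warning.
    """
    if list(eigengenes.columns) != list(traits.index):
        traits = traits.loc[list(eigengenes.columns)]
    n = eigengenes.shape[1]
    if n < 3:
        raise ValueError("module-trait correlation requires >= 3 samples")
    tvals = traits.to_numpy(dtype=float).T  # trait x sample
    const = tvals.std(axis=1) == 0
    if const.any():
        warnings.warn(f"constant trait column(s) {list(traits.columns[const])}: reported as r=0, p=1")
    r = rowwise_pearson(eigengenes.to_numpy(), tvals)
    r[:, const] = 0.0
    p = corr_pvalues(r, n)
    p[:, const] = 1.0
    return ModuleTraitMatrix(
        pd.DataFrame(r, index=eigengenes.index, columns=traits.columns),
        pd.DataFrame(p, index=eigengenes.index, columns=traits.columns),
    )


def rank_modules_by_trait(matrix: ModuleTraitMatrix, trait: str,
                          neglogp_cutoff: float = 2.0) -> tuple[list, list]:
    """Modules passing -log10(p) > cutoff for a trait, split by correlation sign.

    Both lists are ordered by |r| descending (strongest association first).
    The default cutoff of 2 corresponds to p = 0.01.
    """
    if trait not in matrix.r.columns:
        raise KeyError(f"unknown trait {trait!r}")
    passing = matrix.neglogp[trait] > neglogp_cutoff
    r = matrix.r.loc[passing, trait]
    ordered = r.reindex(r.abs().sort_values(ascending=False).index)
    pos = list(ordered.index[ordered > 0])
    neg = list(ordered.index[ordered < 0])
    return pos, neg


def classify_modules(matrix: ModuleTraitMatrix, group_traits: Mapping[str, Sequence[str]],
                     alpha: float = 0.01) -> pd.Series:
    """Label each module by its pattern of significant positive tissue correlations.

    ``group_traits`` maps group labels (e.g. SLO vs target organ) to lists of
    tissue trait columns.  Labels: exactly one significant tissue ->
    ``tissue_specific``; several tissues within one group ->
    ``group_selective``; significant tissues in more than one group ->
    ``bridging`` (modules spanning lymphoid and target compartments); none ->
    ``unassociated``.  Only positive correlations count toward labels.
    """
    all_traits = [t for ts in group_traits.values() for t in ts]
    unknown = [t for t in all_traits if t not in matrix.r.columns]
    if unknown:
        raise KeyError(f"unknown trait column(s): {unknown}")
    labels = {}
    for m in matrix.modules:
        sig = {t for t in all_traits
               if matrix.p.loc[m, t] < alpha and matrix.r.loc[m, t] > 0}
        groups_hit = [g for g, ts in group_traits.items() if sig & set(ts)]
        if not sig:
            labels[m] = "unassociated"
        elif len(groups_hit) > 1:
            labels[m] = "bridging"
        elif len(sig) == 1:
            labels[m] = "tissue_specific"
        else:
            labels[m] = "group_selective"
    return pd.Series(labels, name="label")


def eigengene_network(eigengenes: pd.DataFrame) -> EigengeneNetwork:
    """Pairwise eigengene correlations plus the ((1 + r)/2)^2 layout adjacency."""
    if len(eigengenes) < 2:
        raise ValueError("eigengene network requires >= 2 modules")
    me = eigengenes.to_numpy()
    n = me.shape[1]
    r = rowwise_pearson(me, me)
    np.fill_diagonal(r, 1.0)
    p = corr_pvalues(r, n)
    mods = list(eigengenes.index)
    iu, ju = np.triu_indices(len(mods), k=1)
    edges = pd.DataFrame({
        "module_i": [mods[i] for i in iu],
        "module_j": [mods[j] for j in ju],
        "r": r[iu, ju],
        "p": p[iu, ju],
    })
    adj = pd.DataFrame(((1.0 + r) / 2.0) ** 2, index=mods, columns=mods)
    return EigengeneNetwork(edges, adj)


def classical_mds(expr: ExpressionDataset, n_dims: int = 2, distance: str = "euclidean_topvar",
                  top_k: int = 500) -> pd.DataFrame:
    """Torgerson classical MDS of inter-sample distances.

    ``distance`` is ``"euclidean_topvar"`` (Euclidean on the top-``top_k``
    most variable genes) or ``"correlation"`` (1 - Pearson r between
    samples).  Double-centers the squared distance matrix and embeds on the
    top eigenvectors scaled by sqrt(eigenvalue).  Negative eigenvalues
    (non-Euclidean input) are clamped to zero with a warning when material.
    """
    ns = expr.n_samples
    if ns < n_dims + 1:
        raise ValueError(f"need >= {n_dims + 1} samples for {n_dims}-d MDS")
    x = expr.values
    if distance == "euclidean_topvar":
        if top_k is not None and top_k < x.shape[0]:
            var = x.var(axis=1, ddof=1)
            x = x[np.argsort(-var, kind="stable")[:top_k]]
        d = squareform(pdist(x.T, metric="euclidean"))
    elif distance == "correlation":
        r = rowwise_pearson(x.T, x.T)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    d2 = d**2
    j = np.eye(ns) - np.ones((ns, ns)) / ns
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order]
    kept = evals[:n_dims]
    if (kept < 0).any() and abs(kept.min()) > 1e-8 * max(evals.max(), 1e-12):
        warnings.warn("negative eigenvalues dominate requested MDS dimensions; clamping to 0")
    coords = evecs[:, :n_dims] * np.sqrt(np.clip(kept, 0.0, None))
    return pd.DataFrame(coords, index=expr.sample_ids,
                        columns=[f"dim{i + 1}" for i in range(n_dims)])
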