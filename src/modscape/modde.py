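"""Module-level differential expression (modDE).

modDE asks two questions of each coexpression module under a two-group
contrast: (a) does the module contain an excess of differentially expressed
genes, and (b) is the *direction* of differential expression consistent with
the module's correlation structure?  The consistency statistic is a
kME-signed, kME-weighted Stouffer combination of per-gene signed z-scores,

    T_m = sum_g w_g * s_g * z_g / sqrt(sum_g w_g^2),

with s_g = sign(kME_gm), w_g = |kME_gm| over member genes g, and z_g the
signed z of a per-gene Welch t-test.  Because member genes are correlated,
T_m is calibrated by permuting contrast labels among samples (within tissue
strata when the design spans several tissues), which preserves the
inter-gene correlation that an analytic Stouffer null would ignore.  A
module that is merely shifted gene-by-gene in random directions shows an
excess of DE genes but no direction consistency; a module shifted along its
latent axis shows both — this separation is the point of the test.
"""
from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import _P_FLOOR, bh_adjust
from .dataio import ExpressionDataset, TraitDesign
from .netbuild import ModuleSet

log = logging.getLogger(__name__)

MIN_DISTINCT_PERMUTATIONS = 20


@dataclasses.dataclass
class GeneDEResult:
    """Per-gene Welch test: effect (mean log2 diff, B - A), t, p, signed z."""

    table: pd.DataFrame  # index gene_id; columns effect, t, df, p, z
    contrast: tuple[str, str]
    n_a: int
    n_b: int


@dataclasses.dataclass
class ModDEResult:
    """Per-module consistency and excess-DE statistics."""

    table: pd.DataFrame  # index module; T, p_consistency, q_consistency, n_de, p_excess, q_excess
    contrast: tuple[str, str]
    n_perm: int
    seed: int
    alpha0: float
    null_method: str = "stratified label permutation"


def _welch(x: np.ndarray, mask_b: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized Welch t over genes (rows of x) for one or many group labelings.

    ``mask_b`` is a boolean (n_samples,) or (n_samples, n_perm) array marking
    arm B.  Returns effect, t, df, p, z with shape genes x n_perm (squeezed
    to 1-D for a single labeling).
    """
    single = mask_b.ndim == 1
    m = np.atleast_2d(mask_b.T).T.astype(float)  # n x P
    n = x.shape[1]
    nb = m.sum(axis=0)
    na = n - nb
    sx = x.sum(axis=1, keepdims=True)
    sxx = (x**2).sum(axis=1, keepdims=True)
    sb = x @ m
    qb = (x**2) @ m
    mb = sb / nb
    ma = (sx - sb) / na
    with np.errstate(invalid="ignore", divide="ignore"):
        vb = np.clip((qb - nb * mb**2) / (nb - 1), 0.0, None)
        va = np.clip(((sxx - qb) - na * ma**2) / (na - 1), 0.0, None)
        se2 = va / na + vb / nb
        effect = mb - ma
        t = effect / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    df = np.where(np.isfinite(df) & (df > 0), df, n - 2)
    zero_se = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se, np.where(effect == 0, 0.0, np.sign(effect) * np.inf), t)
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df))
    p = np.clip(p, _P_FLOOR, 1.0)
    z = stats.norm.isf(p / 2.0) * np.sign(t)
    if single:
        return tuple(a[:, 0] for a in (effect, t, df, p, z))
    return effect, t, df, p, z


def _select_contrast(design: TraitDesign, contrast: Sequence[str],
                     within: Mapping[str, str] | None) -> tuple[list[str], np.ndarray, pd.Series]:
    a, b = contrast
    table = design.table
    if within:
        for col, val in within.items():
            if col not in table.columns:
                raise ValueError(f"within-filter column {col!r} not in design")
            table = table[table[col].astype(str) == str(val)]
    sel = table[table["condition"].astype(str).isin([str(a), str(b)])]
    if sel.empty:
        raise ValueError(f"no samples for contrast {a!r} vs {b!r}")
    mask_b = (sel["condition"].astype(str) == str(b)).to_numpy()
    n_b = int(mask_b.sum())
    n_a = len(sel) - n_b
    if min(n_a, n_b) < 2:
        raise ValueError(f"each contrast arm needs >= 2 samples (got {n_a} vs {n_b})")
    return list(sel.index), mask_b, sel["tissue"].astype(str)


def gene_de(expr: ExpressionDataset, design: TraitDesign, contrast: Sequence[str],
            within: Mapping[str, str] | None = None) -> GeneDEResult:
    """Per-gene Welch two-sample t on log2 values for condition B vs A.

    The signed z is z = Phi^-1(1 - p/2) * sign(effect), the standard input
    to direction-aware p-value combination.
    """
    samples, mask_b, _ = _select_contrast(design, contrast, within)
    x = expr.subset_samples(samples).values
    effect, t, df, p, z = _welch(x, mask_b)
    table = pd.DataFrame({"effect": effect, "t": t, "df": df, "p": p, "z": z},
                         index=expr.gene_ids)
    return GeneDEResult(table, (str(contrast[0]), str(contrast[1])),
                        int((~mask_b).sum()), int(mask_b.sum()))


def _count_distinct_permutations(strata: pd.Series, mask_b: np.ndarray) -> float:
    total = 1.0
    for _, idx in strata.groupby(strata, sort=False).groups.items():
        loc = strata.index.get_indexer(idx)
        n = len(loc)
        k = int(mask_b[loc].sum())
        total *= math.comb(n, k)
        if total > 1e12:
            return total
    return total


def _stratified_permutations(strata: pd.Series, mask_b: np.ndarray, n_perm: int,
                             rng: np.random.Generator) -> np.ndarray:
    """n_samples x n_perm boolean matrix of permuted arm-B labels.

    Labels are shuffled independently within each stratum so that condition
    effects are never confounded with tissue.
    """
    n = len(mask_b)
    out = np.empty((n, n_perm), dtype=bool)
    groups = [strata.index.get_indexer(idx) for _, idx in strata.groupby(strata, sort=False).groups.items()]
    for b in range(n_perm):
        col = np.empty(n, dtype=bool)
        for loc in groups:
            col[loc] = mask_b[loc][rng.permutation(len(loc))]
        out[:, b] = col
    return out


def modde(moduleset: ModuleSet, expr: ExpressionDataset, design: TraitDesign,
          contrast: Sequence[str], n_perm: int = 10000, seed: int = 0,
          alpha0: float = 0.05, within: Mapping[str, str] | None = None) -> ModDEResult:
    """modDE: direction-consistency and excess-DE tests for every module.

    Consistency p is the two-sided add-one-corrected empirical p of T_m
    against the stratified label-permutation null (so p >= 1/(n_perm+1)).
    The excess component counts member genes with p < ``alpha0`` against a
    hypergeometric expectation over all genes.  BH q-values are computed
    across modules for each component separately; the headline module p is
    the consistency p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    samples, mask_b, tissues = _select_contrast(design, contrast, within)
    strata = tissues if tissues.nunique() > 1 else pd.Series("all", index=tissues.index)
    n_distinct = _count_distinct_permutations(strata, mask_b)
    if n_distinct < MIN_DISTINCT_PERMUTATIONS:
        raise ValueError(
            f"only {n_distinct:.0f} distinct stratified label permutations; "
            f"need >= {MIN_DISTINCT_PERMUTATIONS} (insufficient samples)")

    sub = expr.subset_samples(samples)
    gene_pos = {g: i for i, g in enumerate(sub.gene_ids)}
    observed = gene_de(expr, design, contrast, within)
    obs_p = observed.table["p"]
    obs_z = observed.table["z"]

    # member bookkeeping: orientation and weight from each gene's own-module kME
    modules = []
    member_rows: list[int] = []
    for mid in moduleset.module_ids:
        members = [g for g in moduleset.members(mid) if g in gene_pos]
        if not members:
            warnings.warn(f"module {mid} absent from expression data; skipped")
            continue
        kme_m = moduleset.kme.loc[members, mid].to_numpy()
        modules.append((mid, members, np.sign(kme_m), np.abs(kme_m)))
        member_rows.extend(gene_pos[g] for g in members)

    member_rows = sorted(set(member_rows))
    row_of = {r: i for i, r in enumerate(member_rows)}
    xm = sub.values[member_rows]

    # weight matrix: modules x member-genes, entries w_g * s_g / sqrt(sum w^2)
    wmat = np.zeros((len(modules), len(member_rows)))
    for i, (mid, members, signs, weights) in enumerate(modules):
        norm = np.sqrt((weights**2).sum())
        norm = norm if norm > 0 else 1.0
        for g, s, w in zip(members, signs, weights):
            wmat[i, row_of[gene_pos[g]]] = s * w / norm

    t_obs = wmat @ obs_z.iloc[member_rows].to_numpy()

    rng = np.random.default_rng(seed)
    masks = _stratified_permutations(strata, mask_b, n_perm, rng)
    *_, z_perm = _welch(xm, masks)
    t_perm = wmat @ z_perm  # modules x n_perm
    exceed = (np.abs(t_perm) >= np.abs(t_obs)[:, None]).sum(axis=1)
    p_cons = (1.0 + exceed) / (n_perm + 1.0)

    # excess-DE component: hypergeometric over all genes in the dataset
    n_total = sub.n_genes
    n_sig_total = int((obs_p < alpha0).sum())
    rows = []
    for i, (mid, members, _, _) in enumerate(modules):
        k = int((obs_p.loc[members] < alpha0).sum())
        m = len(members)
        p_exc = float(stats.hypergeom.sf(k - 1, n_total, n_sig_total, m))
        rows.append({"module": mid, "size": m, "T": float(t_obs[i]),
                     "p_consistency": float(p_cons[i]), "n_de": k,
                     "expected_de": n_sig_total * m / n_total, "p_excess": p_exc})
    table = pd.DataFrame(rows).set_index("module")
    table["q_consistency"] = bh_adjust(table["p_consistency"].to_numpy())
    table["q_excess"] = bh_adjust(table["p_excess"].to_numpy())
    return ModDEResult(table, (str(contrast[0]), str(contrast[1])), n_perm, seed, alpha0)


def modde_trait_table(modde_result: ModDEResult, module_trait_matrix, trait: str,
                      trait_p_cutoff: float = 0.01, modde_q_cutoff: float = 0.05) -> pd.DataFrame:
    """Join trait association and modDE significance per module.

    Produces the scatter-ready table of (-log10 trait p, -log10 modDE
    consistency p) and flags modules significant on both axes — e.g. a
    module both epidermis-linked and coherently perturbed by the contrast.
    """
    if trait not in module_trait_matrix.p.columns:
        raise KeyError(f"unknown trait {trait!r}")
    shared = [m for m in modde_result.table.index if m in module_trait_matrix.p.index]
    if not shared:
        raise ValueError("modDE results and module-trait matrix share no modules")
    tp = module_trait_matrix.p.loc[shared, trait]
    mp = modde_result.table.loc[shared, "p_consistency"]
    mq = modde_result.table.loc[shared, "q_consistency"]
    out = pd.DataFrame({
        "trait_neglogp": -np.log10(tp),
        "modde_neglogp": -np.log10(mp),
        "modde_q": mq,
        "flagged": (tp < trait_p_cutoff) & (mq < modde_q_cutoff),
    }, index=pd.Index(shared, name="module"))
    return out
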