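"""Gene-signature enrichment: hypergeometric overlap, preranked GSEA, ssGSEA.

These are the three enrichment primitives used around coexpression modules:
exact set-overlap tests of modules against external signatures, weighted
Kolmogorov-Smirnov preranked enrichment of module gene sets in an externally
ranked list (e.g. a cross-species blood-vs-epidermis statistic), and
per-sample single-sample GSEA scores from absolute expression ranking.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import DataError, ExpressionDataset, GeneSetCollection, map_gene_symbols

log = logging.getLogger(__name__)


@dataclasses.dataclass
class OverlapResult:
    """Hypergeometric overlap between two gene sets inside a universe."""

    k: int
    size_a: int
    size_b: int
    universe: int
    p: float
    dropped_a: int = 0
    dropped_b: int = 0


@dataclasses.dataclass
class GseaResult:
    """Preranked GSEA outcome for one gene set."""

    es: float
    nes: float
    p: float
    q: float
    set_size: int
    list_size: int
    n_perm: int
    seed: int


def hypergeom_overlap(set_a: Iterable[str], set_b: Iterable[str],
                      universe: Iterable[str]) -> OverlapResult:
    """Upper-tail hypergeometric test P[X >= k] for the overlap of two sets.

    Genes outside the universe are dropped (counts logged).  Symmetric in
    the two sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a_raw, b_raw = set(set_a), set(set_b)
    a, b = a_raw & uni, b_raw & uni
    dropped_a, dropped_b = len(a_raw) - len(a), len(b_raw) - len(b)
    if dropped_a or dropped_b:
        log.info("hypergeometric overlap dropped %d/%d genes outside universe", dropped_a, dropped_b)
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(a), len(b)))
    return OverlapResult(k, len(a), len(b), len(uni), min(p, 1.0), dropped_a, dropped_b)


# ---------------------------------------------------------------------------
# preranked GSEA


def _running_es(scores: np.ndarray, hits: np.ndarray, weight: float) -> float:
    """Signed extreme of the weighted KS running sum.

    Hit steps are proportional to |score|^weight (uniform if all hit weights
    vanish); miss steps are uniform.  With no misses (set = whole list) the
    walk degenerates and ES = 1 by convention.
    """
    n = scores.size
    nh = int(hits.sum())
    if nh == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if nh == n:
        return 1.0
    hw = np.abs(scores) ** weight * hits
    denom = hw.sum()
    if denom == 0:
        hw = hits.astype(float)
        denom = float(nh)
    running = np.cumsum(hw / denom - (~hits) / (n - nh))
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_preranked(scores: pd.Series, gene_set: Iterable[str], weight: float = 1.0,
                   n_perm: int = 1000, seed: int = 0) -> GseaResult:
    """Preranked GSEA: weighted KS enrichment score with a gene-label null.

    ``scores`` maps unique genes to finite ranking scores; the list is
    ordered by descending score (ties broken by gene id, so results are
    platform-independent).  The null draws random gene-label sets of equal
    size; NES = ES / mean |null ES of the same sign|, the nominal p and q
    come from the same-sign null pool (add-one corrected).
    """
    if scores.index.has_duplicates:
        raise ValueError("ranked list contains duplicate genes")
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValueError("ranking scores must be finite")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    vals = scores.loc[order].to_numpy(dtype=float)
    members = set(gene_set)
    hits = np.array([g in members for g in order], dtype=bool)
    es = _running_es(vals, hits, weight)

    nh = int(hits.sum())
    n = len(order)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        h = np.zeros(n, dtype=bool)
        h[rng.choice(n, size=nh, replace=False)] = True
        null[b] = _running_es(vals, h, weight)
    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same.size == 0:
        nes, p, q = np.nan, 1.0 / (n_perm + 1.0), 1.0
    else:
        scale = np.abs(same).mean()
        nes = es / scale if scale > 0 else np.nan
        exceed = int((np.abs(same) >= abs(es)).sum())
        p = (1.0 + exceed) / (same.size + 1.0)
        q = p  # single-set call: FDR over the same-sign null pool equals the nominal p
    return GseaResult(float(es), float(nes), float(p), float(min(q, 1.0)), nh, n, n_perm, seed)


# ---------------------------------------------------------------------------
# single-sample GSEA


def ssgsea(expr: ExpressionDataset, gene_sets: GeneSetCollection, alpha: float = 0.25,
           normalize: bool = True) -> pd.DataFrame:
    """Single-sample GSEA scores (samples x sets) from absolute expression.

    Per sample, genes are ranked by expression (descending; ties broken by
    gene id) and the score is the sum over ranks of the difference between
    the rank^alpha-weighted hit ECDF and the uniform miss ECDF, with the
    top-ranked gene carrying rank N.  With ``normalize`` the whole matrix is
    divided by its score range.
    """
    n = expr.n_genes
    gene_arr = np.array(expr.gene_ids, dtype=object)
    set_masks = {}
    for name, members in gene_sets.sets.items():
        mask = np.isin(gene_arr, list(members))
        if not mask.any():
            raise ValueError(f"gene set {name!r} shares no genes with the dataset")
        set_masks[name] = mask
    rank_weight = (np.arange(n, 0, -1)) ** alpha  # position j (0-based, top first) -> (N - j)^alpha
    out = np.zeros((expr.n_samples, len(set_masks)))
    for s in range(expr.n_samples):
        col = expr.values[:, s]
        order = np.lexsort((gene_arr, -col))
        for j, (name, mask) in enumerate(set_masks.items()):
            hit = mask[order]
            hw = rank_weight * hit
            ecdf_hit = np.cumsum(hw) / hw.sum()
            nm = n - hit.sum()
            ecdf_miss = np.cumsum(~hit) / nm if nm else np.zeros(n)
            out[s, j] = (ecdf_hit - ecdf_miss).sum()
    df = pd.DataFrame(out, index=expr.sample_ids, columns=list(set_masks))
    if normalize:
        rng_ = df.to_numpy().max() - df.to_numpy().min()
        if rng_ > 0:
            df = df / rng_
    return df


# ---------------------------------------------------------------------------
# cross-species module conservation


def module_conservation_test(module_gene_sets: GeneSetCollection, ranked: pd.Series,
                             mapping_table: Mapping[str, str] | pd.DataFrame | None,
                             n_perm: int = 1000, seed: int = 0,
                             min_genes: int = 5) -> pd.DataFrame:
    """Preranked GSEA of (symbol-mapped) module gene sets in an external ranked list.

    Each module's genes are mapped through the orthology table, then tested
    for enrichment at either end of the ranked list (e.g. a human
    blood-vs-epidermis differential statistic).  Modules mapping to fewer
    than ``min_genes`` genes present in the list are skipped with a warning.
    """
    listed = set(ranked.index)
    rows = []
    for i, name in enumerate(module_gene_sets.names()):
        single = GeneSetCollection({name: module_gene_sets.sets[name]})
        try:
            mapped = map_gene_symbols(single, mapping_table)
            members = mapped.sets[name]
        except DataError:
            members = []
        present = [g for g in members if g in listed]
        if len(present) < min_genes:
            warnings.warn(f"module {name!r} maps to {len(present)} genes in the ranked list; skipped")
            continue
        res = gsea_preranked(ranked, present, n_perm=n_perm, seed=seed + i)
        rows.append({"module": name, "n_genes": len(present), "es": res.es,
                     "nes": res.nes, "p": res.p, "q": res.q})
    return pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame(
        columns=["n_genes", "es", "nes", "p", "q"])
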