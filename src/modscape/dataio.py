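"""Core data model and I/O for expression matrices, trait tables and gene sets.

Expression values are assumed already log2-transformed and normalized; no
background correction or quantile normalization happens here.  Missing values
are resolved at load time so that downstream Pearson-correlation machinery can
assume complete matrices.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclasses.dataclass
class ExpressionDataset:
    """A genes x samples matrix of log2 expression with unique identifiers."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    dataset_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if not self.gene_ids or not self.sample_ids:
            raise DataError("gene and sample identifier lists must be nonempty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            raise DataError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dataset_label: str = "") -> "ExpressionDataset":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), dataset_label)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise DataError(f"genes not in dataset: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionDataset(self.values[rows], list(genes), list(self.sample_ids), self.dataset_label)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionDataset":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise DataError(f"samples not in dataset: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return ExpressionDataset(self.values[:, cols], list(self.gene_ids), list(samples), self.dataset_label)


@dataclasses.dataclass
class TraitDesign:
    """Per-sample design: tissue and condition labels, optional group/replicate."""

    table: pd.DataFrame  # indexed by sample_id; columns tissue, condition[, group, replicate]

    def __post_init__(self) -> None:
        for col in ("tissue", "condition"):
            if col not in self.table.columns:
                raise DataError(f"trait table missing required column {col!r}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise DataError(f"duplicate sample ids in trait table: {dups[:5]}")
        if self.table[["tissue", "condition"]].isna().any().any():
            raise DataError("tissue/condition may not be missing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def matched_to(self, expr: ExpressionDataset) -> "TraitDesign":
        """Return the design reordered to ``expr``'s samples, enforcing a 1:1 match."""
        have = set(self.table.index)
        want = set(expr.sample_ids)
        missing = sorted(want - have)
        extra = sorted(have - want)
        if missing:
            raise DataError(f"samples missing from trait table: {missing}")
        if extra:
            raise DataError(f"trait table has samples absent from expression data: {extra}")
        return TraitDesign(self.table.loc[expr.sample_ids].copy())


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (GMT-backed); member lists deduplicated, never empty."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            seen: dict[str, None] = dict.fromkeys(str(m) for m in members)
            if not seen:
                raise DataError(f"gene set {name!r} is empty")
            clean[str(name)] = list(seen)
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_tsv(path: str | Path, missing_policy: str = "drop_gene",
                        dataset_label: str | None = None) -> ExpressionDataset:
    """Load a genes-as-rows TSV (header = sample ids, first column = gene ids).

    ``missing_policy`` is ``"drop_gene"`` (drop rows containing missing
    values, logging the count) or ``"fail"``.  Duplicate gene ids are
    collapsed to the highest-variance row.
    """
    path = Path(path)
    if missing_policy not in ("drop_gene", "fail"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise DataError(f"{path.name}: duplicate sample ids in header: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise DataError(f"{path.name}: malformed header (no sample columns)")
    num = df.apply(pd.to_numeric, errors="coerce")
    # distinguish genuine NA tokens from unparseable text
    bad = num.isna() & df.notna() & ~df.apply(lambda c: c.str.strip().str.upper().isin(["NA", "NAN", ""]))
    if bad.any().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"{path.name}: non-numeric value {df.iat[gi, si]!r} at gene "
            f"{df.index[gi]!r}, sample {df.columns[si]!r}"
        )
    missing_rows = num.isna().any(axis=1)
    if missing_rows.any():
        if missing_policy == "fail":
            raise DataError(f"{path.name}: missing values in genes {list(num.index[missing_rows])[:5]}")
        log.info("%s: dropped %d gene(s) with missing values", path.name, int(missing_rows.sum()))
        num = num.loc[~missing_rows]
    if num.index.has_duplicates:
        num = _collapse_duplicates_by_variance(num)
    return ExpressionDataset.from_frame(num, dataset_label or path.stem)


def _collapse_duplicates_by_variance(df: pd.DataFrame) -> pd.DataFrame:
    var = df.var(axis=1, ddof=1).to_numpy()
    keep = np.zeros(len(df), dtype=bool)
    order = pd.Series(np.arange(len(df)), index=df.index)
    for _, pos in order.groupby(level=0, sort=False):
        rows = pos.to_numpy()
        keep[rows[np.argmax(var[rows])]] = True
    n_dropped = (~keep).sum()
    log.info("collapsed %d duplicate gene row(s) by highest variance", int(n_dropped))
    return df.iloc[np.flatnonzero(keep)]


def write_expression_tsv(expr: ExpressionDataset, path: str | Path) -> None:
    expr.frame.rename_axis("gene_id").to_csv(path, sep="\t")


def read_traits_tsv(path: str | Path, expr: ExpressionDataset) -> TraitDesign:
    """Load a sample trait table and match it 1:1 against ``expr``'s samples."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise DataError(f"{Path(path).name}: missing sample_id column")
    design = TraitDesign(df.set_index("sample_id"))
    return design.matched_to(expr)


def write_traits_tsv(design: TraitDesign, path: str | Path) -> None:
    design.table.rename_axis("sample_id").to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{Path(path).name}:{lineno}: expected >= 3 tab-separated fields")
            name, description, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                raise DataError(f"{Path(path).name}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise DataError(f"{Path(path).name}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            desc[name] = description
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            description = collection.descriptions.get(name, "")
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# gene filtering and symbol mapping


def filter_genes(expr: ExpressionDataset, exclusion_list: Iterable[str] = (),
                 top_k_by_variance: int | None = None) -> ExpressionDataset:
    """Remove listed genes, then optionally keep the top-k most variable genes.

    This implements the tissue-specific-gene subtraction step (the exclusion
    list is user supplied) followed by the usual variance-based gene
    selection.  Gene order of the survivors is preserved.
    """
    excluded = set(exclusion_list)
    keep = [g for g in expr.gene_ids if g not in excluded]
    if top_k_by_variance is not None:
        if top_k_by_variance < 2:
            raise ValueError("top_k_by_variance must be >= 2")
        sub = expr.subset_genes(keep)
        var = sub.values.var(axis=1, ddof=1)
        order = np.argsort(-var, kind="stable")[:top_k_by_variance]
        chosen = {sub.gene_ids[i] for i in order}
        keep = [g for g in keep if g in chosen]
    if len(keep) < 2:
        raise DataError(f"gene filtering left {len(keep)} gene(s); need >= 2")
    if len(keep) == expr.n_genes:
        return expr
    return expr.subset_genes(keep)


def map_gene_symbols(obj, mapping_table: Mapping[str, str] | pd.DataFrame | None = None):
    """Map gene identifiers through an explicit orthology/symbol table.

    ``mapping_table`` is a mapping old->new or a two-column DataFrame.  With
    ``None`` a documented convenience fallback upper-cases mouse-style
    symbols (Gzmb -> GZMB).  Unmapped genes are dropped (count logged);
    duplicates after mapping are collapsed (expression: highest-variance row;
    gene sets: deduplicated).
    """
    if mapping_table is None:
        mapper = None
    elif isinstance(mapping_table, pd.DataFrame):
        if mapping_table.shape[1] < 2:
            raise ValueError("mapping table needs two columns (source, target)")
        mapper = dict(zip(mapping_table.iloc[:, 0].astype(str), mapping_table.iloc[:, 1].astype(str)))
    else:
        mapper = {str(k): str(v) for k, v in mapping_table.items()}

    def _map(g: str) -> str | None:
        if mapper is None:
            return g.upper()
        return mapper.get(g)

    if isinstance(obj, ExpressionDataset):
        mapped = [(_map(g), i) for i, g in enumerate(obj.gene_ids)]
        kept = [(m, i) for m, i in mapped if m is not None]
        n_dropped = len(mapped) - len(kept)
        if n_dropped:
            log.info("symbol mapping dropped %d unmapped gene(s)", n_dropped)
        if not kept:
            raise DataError("symbol mapping produced an empty dataset")
        df = pd.DataFrame(obj.values[[i for _, i in kept]],
                          index=[m for m, _ in kept], columns=obj.sample_ids)
        if df.index.has_duplicates:
            df = _collapse_duplicates_by_variance(df)
        return ExpressionDataset.from_frame(df, obj.dataset_label)
    if isinstance(obj, GeneSetCollection):
        out: dict[str, list[str]] = {}
        total_dropped = 0
        for name, members in obj.sets.items():
            mapped_members = [_map(m) for m in members]
            kept_members = [m for m in mapped_members if m is not None]
            total_dropped += len(members) - len(kept_members)
            if kept_members:
                out[name] = kept_members
        if total_dropped:
            log.info("symbol mapping dropped %d unmapped set member(s)", total_dropped)
        if not out:
            raise DataError("symbol mapping produced an empty collection")
        return GeneSetCollection(out, dict(obj.descriptions))
    raise TypeError(f"cannot map symbols on {type(obj).__name__}")
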