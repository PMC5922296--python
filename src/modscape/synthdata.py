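"""Synthetic multi-tissue expression generator with planted module structure.

The generator emulates a sorted-cell multi-tissue study design: ~3 replicate
samples per tissue across ~10 tissues (blood, spleen, lymph nodes, bone
marrow, liver, gut lamina propria and intraepithelial compartments, dermis,
epidermis) and experimental conditions, with planted coexpressed gene
modules whose latent factors are tied to tissue/condition indicators, an
optional second "independent" dataset that shares (or scrambles) module
structure, and a perturbation that shifts a module coherently or
incoherently with its correlation structure.

Model: each module m has a latent factor per sample,

    f_m(s) = effect * 1[trait(s)] + delta * 1[perturbed(s)] + N(0, 1),

and each member gene g with loading lambda_g in (0, 1]

    x_g(s) = lambda_g * f_m(s) + N(0, (sigma * sqrt(1 - lambda_g^2))^2) + baseline,

so with sigma = 1 lambda_g is the gene-factor correlation.  The incoherent
perturbation bypasses the factor and adds r_g * lambda_g * delta directly to
gene g (r_g = +/-1 i.i.d.), preserving the module's correlation structure
and per-gene effect magnitude while randomizing effect direction — exactly
the case a direction-aware module DE test must *not* call significant.
Background genes are pure noise.  Everything is reproducible from the seed.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataio import ExpressionDataset, TraitDesign

TISSUES_10 = ["blood", "spleen", "pLN", "mLN", "BM", "liver", "LP", "IEL", "dermis", "epidermis"]


@dataclasses.dataclass
class ModuleSpec:
    """A planted module: size, loading range, optional trait link."""

    size: int
    loading_range: tuple[float, float] = (0.7, 0.9)
    trait: Optional[tuple[str, str]] = None   # ("tissue"|"condition", level)
    effect: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("loadings must lie in (0, 1]")
        if self.trait is not None and self.trait[0] not in ("tissue", "condition"):
            raise ValueError("trait kind must be 'tissue' or 'condition'")


@dataclasses.dataclass
class PerturbationSpec:
    """A shift applied to one module in samples of a given condition.

    ``mode`` is ``"coherent"`` (delta added to the latent factor) or
    ``"incoherent"`` (per-gene shifts of matched magnitude but random sign).
    ``tissue`` optionally restricts the perturbed samples to one tissue.
    """

    module: int
    delta: float
    mode: str = "coherent"
    condition: str = "perturbed"
    tissue: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("coherent", "incoherent"):
            raise ValueError("perturbation mode must be 'coherent' or 'incoherent'")


@dataclasses.dataclass
class SynthConfig:
    """Full study design for one generated dataset (plus optional second)."""

    n_genes: int = 3000
    tissues: Sequence[str] = tuple(TISSUES_10)
    conditions: Sequence[str] = ("syn", "allo")
    replicates: int = 3
    modules: Sequence[ModuleSpec] = ()
    perturbations: Sequence[PerturbationSpec] = ()
    second_dataset: Optional[Sequence[bool]] = None   # preserved flag per module
    noise_sd: float = 1.0
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("sum of module sizes exceeds n_genes")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if self.second_dataset is not None and len(self.second_dataset) != len(self.modules):
            raise ValueError("second_dataset needs one preserved flag per module")

    @property
    def n_samples(self) -> int:
        return len(self.tissues) * len(self.conditions) * self.replicates


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of the planted structure."""

    assignments: pd.Series               # gene -> module (0 = background)
    loadings: pd.Series                  # gene -> lambda (0 for background)
    factors: pd.DataFrame                # module x sample latent factors
    trait_effects: dict                  # module -> (kind, level, effect)
    perturbations: list                  # list of PerturbationSpec
    perturbation_shift: pd.Series        # gene -> signed per-sample shift applied
    preserved: Optional[dict] = None     # module -> bool (second dataset)
    assignments2: Optional[pd.Series] = None
    factors2: Optional[pd.DataFrame] = None


@dataclasses.dataclass
class SyntheticData:
    expr: ExpressionDataset
    design: TraitDesign
    truth: SyntheticTruth
    expr2: Optional[ExpressionDataset] = None
    design2: Optional[TraitDesign] = None


def _design(config: SynthConfig, suffix: str = "") -> TraitDesign:
    rows = []
    for tissue in config.tissues:
        for cond in config.conditions:
            for rep in range(1, config.replicates + 1):
                rows.append({"sample_id": f"{tissue}.{cond}.r{rep}{suffix}",
                             "tissue": tissue, "condition": cond, "replicate": rep})
    return TraitDesign(pd.DataFrame(rows).set_index("sample_id"))


def _perturbed_mask(design: TraitDesign, spec: PerturbationSpec) -> np.ndarray:
    t = design.table
    mask = (t["condition"].astype(str) == spec.condition).to_numpy()
    if spec.tissue is not None:
        mask &= (t["tissue"].astype(str) == spec.tissue).to_numpy()
    return mask


def _simulate(config: SynthConfig, design: TraitDesign, rng: np.random.Generator,
              assignments: np.ndarray, loadings: np.ndarray,
              apply_perturbations: bool) -> tuple[np.ndarray, pd.DataFrame, pd.Series]:
    """One dataset realization given gene->module structure and loadings."""
    t = design.table
    ns = len(t)
    x = np.empty((config.n_genes, ns))
    factors = {}
    shift = np.zeros(config.n_genes)
    for mi, mod in enumerate(config.modules, start=1):
        members = np.flatnonzero(assignments == mi)
        f = rng.standard_normal(ns)
        if mod.trait is not None:
            kind, level = mod.trait
            ind = (t[kind].astype(str) == level).to_numpy().astype(float)
            f = f + mod.effect * ind
        if apply_perturbations:
            for spec in config.perturbations:
                if spec.module == mi and spec.mode == "coherent":
                    f = f + spec.delta * _perturbed_mask(design, spec)
        factors[mi] = f
        lam = loadings[members][:, None]
        noise = rng.standard_normal((members.size, ns)) * (config.noise_sd * np.sqrt(1 - loadings[members]))[:, None]
        x[members] = lam * f[None, :] + noise
        if apply_perturbations:
            for spec in config.perturbations:
                if spec.module == mi:
                    if spec.mode == "coherent":
                        shift[members] = loadings[members] * spec.delta
                    else:
                        signs = rng.choice([-1.0, 1.0], size=members.size)
                        gshift = signs * loadings[members] * spec.delta
                        shift[members] = gshift
                        x[members] += gshift[:, None] * _perturbed_mask(design, spec)[None, :]
    background = np.flatnonzero(assignments == 0)
    x[background] = rng.standard_normal((background.size, ns)) * config.noise_sd
    x += config.baseline
    fdf = pd.DataFrame(factors, index=t.index).T if factors else pd.DataFrame(columns=t.index)
    return x, fdf, pd.Series(shift)


def generate(config: SynthConfig) -> SyntheticData:
    """Generate the dataset(s), design and ground truth for a configuration."""
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    assignments = np.zeros(config.n_genes, dtype=int)
    loadings = np.zeros(config.n_genes)
    cursor = 0
    for mi, mod in enumerate(config.modules, start=1):
        sl = slice(cursor, cursor + mod.size)
        assignments[sl] = mi
        loadings[sl] = rng.uniform(*mod.loading_range, size=mod.size)
        cursor += mod.size

    design = _design(config)
    x, factors, shift = _simulate(config, design, rng, assignments, loadings, True)
    expr = ExpressionDataset(x, gene_ids, design.sample_ids, "dataset1")

    truth = SyntheticTruth(
        assignments=pd.Series(assignments, index=gene_ids, name="module"),
        loadings=pd.Series(loadings, index=gene_ids, name="loading"),
        factors=factors,
        trait_effects={mi: (m.trait[0], m.trait[1], m.effect)
                       for mi, m in enumerate(config.modules, start=1) if m.trait is not None},
        perturbations=list(config.perturbations),
        perturbation_shift=pd.Series(shift.to_numpy(), index=gene_ids, name="shift"),
    )

    expr2 = design2 = None
    if config.second_dataset is not None:
        # scrambled modules hand their structure to random genes outside the
        # preserved modules; their original members revert to background noise
        assignments2 = np.zeros(config.n_genes, dtype=int)
        loadings2 = np.zeros(config.n_genes)
        preserved_map = {}
        taken: set[int] = set()
        for mi, (mod, keep) in enumerate(zip(config.modules, config.second_dataset), start=1):
            preserved_map[mi] = bool(keep)
            if keep:
                members = np.flatnonzero(assignments == mi)
                assignments2[members] = mi
                loadings2[members] = loadings[members]
                taken.update(members.tolist())
        for mi, (mod, keep) in enumerate(zip(config.modules, config.second_dataset), start=1):
            if not keep:
                pool = np.setdiff1d(np.arange(config.n_genes), np.fromiter(taken, int, len(taken)))
                members = rng.choice(pool, size=mod.size, replace=False)
                assignments2[members] = mi
                loadings2[members] = rng.uniform(*mod.loading_range, size=mod.size)
                taken.update(members.tolist())
        design2 = _design(config, suffix=".d2")
        x2, factors2, _ = _simulate(config, design2, rng, assignments2, loadings2, False)
        expr2 = ExpressionDataset(x2, gene_ids, design2.sample_ids, "dataset2")
        truth.preserved = preserved_map
        truth.assignments2 = pd.Series(assignments2, index=gene_ids, name="module")
        truth.factors2 = factors2

    return SyntheticData(expr, design, truth, expr2, design2)


# ---------------------------------------------------------------------------
# presets


def standard_scenarios() -> dict[str, SynthConfig]:
    """Named study-condition presets used throughout the tests and examples.

    - ``recovery``: 3000 genes, 6 modules of 50-200 genes (loadings
      0.7-0.9), 10 tissues x 2 conditions x 3 replicates = 60 samples,
      tissue/condition-linked factors with effect 2.0 — module discovery.
    - ``trait_calibration`` / ``trait_null``: smaller gene count for the
      module-trait power/null calibration (effects 2.0 / 0.0).
    - ``preservation``: two datasets; modules 1-3 preserved, 4-6 scrambled.
    - ``modde_coherent`` / ``modde_incoherent``: a strong (delta = 2 on the
      latent scale) perturbation of module 1 in the 'perturbed' condition,
      shifting it with or against its correlation structure.
    - ``modde_null``: 20 correlated modules, no condition effect.
    - ``two_species``: a preserved second dataset for symbol-mapped
      cross-dataset module conservation.
    """
    tissue_links = ["blood", "spleen", "pLN", "LP", "epidermis"]

    def linked_modules(sizes, effect, loading=(0.7, 0.9)):
        mods = []
        for i, size in enumerate(sizes):
            if i < len(tissue_links):
                trait = ("tissue", tissue_links[i])
            else:
                trait = ("condition", "allo")
            mods.append(ModuleSpec(size, loading, trait, effect))
        return mods

    scenarios: dict[str, SynthConfig] = {}
    scenarios["recovery"] = SynthConfig(
        n_genes=3000, tissues=TISSUES_10, conditions=("syn", "allo"), replicates=3,
        modules=linked_modules([200, 170, 140, 110, 80, 50], effect=2.0), seed=11)
    scenarios["trait_calibration"] = SynthConfig(
        n_genes=1000, tissues=TISSUES_10, conditions=("syn", "allo"), replicates=3,
        modules=linked_modules([120, 100, 90, 80, 70, 60], effect=2.0), seed=13)
    scenarios["trait_null"] = SynthConfig(
        n_genes=1000, tissues=TISSUES_10, conditions=("syn", "allo"), replicates=3,
        modules=linked_modules([120, 100, 90, 80, 70, 60], effect=0.0), seed=17)
    scenarios["preservation"] = SynthConfig(
        n_genes=2000, tissues=TISSUES_10, conditions=("syn", "allo"), replicates=3,
        modules=linked_modules([200, 160, 130, 100, 70, 50], effect=2.0),
        second_dataset=[True, True, True, False, False, False], seed=19)
    perturbed = [ModuleSpec(150, (0.7, 0.9), ("tissue", "epidermis"), 2.0)] + [
        ModuleSpec(s, (0.7, 0.9), ("tissue", t), 2.0)
        for s, t in zip([120, 100, 80, 60, 50], ["blood", "spleen", "pLN", "LP", "dermis"])]
    # the modde presets carry an unperturbed second dataset: the reference
    # experiment on which modules and kME are defined, so that the tested
    # perturbation cannot leak into the module orientation
    scenarios["modde_coherent"] = SynthConfig(
        n_genes=1500, tissues=TISSUES_10, conditions=("control", "perturbed"), replicates=3,
        modules=perturbed, perturbations=[PerturbationSpec(1, 2.0, "coherent", "perturbed")],
        second_dataset=[True] * len(perturbed), seed=23)
    scenarios["modde_incoherent"] = SynthConfig(
        n_genes=1500, tissues=TISSUES_10, conditions=("control", "perturbed"), replicates=3,
        modules=perturbed, perturbations=[PerturbationSpec(1, 2.0, "incoherent", "perturbed")],
        second_dataset=[True] * len(perturbed), seed=29)
    scenarios["modde_null"] = SynthConfig(
        n_genes=1000, tissues=TISSUES_10, conditions=("control", "perturbed"), replicates=3,
        modules=[ModuleSpec(40, (0.6, 0.9)) for _ in range(20)],
        second_dataset=[True] * 20, seed=31)
    scenarios["mini"] = SynthConfig(
        n_genes=400, tissues=("blood", "spleen", "pLN", "dermis", "epidermis"),
        conditions=("syn", "allo"), replicates=3,
        modules=[ModuleSpec(60, (0.7, 0.9), ("tissue", "blood"), 2.0),
                 ModuleSpec(50, (0.7, 0.9), ("tissue", "epidermis"), 2.0),
                 ModuleSpec(40, (0.7, 0.9), ("condition", "allo"), 2.0)],
        perturbations=[PerturbationSpec(2, 2.0, "coherent", "allo")],
        second_dataset=[True, False, True], seed=41)
    scenarios["two_species"] = SynthConfig(
        n_genes=1200, tissues=TISSUES_10, conditions=("syn", "allo"), replicates=3,
        modules=linked_modules([150, 120, 100, 80, 60, 50], effect=3.0),
        second_dataset=[True] * 6, seed=37)
    return scenarios
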