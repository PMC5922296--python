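# Methods

modscape implements weighted gene coexpression network analysis (WGCNA-style
module discovery) for multi-tissue bulk transcriptomics, together with the
downstream machinery that turns modules into biology: module–trait mapping,
cross-dataset preservation statistics, a direction-aware module-level
differential-expression test (modDE), and signature enrichment. This note
records the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic benchmark does and does not demonstrate.

## Network construction and module detection

Input is a genes × samples matrix of log2-scale, normalized expression with
no missing values (missingness is resolved at load time — by default genes
with any missing value are dropped — so that all correlation machinery can
assume complete matrices). Duplicate gene identifiers are collapsed to the
highest-variance row, the usual array-probe convention.

The network is built from the gene–gene Pearson correlation matrix `r`,
soft-thresholded into an adjacency:

- `signed_hybrid` (default): `a_ij = r_ij^β` for `r_ij > 0`, else 0. This
  prevents anti-correlated programs (e.g. lymphoid- vs target-organ-skewed
  genes) from fusing into one module.
- `unsigned`: `a_ij = |r_ij|^β`, for fidelity to older conventions.

The soft power β can be chosen by the scale-free-topology criterion: the
connectivity distribution is binned (10 equal-width bins), and the R² of the
log₁₀(frequency) vs log₁₀(mean connectivity) regression is computed, signed
so that positive slopes score 0. The smallest candidate power reaching
R² ≥ 0.8 is chosen; if none does, the canonical default β = 6 is used with a
warning. Caveat: near-zero connectivity distributions (e.g. pure noise at
high powers) can *also* look scale-free under this index, so a satisfied
criterion is not by itself evidence of modular structure; module detection
and preservation statistics are the real arbiters.

Adjacency is smoothed into the topological overlap matrix

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

with `k` the connectivity (zero-diagonal row sums) and `TOM_ii = 1`. Genes
are clustered by average-linkage hierarchical clustering of `1 − TOM` and
cut with a simplified dynamic-hybrid procedure:

1. static cut of the dendrogram at height 0.995;
2. recursive binary splitting of each branch, up to `deep_split` (default 2)
   levels, accepted only when both children have at least `min_size`
   (default 30) genes;
3. a PAM-like membership pass: eigengenes of the branch cores are computed,
   and every gene is assigned to the module of maximal kME provided that
   kME exceeds 0.4 (otherwise the gene is left unassigned, module 0). This
   both rescues stray genes and expels genes a branch absorbed through
   chance correlation with its latent profile — without this pass, planted
   modules systematically absorb ~30–50% extra background genes;
4. iterative merging of modules whose eigengenes correlate above
   `1 − merge_threshold` (default correlation 0.75);

Final modules are renumbered 1..k by descending size (module 0 collects
unassigned genes). The procedure is fully deterministic and invariant to
sample reordering; a seed argument exists only for provenance recording.

A module eigengene is the first principal component of the module's
per-gene-standardized expression, scaled to mean 0 / unit variance (ddof 1)
across samples and oriented so that the mean member kME is positive; an
exactly balanced module is oriented by the loading of its lexicographically
first member. kME (module membership / intramodular connectivity) is the
Pearson correlation of each gene with each eigengene, with two-sided p from
the exact t transform `t = r√((n−2)/(1−r²))` and Benjamini–Hochberg q
computed per module across genes (matching the per-module FDR coloring used
in hub-network figures). Driver genes are the top members by own-module kME,
ties broken lexicographically.

## Module–trait mapping, classification, MDS

Traits are 0/1 sample indicators — one per tissue, one per condition, plus
configured tissue groups (e.g. secondary lymphoid organs vs target organs).
Module–trait association is the point-biserial Pearson correlation of
eigengene vs indicator with the exact t-based p; constant indicators report
r = 0, p = 1 with a warning. Modules are ranked per trait at the
−log₁₀(p) > 2 cutoff (p = 0.01) and classified from the pattern of
*positive* significant tissue correlations: one tissue → `tissue_specific`;
several tissues within one group → `group_selective`; tissues in more than
one group → `bridging`; none → `unassociated`. Negative associations are
reported but do not drive labels, since the labels describe where a module
is expressed.

Sample maps use Torgerson classical MDS (double-centered squared distances,
top eigenvectors scaled by √eigenvalue), by default on Euclidean distances
over the 500 most variable genes; a correlation metric (1 − r) is available.
Negative eigenvalues (non-Euclidean inputs) are clamped to zero with a
warning when they are material to the requested dimensions. Exactly
embeddable distance matrices are reproduced up to rigid motion at machine
precision.

## Module preservation

Whether a module found in a reference dataset is "real" is judged by whether
its topology recurs in an independent dataset. For each reference module,
two statistics are computed in the test data with the same adjacency
parameters:

- density: mean off-diagonal adjacency among the module's genes;
- connectivity: Pearson correlation between the intramodular connectivity
  vectors (kIM, within-module adjacency row sums) computed in reference vs
  test data over shared module genes.

A null is built from `n_perm` (default 200) random gene sets of identical
size drawn from the genes shared by both datasets *excluding the module
under test* (preventing leakage of the module's own signal into the null).
Z = (observed − null mean)/null sd per statistic and
`Z_summary = (Z_density + Z_connectivity)/2`. The canonical reference
statistic is a median over a larger family; this two-component mean is a
documented simplification that keeps the established threshold semantics:
Z_summary < 2 not preserved, 2–10 weak-to-moderate, ≥ 10 strong. Modules
whose gene overlap with the test data falls below half their size are
flagged not evaluable; a zero-spread null flags the module degenerate
rather than reporting an infinite Z. Because random null sets can contain
fragments of *other* (preserved) modules, the connectivity null is not
centered at zero and Z_connectivity is the weaker component; Z_summary is
dominated by density in practice, which is also where the separation
between preserved and scrambled modules is cleanest.

## modDE

modDE asks, per module m with member genes g: is there an excess of
differentially expressed genes, and is the *direction* of differential
expression consistent with the module's correlation structure? Per-gene
evidence comes from a Welch two-sample t-test on log2 values (robust and
assumption-light at n ≈ 3/group; moderated-variance tests would be a
natural extension), converted to a signed z, `z_g = Φ⁻¹(1 − p_g/2)·sign(effect_g)`.
The consistency statistic is a kME-signed, kME-weighted Stouffer
combination,

    T_m = Σ_g w_g s_g z_g / √(Σ_g w_g²),   s_g = sign(kME_gm), w_g = |kME_gm|.

Because member genes are strongly correlated, the analytic Stouffer null is
wrong; T_m is instead calibrated by permuting condition labels among
samples, within tissue strata whenever the design spans several tissues (so
condition effects are never confounded with tissue). The consistency p is
the two-sided add-one-corrected empirical p (hence p ≥ 1/(n_perm+1); at
least 20 distinct stratified permutations are required). The excess
component counts member genes with p < α₀ (default 0.05) against the
hypergeometric expectation over all genes. The headline module p is the
consistency p; the excess p is reported alongside rather than multiplied in,
because the two components are dependent and no principled combination rule
is assumed. BH q-values are computed across modules per component.

Two design points matter in practice:

- kME orientation should come from a reference experiment, not from the
  perturbed data being tested. A strong mean shift between groups is itself
  a rank-one component of the sample covariance; estimated on the perturbed
  data, it contaminates eigengene/kME orientation and an incoherent shift
  masquerades as coherent. The benchmark scenarios therefore estimate
  modules on an unperturbed reference dataset, mirroring a two-experiment
  design (network atlas first, perturbation experiment second).
- T_m is exactly invariant to flipping the sign of any member gene's
  expression (kME and z flip together), and symmetric about zero under the
  null.

## Enrichment primitives

- Hypergeometric overlap: upper-tail `P[X ≥ k]` for the intersection of two
  sets inside an explicit universe (genes outside the universe are dropped
  with logged counts); symmetric in the two sets; exact to enumeration.
- Preranked GSEA: weighted Kolmogorov–Smirnov running sum on a descending
  ranked list (ties broken by gene id, so results are platform-independent);
  hit steps ∝ |score|^weight, miss steps uniform; ES is the signed extreme
  deviation, with ES = 1 by convention for an all-hit list. The null
  permutes gene labels (not phenotypes — the typical use here has no
  phenotype replicates); NES = ES / mean |same-sign null ES|; nominal p and
  q come from the same-sign null pool with add-one correction.
- ssGSEA: per sample, genes are ranked by expression (descending, ties by
  gene id; the top gene carries rank N) and the score is the summed
  difference between the rank^α-weighted hit ECDF and the uniform miss ECDF
  (α = 0.25), optionally normalized by the global score range. Scores are
  rank-based, hence invariant to per-sample monotone shifts.
- Cross-dataset module conservation maps module gene sets through an
  explicit orthology/symbol table (an upper-casing fallback exists for
  mouse→human symbol style) and runs preranked GSEA per module against an
  externally ranked list; modules mapping to fewer than 5 listed genes are
  skipped with a warning.

## Synthetic data generator

The generator emulates a sorted-cell multi-tissue atlas: ~10 tissues
(blood, spleen, peripheral and mesenteric lymph nodes, bone marrow, liver,
gut lamina propria and intraepithelial compartments, dermis, epidermis) ×
conditions × 3 replicates. Each planted module m has a per-sample latent
factor

    f_m(s) = effect·1[trait(s)] + δ·1[perturbed(s)] + N(0,1),

and member genes `x_g(s) = λ_g f_m(s) + N(0, σ²(1−λ_g²)) + baseline` with
loadings λ_g ~ U(λ_lo, λ_hi). With the default σ = 1 the loading λ_g *is*
the gene–factor correlation, which makes the loading range directly
interpretable; this per-gene noise scaling is this package's convention.
Background genes are N(0, σ²) noise around the baseline (8.0, a typical
log2 microarray intensity). An optional second dataset regenerates factors
with identical membership and loadings for preserved modules and hands a
scrambled module's structure to randomly chosen other genes (its original
members reverting to noise). The incoherent perturbation bypasses the
factor and adds `r_g·λ_g·δ` directly to each member gene in perturbed
samples, with r_g = ±1 i.i.d.: per-gene effect magnitudes exactly match the
coherent mode (whose per-gene effect is λ_g·δ), so the two modes differ
*only* in direction consistency — precisely the contrast modDE claims to
detect. Everything is reproducible bitwise from the seed.

Preset study conditions (`standard_scenarios()`): the recovery preset uses
3000 genes, six modules of 200/170/140/110/80/50 genes, λ ∈ [0.7, 0.9],
10 tissues × 2 conditions × 3 replicates (60 samples), with five modules
tied to tissues and one to a condition at effect 2.0 (a two-sd latent
shift, i.e. a clear but not overwhelming tissue program). The modDE
presets perturb an epidermis-linked module at δ = 2.0 across the
'perturbed' condition: on the latent scale this is a two-sd shift, chosen
to emulate the very strong depletion effects this class of experiment
reports; smaller δ are exercised by the monotone-power tests. modDE null
calibration uses 20 correlated 40-gene modules with no condition effect.
Problem sizes of the benchmark runs (20 seeds for recovery and
preservation, 50 for trait calibration, 1000 null module tests, 10⁴
permutations for the headline coherent test) were fixed as
single-workstation-scale study conditions.

What the generator does *not* emulate — and hence what passing benchmarks
cannot show about real data: heteroskedastic (intensity-dependent) noise,
heavy-tailed outliers, batch structure, nested or overlapping modules,
correlated background genes, and count-based (RNA-seq) sampling noise. The
single-factor-per-module model is analytically transparent and sufficient
for every property the pipeline tests, but real modules are messier; the
defaults (min_size 30, merge threshold 0.25, kME membership 0.4) are
canonical rather than optimal for any particular dataset.

## Numerical conventions and degenerate inputs

- Correlation p-values use the exact t transform; |r| = 1 maps to the
  smallest representable positive p (1e-300 floor) so signed z-scores stay
  finite.
- Variance and standardization use ddof = 1 throughout.
- Zero-variance genes are an error in correlation contexts (callers filter
  first); zero-variance Welch denominators yield t = 0 (equal means) or
  ±∞ → p floor (unequal means).
- Eigengene sign ties are broken by the lexicographically first member's
  loading; GSEA ranking ties by gene id; driver-gene ties lexicographically.
- Modules smaller than `min_size` after any stage dissolve into module 0;
  a dataset with fewer genes than `min_size` yields an all-unassigned
  result with a warning.
- All permutation machinery draws from `numpy.random.default_rng(seed)`
  with a fixed draw order, so fixed seeds give bitwise-identical results.

## Known limitations

- Biweight midcorrelation is not implemented (Pearson only).
- The preservation composite uses two statistics rather than the canonical
  larger family; Z_connectivity is noisy when random null sets overlap
  other real modules (see above).
- modDE's gene-level test is unmoderated Welch; with 2–3 replicates per
  arm, per-gene power is limited and the module-level aggregation is doing
  the statistical work.
- The CLI recomputes eigengenes/kME from assignments rather than
  serializing the full module object; this is deterministic but assumes the
  expression file is unchanged between stages (input hashes in the manifest
  make violations detectable).
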