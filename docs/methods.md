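# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical choices a user re-deriving results should know about.

## Data model and normalization

Expression is held genes × cells with a layer tag (`counts`, `lognorm`,
`imputed`). Counts are depth-normalized per cell and transformed as
`log(1 + s·c/total)` with natural log and scale factor `s = 10⁴` (a
convention; the base and scale only rescale monotonically, and every
downstream score is rank- or comparison-based). Cells with zero totals are
kept as all-zero profiles with a warning rather than dropped, so cell-id
alignment with annotation never silently changes.

TMA H-scores are long-format `(core, marker, score)` rows on a 0–200 scale
(Ki-67 proliferation index 0–100). A missing stain is an absent row, never a
zero: zero is a valid biological measurement (marker-negative tumor), so
conflating the two would bias concordance estimates downward.

## Regulon activity (AUCell-style)

Per cell, genes are ranked by descending expression; with
`T = ⌈top_fraction·n_genes⌉` and `hits(r)` the number of regulon genes at
rank ≤ r, activity is `Σ_{r≤T} hits(r)` divided by its maximum
`Σ_{r≤T} min(r, m)` (m regulon genes present), giving a value in [0, 1].

- `top_fraction = 0.05`: the standard recovery-window convention for this
  score; exposed in `AnalysisConfig`.
- Ties are abundant in sparse counts, so tie-breaking is a seeded random
  permutation shared across cells; `tie_break="gene_id"` gives a fully
  deterministic alternative for exact-reproduction runs.
- A regulon with no gene in the matrix scores NaN (missing), never 0 — a 0
  is a meaningful "no regulon gene highly ranked" observation.

The scaled view z-scores each regulon across cells (population moments) and
clips to ±2 (`zclip`), matching the convention of displaying activities on a
−2..2 z scale; constant regulons map to 0.

## GRN discovery

Cells are clustered with Ward linkage on Euclidean distances over the
scaled, clipped activity matrix (the metric/linkage pair was an open choice;
Ward on standardized features is the default recommendation for compact
states and makes the merge heights interpretable as variance increments).

**Cut selection.** The number of states is chosen by resampling stability:
for each candidate k (default 2..15), the full-data cut is compared by ARI
with cuts re-estimated on twenty 80 % subsamples; the k with the highest
mean ARI wins, ties toward smaller k (parsimony). The full
`(k, mean ARI, sd)` profile is exported so the chosen cut is auditable, and
the cut height realizing k is recorded on the dendrogram. Degenerate input
(all cells identical) returns a single state with an empty profile rather
than an arbitrary split. This stability criterion is deterministic given the
seed; on planted 5-state cohorts with effect size 8 it recovers k exactly
(see `scripts/acceptance.py`).

**RSS.** A regulon's raw non-negative activities are normalized to a
probability vector over cells and compared with the uniform distribution on
a cluster via base-2 Jensen–Shannon divergence: `RSS = 1 − √JSD ∈ [0, 1]`,
with exactly 0 for disjoint support (the reason for base-2 logs) and
invariance to positive rescaling of the activity vector. Raw rather than
z-scaled activities are used because the JSD construction requires a
non-negative measure. Significance is by label permutation (default 1000;
warning below 100 since resolution is 1/n_perm) with a +1 continuity
correction and BH adjustment within each cluster.

**Robustness.** Leave-one-unit-out (typically per patient): remove the
unit's cells, recluster at the same k, report ARI on the retained cells. A
state private to one unit collapses by construction when that unit is held
out; multi-unit states should hold ARI near 1.

## Patient-diversity entropy

Clustering is PhenoGraph-style: PCA (30 components), kNN (k = 30),
shared-neighbour Jaccard edge weights, Leiden modularity at resolution 1.0,
seeded. Note that modularity at this resolution can subdivide large
homogeneous groups (a well-known property); this is harmless here because
clusters serve as sampling strata for entropy, not as state estimates —
subdividing a stratum leaves its patient composition unchanged.

Entropy is `−Σ p ln p` (natural log; the base rescales all values equally
and comparisons are rank-based). To keep cluster size from confounding the
comparison, each cluster is resampled 100 times at 100 cells with
replacement (so clusters below 100 cells are still usable) and all
repetitions are retained. Group comparisons use the two-sided Wilcoxon
rank-sum test on per-cluster mean entropies — the groups are unpaired
cluster sets, so the rank-sum form is the applicable one; the signed-rank
test remains available for genuinely paired inputs. Significance tiers
follow the conventional star thresholds 0.05 / 0.01 / 0.001 / 10⁻⁴.

## Diffusion imputation

A Markov matrix over cells is built from a kNN graph in PCA space (20
components by default — the neighbourhood space is an open choice and is
configurable): adaptive Gaussian kernel with per-cell bandwidth equal to the
distance to the ⌈k/3⌉-th neighbour, self-affinity 1, symmetrization by the
mean, row normalization. Imputation averages each cell over its
neighbourhood t times (`X ← X·(Mᵗ)ᵀ`), so per-gene value ranges are
preserved and t = 0 is the identity. With two cells at distance d and k = 1
the transition weights are (1, e⁻¹)/(1 + e⁻¹) — the self-affinity keeps the
walk lazy; a unit-weight kernel would give (½, ½) instead.

## Marker statistics

- **Lin's CCC** uses population (1/n) moments; the default 95 % CI applies
  Lin's asymptotic variance on the Fisher-z scale, with a seeded percentile
  bootstrap as the small-n alternative.
- **Wilcoxon tests** are exact for small tie-free samples (rank-sum
  n_x+n_y ≤ 12, signed-rank n ≤ 15) and normal-approximated with tie
  correction otherwise; all-zero paired differences report p = 1.
- **Hurdle DE**: per gene, a binomial LRT on the detection indicator plus a
  Gaussian LRT on log-normalized expression among detected cells; the
  combined statistic is the sum of the two chi-squares with summed df,
  dropping inestimable parts (constant detection, single-group detection).
  This is a deliberate simplification of the full hurdle framework — no
  cellular-detection-rate covariate and no coefficient shrinkage — because
  only gene-level log2FC and adjusted p feed the downstream overlap
  analysis; the group argument is a hook where a covariate design could be
  added. log2FC is `log2((mean_A+1)/(mean_B+1))` on depth-normalized means
  (pseudocount 1 keeps it finite for one-group detection); note model-based
  fold changes from a fitted hurdle would differ slightly. Type-I error is
  calibrated within 2 binomial SEs of nominal at α ∈ {0.01, 0.05} under a
  2000-gene label-split null (recomputed by the acceptance script).
- **Overlap**: one-sided hypergeometric tail (Fisher exact) for DEG-set
  enrichment; cross-cohort "shared" genes must pass |log2FC| > 0.4 and
  BH-adjusted p < 0.05 in both cohorts with matching sign.
- "P_adj" is Benjamini–Hochberg throughout (the common companion of
  hurdle-style DE); the adjustment is a single exposed function.

## Synthetic generators

**Cohort.** Counts are negative binomial with size (dispersion) 10 and
baseline mean 2: `mean = baseline × effect^{[gene ∈ state's regulon]} ×
fold^{[antigen coupled to state]}`. Defaults: 5 states × 120 cells, 18-gene
regulons over 500 background genes, effect 8 — a compact cohort whose
planted structure is strong enough to be recoverable yet small enough that
the full 20-seed acceptance sweep runs in seconds. Patients are drawn per
state from Dirichlet-distributed frequencies over 8 patients: concentration
0.05 concentrates a state in one patient (the patient-specific,
treatment-resistant pattern), 50 spreads it evenly (the shared pattern);
state categories default accordingly (`CRPC_adeno` vs `naive_CSPC`).
Negative binomial was chosen over zero-inflated models: at these means,
dropout arises naturally from the count distribution, which is sufficient
for rank-based downstream scores. Not emulated: batch effects, doublets,
gene-length/GC bias, library-size variation beyond NB sampling, ambient
RNA — so passing recovery tests demonstrates correctness of the inference
machinery, not robustness to those artifacts.

**Two cohorts.** Both cohorts share one gene universe; shared states plant
identical regulon gene sets, private states use disjoint sets whose targets
stay at baseline in the other cohort. This makes cross-cohort DEG overlap
well-defined with an honest negative control.

**H-scores.** For a pair of new markers, both are `center + latent + noise`
with latent variance solved from `CCC = τ²/(τ² + σ²)` (sign via the latent's
sign), so the pre-clipping population CCC equals the target exactly. A pair
may reuse one already-generated marker (hub markers such as ASCL1): the new
marker is regressed on the existing one with matched mean and variance,
which again fixes the population CCC. Scores are clipped to [0, 200]
(Ki-67 halved to 0–100); with the default center 100 and noise sd 15 the
clipped mass is ≈1 %, shrinking realized CCC by well under the sampling
tolerance used in tests (±0.05 at the test sizes). Targets of exactly ±1
require zero noise (the closed form is otherwise infeasible and raises).

## Problem sizes and determinism

Acceptance-level computations use: 20 simulation seeds for cut-selection
recovery (600 cells × 590 genes each), a 1200-cell 10-state cohort for the
entropy contrast, 2000 null genes (200 vs 200 cells) for DE calibration,
and 2000 TMA cores for concordance recovery — sizes at which the measured
quantities' sampling noise is small relative to the assertions made about
them. Every stochastic step takes an explicit seed; the pipeline derives
per-stage seeds by stable hashing of stage names from one global seed, so
outputs are byte-identical across reruns and adding a stage never perturbs
earlier stages.

## Known limitations

- Regulon *inference* (co-expression plus motif pruning) is out of scope;
  regulons are consumed as GMT gene sets.
- The hurdle DE model omits covariates; strong cell-level confounds (e.g.
  detection-rate differences between groups) would inflate its statistics.
- Stability-based cut selection assumes the activity space separates states;
  overlapping states with effect sizes near 1 select conservative k.
- The CCC confidence interval is asymptotic; below n ≈ 20 prefer the
  bootstrap option.
- Leiden at resolution 1.0 may split large homogeneous clusters; for
  state-count estimates use the dendrogram/ARI machinery, not the graph
  clustering.
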