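# Methods

## Model and estimation

### Linear model and BLUP solver

All parametric prediction rests on the additive marker model
y = μ + Zu + e with u ~ N(0, I σ²u) and e ~ N(0, I σ²e). The intercept is
estimated as the training phenotype mean; no other fixed effects are
modelled (the breeding data the package targets carry none that survive to
the prediction stage). Marker columns are centered by their training means
but not variance-scaled: any per-marker scaling is absorbed into λ, and
centering alone keeps the GEBV of an average genotype identically μ̂.

The solver uses the n×n dual (kinship) system
û = Zcᵀ(ZcZcᵀ + λI)⁻¹(y − μ̂): training sizes (hundreds to ~2000 hybrids)
are far below marker counts (10³–10⁴), so the dual solve is the cheap
direction. Cholesky factorization is used with a 1e-8 jitter retry on
failure. The primal/dual (GBLUP) equivalence is exercised by oracle tests
rather than assumed.

### Choosing λ

* `reml` (rrBLUP default): the training kinship K = ZcZcᵀ is rescaled by its
  mean diagonal c so it behaves like a correlation-scale GRM, single-component
  REML estimates h², and λ = c(1 − h²)/h². This is what canonical
  ridge-BLUP implementations effectively do.
* `cv_grid`: 25 log-spaced candidates spanning [10⁻³·c, 10³·c], 10-fold CV
  on mean squared prediction error, ties broken toward heavier shrinkage
  (the flatter region of the criterion).
* HEBLP|A: σ²u is the HE-regression slope on the standardized-phenotype
  scale, clamped to [0.01, 0.99] so λ = (1 − σ²u)/σ²u stays finite and
  positive, then mapped to the solver scale by the same mean-diagonal
  constant c. At equal λ the HEBLP|A and rrBLUP solutions are identical by
  construction; the methods differ only in how λ is chosen.

### Heritability

* REML: eigendecomposition G = U diag(d) Uᵀ reduces the model to independent
  coordinates with variances σ²p(h²dᵢ + 1 − h²); σ²p is profiled out
  analytically and h² maximized by bounded scalar search on
  [10⁻⁶, 1 − 10⁻⁶] (xatol 1e-6). Variance components are reported on the
  observed phenotype scale.
* HE regression: phenotypes are standardized (zero mean, unit variance), and
  the cross-products yᵢyⱼ over all i<j pairs are regressed on pairwise
  relatedness; the slope is σ²g on the unit-variance scale, i.e. h²
  directly. Standardization makes the estimate invariant to affine
  transformations of the trait. Estimates are clamped to [0, 1] with a flag.

  IBS similarity (1 − mean |dᵢ − dⱼ|/2) is an affine *compression* of the
  genomic relationship: its slope per unit relationship is roughly the mean
  marker heterozygosity (~0.2–0.3 for realistic panels), so regressing on
  raw IBS would overestimate σ²u several-fold. `compute_ibs` therefore
  stores an affine calibration (a, b) obtained by regressing the panel's own
  VanRaden GRM off-diagonals on the IBS off-diagonals, and HE regression
  applies it before fitting. Because the calibrated predictor is the
  projection of the GRM onto IBS, the OLS projection identity makes the HE
  slope an unbiased estimate of h² despite the compression. When the
  calibration cannot be computed (tiny panels) the fallback map
  (IBS − c)/(1 − c), c the mean off-diagonal, pins self-similarity at 1 and
  the average pair at 0.

* GRM: VanRaden scaling with observed allele frequencies — columns centered
  by 2p̂ and divided by √(2p̂(1 − p̂)), G = WWᵀ/m. Markers must be
  polymorphic and imputed first; the filter stage guarantees both.

### Ensemble baselines

Random forest (scikit-learn `RandomForestRegressor`) and gradient-boosted
trees (lightgbm `LGBMRegressor`) are fitted on the same marker matrix with
each library's default hyperparameters and a fixed seed, behind the same
predict contract as the parametric models. They serve as non-parametric
baselines; their internals are deliberately not re-implemented.

## Genotype handling

* Dosages are alt-allele counts 0/1/2 with NaN for missing; inbred parents
  are expected near-homozygous but dosage 1 is accepted on the real-data
  path.
* Marker retention (parental matrix, in order, first-failing attribution):
  (a) ≥2 distinct non-missing genotype classes, (b) missing fraction ≤ 0.3,
  (c) minor-allele frequency over non-missing calls ≥ 0.1. "Genotype
  classes" are the categories 0/1/2; MAF is computed over observed calls.
* F1 hybrid genotype = mean of the two parental dosages on the 0–2 scale,
  missing if either parent is missing. For fully inbred parents this is the
  exact F1 genotype; it keeps hybrids on the same additive scale as parents,
  so a cross's GEBV is the mean of its parents' GEBV deviations plus μ̂.
  Hybrid ids are canonicalized with the lexicographically smaller parent
  first, making (A,B) and (B,A) identical.
* Missing entries are imputed by the marker mean of observed calls after
  filtering and before any model fitting.

## Diallel analysis

The complete half-diallel of N parents holds N(N−1)/2 unordered crosses,
no selfs. Exhaustive prediction builds hybrid genotypes in batches (default
5000) so the full cross set is never materialized; batching provably does
not change predictions. Top-fraction selection takes floor(f·N) crosses with
ties broken by canonical pair order; genetic gain is the top-fraction mean
GEBV minus the overall mean (zero for an empty selection). GCA here is the
breeder's operational definition — a line's mean GEBV over its N−1 crosses —
not the classical least-squares diallel decomposition; the mean of GCAs
equals the overall cross mean exactly. Heterotic summaries report count,
mean and sd of GEBV per unordered group-pair category (k(k+1)/2 categories
for k groups), each category's share of requested top fractions, and the
share of top crosses with at least one parent in each group.

## Germplasm grouping

p-distance between lines is the complement of IBS over shared non-missing
markers. Trees come from Saitou–Nei neighbor joining (scikit-bio), which is
exact on additive (tree-metric) inputs; negative branch lengths are kept as
computed so that exactness is testable. Group assignment cuts an
average-linkage dendrogram of the p-distance matrix into k clusters, with
labels ordered by cluster size; curated labels loaded from a two-column file
are the primary path for real analyses, since no principled tree-cut rule
exists for germplasm delineation.

## Synthetic populations

The generator emulates a structured maize breeding program:

* **Group structure** — Balding–Nichols: ancestral allele frequency
  p ~ U(0.1, 0.9) per marker; each group draws its frequency from a Beta
  with mean p and variance F·p(1 − p). F (default 0.2) is the single
  differentiation knob; 0.2 gives three cleanly separable clusters without
  fixing alleles. Founders are fully homozygous (dosage 0/2) before
  missingness (default 2% missing calls), as befits inbred lines.
* **Architecture** — n_qtl markers (default 200 of 2000) get i.i.d. normal
  effects, rescaled so the genetic-value variance across founders is exactly
  1; h² then controls the noise variance exactly
  (σ²e = σ²g(1 − h²)/h²) and all downstream tolerances are scale-free.
* **Phenotypes** — simulated on hybrids only (the breeding program
  phenotypes crosses, not parents): genetic value + optional group-pair
  shift + Gaussian noise. h² = 1 means zero noise; h² = 0 is rejected.
* **Heterotic shifts** — an arbitrary map from unordered group pairs to
  trait-unit offsets. The demo plants a per-parent "tropic bonus"
  (+δ/2 per tropic parent, so tropic×tropic carries +δ): a purely additive
  marker model can represent a per-parent bonus exactly, whereas a bonus
  confined to one category alone is a parent-pair interaction whose
  GEBV-recoverable share is analytically only half. The per-parent pattern
  also matches the biology the package targets (tropical germplasm raising
  cross performance across the board).

What the generator does **not** emulate: linkage and recombination (markers
are exchangeable), dominance and epistasis, genotype-by-environment
interaction, allele-frequency spectra from real ascertainment, and
pedigree-correlated missingness. Passing tests therefore demonstrate
correctness of the machinery and statistical calibration under an idealized
additive world, not performance on any particular real panel.

## Problem sizes and numerical choices

Test and demonstration runs use deliberately scaled-down panels — typically
70–180 founder lines, 500–2000 markers, 300–2000 phenotyped hybrids, and
10 replicates — chosen so the full pipeline exercises every stage at
statistically meaningful sizes. Key tolerances: solver oracle agreement
1e-8; NJ exactness on additive metrics 1e-10; REML search tolerance 1e-6;
heritability-recovery band ±0.1 on means over 20 replicates; rrBLUP vs
HEBLP|A accuracy gap ≤ 0.05; planted-contrast recovery ≤ 0.25 genetic sd.
Degenerate inputs (monomorphic markers, fully missing loci, zero-variance
traits, empty hybrid sets, self-crosses, incomplete diallels) raise typed
errors early rather than propagating NaNs.

## Known limitations

* HE regression inherits the usual moment-estimator variance: at small n its
  spread is large, and strong planted group effects push the estimate to the
  upper clamp (the demo shows this deliberately).
* The IBS calibration requires ≥10 lines and at least two polymorphic
  markers; below that, the anchor-based fallback is biased upward.
* REML assumes a single genetic variance component; no GxE or dominance.
* p-distances need not satisfy the triangle inequality; NJ still runs, but
  the exactness guarantee applies only to additive inputs.
* GCA rankings from a GEBV table are as good as the underlying additive
  model: specific combining ability is invisible to it by construction.
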