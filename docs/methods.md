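# Methods

## Model

`omicsgp` fits, for one quantitative trait on *n* lines,

    y = 1 μ + Σₖ uₖ + ε,    uₖ ~ N(0, σₖ² Kₖ),    ε ~ N(0, σₑ² I),

a univariate Gaussian mixed model in which every random effect's covariance
is a kernel matrix over the same lines. Phenotypes are modelled one trait at
a time; the model assumes i.i.d. residuals (a single environment, no
genotype-by-environment structure) and additive combination of the kernel
terms.

## Kernels

**Preprocessing.** Transcriptomic and metabolomic features are mean-imputed
(column mean over observed lines) and then z-scored (mean 0, sample sd 1,
n−1 denominator); zero-variance features are dropped with a warning.
Genotype markers stay on 0/1/2 dosage coding for the VanRaden genomic
relationship matrix; missing dosages are mean-imputed and rounded back to
the nearest valid code. When markers feed a Gaussian or generic linear
kernel they are z-scored like any other layer. Imputation precedes
standardization so column means are taken on the raw scale. All layers of a
dataset are aligned to the lexicographically sorted intersection of their
line IDs; every kernel and phenotype vector inherits that order.

**Linear kernels.** `K = X Xᵀ / p` on standardized features; for markers,
VanRaden's `K = Z Zᵀ / (2 Σ pₖ(1−pₖ))` with `Z = M − 2p` and `pₖ` the
observed allele frequency. Both are positive semi-definite by construction.

**Gaussian kernels.** `K_ij = exp(−d²_ij / σ)` with `d²` the squared
Euclidean distance between standardized feature rows and `σ` the median of
the n(n−1)/2 *off-diagonal* squared distances. Including the diagonal zeros
in the median would bias the bandwidth downward, so they are excluded; the
diagonal of K is set to exactly 1. A dataset containing only identical rows
has median distance 0 and is rejected (degenerate bandwidth).

**Hybrid interaction kernels.** For two same-kind base kernels the product
`P = K₁K₂` is split into an upper triangle UT (diagonal included) and a
strictly lower triangle LT, each symmetrized: `K_CC = UT + UTᵀ`,
`K_PP = LT + LTᵀ`. Assigning the diagonal to exactly one triangle makes the
decomposition exact: `K_CC + K_PP = P + Pᵀ` entrywise, a property the test
suite checks on random inputs. Because `P` is generally asymmetric, the
symmetrized triangles need not be positive semi-definite even when both
bases are — `K_PP = P − diag(P)` is indefinite already for `P = 11ᵀ` — so
both are always passed through eigenvalue clipping (below) before serving
as covariances. Interactions are built linear×linear or Gaussian×Gaussian,
never mixed-kind. The Hadamard (entrywise) product kernel, the conventional
interaction term, is provided for comparison; by the Schur product theorem
it needs no repair.

**PSD repair and scaling.** `psd_repair` eigendecomposes a symmetric
matrix, clips negative eigenvalues to zero, reconstructs, and logs the
clipped mass (|negative| spectrum as a fraction of the absolute spectrum).
Every kernel entering a model is then divided by its mean diagonal so that
mean(diag K) = 1; variance components of kernels with different
constructions are thereby on a common per-line variance scale. Hybrid
CC/PP pairs are computed once per (layer pair, kind) and cached, so every
model reuses bitwise-identical kernels.

## The 24 predictors

A registry maps M1–M24 to ordered term lists written in a small grammar:
main terms `gL, tL, mL, gG, tG, mG` (layer × linear/Gaussian) and
interaction terms such as `gLtLCC` or `tGmGPP`. M1–M3/M12–M14 are
single-layer baselines, M4/M15 the additive three-layer models, M5–M11 and
M16–M22 add one to three CC/PP interaction pairs, M23 combines both
additive sets, and M24 adds the six Gaussian interaction kernels to M23
(12 terms). Custom predictors can be written in the same grammar; term
order (and hence sampler update order) follows the formula left to right.

## Gibbs sampler

Each kernel is eigendecomposed once (`K = Γ Λ Γᵀ`, eigenvalues below
1e-8 × λ_max dropped) and its effect parameterized as `uₖ = Bₖ δₖ` with
`Bₖ = Γ Λ^{1/2}` and `δₖ ~ N(0, σₖ² I)`. Since `BₖᵀBₖ = Λ` is diagonal,
every full conditional is Gaussian with diagonal precision and the update
of a whole term costs two n×r matrix–vector products; the sampler is exact
(no Metropolis steps) and stable for the n of a few hundred typical of
multi-omics panels.

Per iteration the sampler updates: the intercept μ (flat prior, Gaussian
full conditional); each term's δₖ; each σₖ² and σₑ² from
scaled-inverse-chi-square full conditionals; and the masked phenotype
entries from their Gaussian predictive distribution (data augmentation).
Priors are scaled-inverse-chi-square with df₀ = 5; the prior scales are set
so the prior modes allocate a fraction `prior_R2 = 0.5` of var(y observed)
equally across the kernel terms and the remainder to the residual — the
weakly informative convention of standard Bayesian genomic-prediction
software. Defaults: 6000 iterations, 1000 burn-in, thinning 5 (1000
retained draws per chain; at least 50 retained draws are enforced).

For validation the variance components can be held fixed
(`fixed_variances`) and the intercept pinned (`fix_mu`); the sampler's
stationary mean then equals the closed-form GBLUP/ridge solution
`û = K (K + λI)⁻¹ (y − ȳ)`, which the tests verify to Monte-Carlo
precision. The fit is exactly equivariant under rescaling of y (variances
scale by c², predictions' deviations from μ by c) because the prior scales
are proportional to var(y).

**Predictions** for masked lines are the posterior mean of `μ + Σₖ uₖ` at
those indices (equivalent to, and lower-variance than, averaging the
augmented draws).

**Convergence** is monitored with the Gelman–Rubin potential scale
reduction factor computed per variance parameter across independent chains,
`R̂ = sqrt(((m−1)/m · W + B/m) / W)`; fits used for headline variance
components run 2 chains and are expected to satisfy R̂ < 1.1. (For two
literally identical chains the formula gives sqrt((m−1)/m), i.e. ≈1 from
below, not exactly 1.) Cross-validation fits use a single chain for cost.

## Evaluation protocol

Twenty independent uniform random partitions split the lines 50% train /
50% test (train size ⌊n/2⌋); test phenotypes are masked during fitting and
predicted by data augmentation. Metrics per partition:

* **APC** — Pearson correlation between observed and predicted test
  phenotypes; undefined (recorded as missing, excluded from averages with a
  warning) when either vector is constant.
* **NRMSE** — RMSE divided by the observed test range (a mean-normalized
  variant is available by flag). Range normalization is scale-free and
  keeps typical values in the 0.1–0.3 band.

Aggregation: partition metrics are averaged over partitions within each
trait and then across traits, unweighted; the reported sd is across
partitions of the per-partition across-trait mean (matching error bars over
the 20 partitions).

**Heritability** comes from full-data (unmasked) fits:
`V_P = Σₖ E[σₖ² | y]` over all kernel terms of the model, `h² =
V_P/(V_P + V_e)`. Across traits the *per-trait ratios* are averaged (mean
of ratios, not ratio of means) — the two differ whenever traits have
different variance scales, and the mean-of-ratios convention is the one
consistent with published per-model summary tables in this literature.

## Synthetic data generator

The generator emulates the statistical structure the models assume, at the
scale of the smallest real multi-omics panels: defaults n = 210 lines,
1000 markers, 2000 transcripts, 500 metabolites, 4 traits.

* **Genotypes**: Balding–Nichols admixture. Ancestral allele frequencies ~
  Uniform(0.05, 0.5); 5 subpopulations diverged at Fst = 0.25 (Beta model);
  per-line admixture ~ Dirichlet(0.2); dosages Binomial(2, ·). Diversity
  panels are strongly structured, and that relatedness is what makes
  untested lines predictable; Fst = 0 gives an unstructured population.
* **Transcripts/metabolites**: each feature is
  √q·(standardized random linear combination of ~20 markers) +
  √(1−q)·N(0,1), with the genetic proportion q defaulting to 0.5 for both
  layers, then column-standardized. The layers therefore carry genetic
  signal overlapping the markers', plus layer-specific variation.
* **Phenotypes**: each configured term's effect is drawn exactly from
  N(0, f·K) in the kernel's eigenbasis (reusing the sampler's spectral
  factor, which avoids Cholesky failures on repaired kernels); noise is
  N(0, residual·I). Default fractions g = 0.3, t = 0.2, m = 0.1, residual
  0.4 (heritable fraction 0.6, mid-range for agronomic traits). Each trait
  is standardized, with the stored effects and noise rescaled identically
  so truth bookkeeping remains exact.

What the generator does **not** emulate: linkage disequilibrium and marker
ascertainment, pedigree/family designs, nonlinear regulation between
layers, marker-level epistasis beyond the kernel-defined interactions, and
genotype-by-environment structure. Passing tests therefore demonstrate
correctness of the machinery and recoverability of kernel-level variance
structure, not performance on any real panel.

A note on attainable accuracy: for effects drawn from N(0, K), the best
possible test-set predictor is the conditional mean given the training
lines, and its accuracy is bounded by the relatedness structure in K — with
noiseless phenotypes it is far from 1 unless the kernel is strongly
low-rank. The test suite therefore benchmarks the sampler against that
closed-form conditional-mean oracle (computed independently by linear
algebra from the true fractions) rather than against an absolute accuracy.

## Numerical and design choices

* "Normalization" of omics features = per-feature z-score; markers stay on
  dosage coding for VanRaden (their centering is part of that kernel).
* Missing token on input: empty cell or "NA"/"NaN"/"N/A", case-insensitive.
* Canonical line order: lexicographic; partitions and kernels inherit it,
  making every output reproducible from (data, seed).
* UT keeps the diagonal, LT excludes it (exactness of the decomposition);
  the doubled diagonal of K_CC is absorbed by mean-diagonal scaling.
* Eigenvalue floor for the sampler basis: 1e-8 × λ_max.
* Per-cell RNG substreams: each (dataset, trait, model, partition, chain)
  seed is derived from the master seed by hashing the tokens, so any subset
  of a benchmark reproduces the full run's numbers exactly.
* Degenerate inputs are rejected early with named errors: monomorphic-only
  marker sets, all-constant features, constant observed phenotypes,
  zero-range NRMSE normalizers, empty line-ID intersections.

## Problem sizes used in the shipped checks

Unit and property tests run at n ≤ 150 with reduced chain lengths where the
check is about correctness rather than posterior quality. The acceptance
script uses n = 50 (closed-form GBLUP agreement, 5000 retained draws),
200 random kernel pairs (triangle algebra), n = 300 × 5 replicates
(variance recovery at default chain lengths), and a 210-line benchmark of
M1/M4/M5 over 2 traits × 20 partitions. These sizes were chosen to make the
full suite comfortably runnable on a laptop core while keeping Monte-Carlo
error well inside the stated tolerances.

## Known limitations

* The sampler is O(n³) in the one-off eigendecompositions and O(n²) per
  term per iteration; thousands of lines would need a low-rank or
  REML-style alternative, which is out of scope.
* No multi-trait models, no G×E, no pedigree kernels, no bandwidth tuning
  beyond the median rule.
* Heritability estimates from models with many correlated kernels absorb
  overlapping signal; summed variance components can overstate the
  strictly genomic heritable fraction (visible in the worked example,
  where h² slightly exceeds the generating fraction).
* The CC/PP construction depends on line order through the triangles; the
  canonical sort makes results deterministic, but a different ordering
  convention would give (slightly) different interaction kernels.
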