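# Methods

## Model and estimation

A sample's stacked molecular profile `x` (n features across t data
types) is modeled as `x = Bᵀz + e` with `z ~ N(0, I_k)` i.i.d. and
`e ~ N(0, Ψ)`, Ψ diagonal and constant within a data type. The
complete-data log-likelihood is

```
ℓ(B, Ψ; X, Z) = -½ tr((X-ZB) Ψ⁻¹ (X-ZB)ᵀ) - (N/2) log det Ψ - ½ tr(ZᵀZ)
```

penalized by `Σ_j λ₁ⱼ|bⱼ|₁ + λ₂ⱼ|bⱼ|₂²` with per-data-type levels
(`λ₁ = α·l`, `λ₂ = 1e-6 + (1-α)·l`, α = 0.9 default). Note the `N/2`
normalization on the log-determinant term: the likelihood of N i.i.d.
samples requires it, and the package uses it throughout.

The EM loop (PCA init → E-step with unit-variance factor rescaling →
one coordinate-descent sweep → per-type residual variance → convergence
check) follows the algorithm described in the README. Three numerical
choices deserve explanation:

* **Residual variance orientation and floor.** The M-step residual
  variance is `Ψ̂ᵢ = (tr(XᵢXᵢᵀ) - tr(E[Z|X] B̂ᵢ Xᵢᵀ)) / (nᵢN)`, floored
  at 1e-8. This two-trace form is not the exact conditional-expectation
  M-step (which would add the posterior second-moment term); with a
  flexible fit it can touch the floor, in which case the posterior
  solve is deliberately surfaced as an error rather than silently
  ridge-regularized — a floored Ψ means the model is absorbing a block
  perfectly, which on real data indicates a degenerate configuration
  (e.g. more factors than a small block supports).
* **Why rescaling is mandatory.** The printed coordinate update divides
  by `(1 + λ₂)` without the factor's second moment; that is a correct
  coordinate step only when `(1/N)·diag(E[ZᵀZ|X]) ≈ 1`, which is
  precisely what the unit-variance rescaling enforces. The update and
  the rescaling are therefore a package deal; the non-rescaled baseline
  in `synthgen` uses a closed-form solve instead.
* **Reconstruction error is monitored, not guaranteed monotone.** The
  convergence statistic is `(1/Nn)‖X - E[Z|X]B‖²_F` with the rescaled
  posterior mean. PCA initialization is the exact minimizer of the
  *unpenalized* reconstruction error, so the penalized, shrunk fixed
  point necessarily lies slightly above the first iterate; the error
  approaches it from below with transient per-step increases of order
  1e-7 relative to error values of order 0.1–0.3. The suite asserts the
  honest property — overall decrease with transients below 1e-5
  relative — rather than exact monotonicity.

Solutions are identifiable only up to factor sign and permutation;
comparisons across runs use `match_factors` (optimal assignment on
absolute Pearson correlation).

## Model selection

BIC is assembled as `-2·logL + df·log N` and minimized, with ties
broken toward the larger total penalty. `logL` is the observed-data
log-likelihood `x ~ N(0, BᵀB + Ψ)` with the factors integrated out
(computed via the Woodbury identity). This is a deliberate design
choice: the complete-data plug-in (with posterior factor scores
inserted) lets the factors absorb part of whatever the penalized
coefficients lose, which makes the ranking of neighboring penalty
levels erratic across data draws; the marginal likelihood ranks them
stably and is the quantity BIC is defined for. The complete-data
likelihood remains available (`loglik`) for objective tracing.

Effective degrees of freedom use the Tibshirani–Taylor active-set trace
formula. Once the E-quantities are fixed the multi-response penalized
regression decouples across factors, so each (factor f, data type d)
contributes `|A| · zᵀz / (zᵀz + 2λ₂,d)` where `A` is the set of active
coefficients of factor f in type d and `z` the rescaled factor column —
the trace of the block-diagonal multi-response ridge smoother. In the
lasso limit this counts nonzero coefficients; for λ₂ → ∞ it vanishes.

The default grid is 6 logarithmically spaced levels on [0.01, 1] per
data type. The full Cartesian product is supported; the `coupled`
option moves all data types along the grid together, which is what the
recovery benchmark uses (6 fits instead of 216, with warm starts —
verified to select the same point as cold starts on the test fixtures).

## Preprocessing conventions

* MAD feature selection uses the raw median absolute deviation (no
  1.4826 consistency constant); ties at the cutoff break by original
  column order; selection precedes precision weighting.
* Precision weights multiply the expression values element-wise and are
  retained so model transfer can divide coefficients by each gene's
  average weight.
* Copy number is summarized per (sample, region) as the unweighted
  median of all segments overlapping the region by at least one base
  pair; SEG coordinates are 1-based inclusive. A sample with no
  overlapping segment for some region is an error, not an imputation.
* Each feature is mean-centered (the model has no intercept) and each
  data type is divided by one pooled scalar SD — not per-feature —
  because the shared per-type penalty is designed to act on the
  within-type variance structure. Centering means and scale factors are
  stored for transfer.

## Gene-set enrichment

The regression of all genes on the factors is joint (all k factors as
covariates), with factors and genes centered; coefficients are divided
by the gene's population SD, so with a single unit-variance factor the
scores are exactly Pearson correlations. Ranking ties break by gene id.
The enrichment statistic is the weighted KS running sum with weight
exponent p = 1 (hits weighted by |score| normalized over the set,
misses by `1/(n - |S|)`); the leading-edge proportion counts set
members at or before the extremum for positive scores, strictly after
for negative.

The permutation null shuffles factor rows across samples and recomputes
the entire regression → normalization → ranking → enrichment chain —
permuting samples changes the regression coefficients, so recomputing
only the statistic would understate the null variance. The p-value is
the same-sign tail with the add-one convention, `(1 + #{null at least
as extreme}) / (1 + #{null of that sign})`: the observed statistic is
exchangeable with its same-sign nulls, making the p-value uniform under
the null (verified by simulation). NES divides by the mean same-sign
null; FDR follows the pooled-NES tail-ratio convention with
Benjamini–Hochberg available as a flag. Defaults: n_perm = 1000,
report filter FDR < 0.25 and leading edge < 0.5. Note that any filter
controlling FDR at 0.25 will, on a dataset with *no* signal, still
flag something in a nontrivial fraction of datasets — that is what an
FDR of 0.25 means — so the report filter is a triage device for manual
curation, not a family-wise error guarantee.

## Transfer

Cross-platform scoring proceeds: divide the mRNA coefficients per gene
by the average training precision weight; map each modeled gene to its
most variable probe (variance measured on the new cohort); center each
gene on the new cohort and scale to the reference variance; project
with `Z = X Bᵀ(BBᵀ + I)⁻¹`. Genes absent from the new platform are
dropped from both X and B without renormalization (the projection
formula has none), with the drop count logged as a quality metric.

## Synthetic data

`SyntheticSpec` draws `Z ~ N(0, I)`, a sparse B per data type
(`round(sᵢ·k·nᵢ)` nonzero entries at uniform positions, values
N(0, τ²)), and `Xᵢ = ZBᵢ + noise`. Noise is parameterized by per-type
signal-to-noise: `ψᵢ = sᵢ·k·τ²/snrᵢ` (average per-entry signal variance
over SNR), so fixtures stay meaningful when feature counts change. One
master seed fans out through independent `SeedSequence` substreams per
data type, so adding a data type leaves the other blocks' draws
untouched.

The default spec — N = 300 samples, k = 4 factors, blocks of 500/60/40
features with sparsity 0.2/0.5/0.5, τ = 1, SNR 3:1 — mimics the shape
of a bulk multi-omics cohort (wide sparse expression block, narrow
denser copy-number and protein blocks). What it does *not* emulate:
realistic segment/chromosome structure in copy number, count
mean-variance trends, batch effects, or non-Gaussian (e.g. binary
mutation) features. Passing recovery tests therefore certify the
estimator under its own model assumptions, not robustness to their
violation.

`baseline_em_fit` is the comparison arm for convergence benchmarking:
the same EM loop without factor rescaling, with a one-shot generalized
ridge solve plus soft-threshold instead of coordinate descent. Both
arms start from PCA, so at the benchmark's moderate penalties both
reach the PCA-level explained variance essentially immediately; the
comparison certifies that the rescaled coordinate-descent arm is never
slower and does not degrade away from the benchmark.

## Problem sizes in the test suite

Oracle-equivalence tests run on instances with N, n ≤ 10 against dense
explicit-inversion or brute-force oracles. Recovery uses the default
spec with 5 replicate seeds and the coupled 6-point grid; enrichment
calibration uses 60 samples x 300 genes, 50 sets x 4 factors, 200
permutations, 10 seeded repeats; the convergence benchmark uses 10
replicates of a 150 x 140 two-block design. These sizes keep the full
suite around a minute on one CPU while leaving every statistical check
adequately powered.

## Known limitations

* No missing-data mechanism: inputs with missing cells are rejected at
  read time.
* Binary data (mutations) do not fit the Gaussian likelihood and are
  deliberately out of scope.
* The two-trace residual-variance update can floor at 1e-8 on
  degenerate configurations (tiny block, excess factors), surfaced as a
  posterior-solve error.
* The enrichment FDR is the pooled-NES estimate; under strong
  inter-set correlation it can be anti-conservative, which is why the
  report filter also requires a dispersed leading edge.
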