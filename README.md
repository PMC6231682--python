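# funcsfa

Sparse-factor analysis for integrating multiple molecular data types —
RNA expression, copy number, protein (RPPA) — into a small number of
continuous per-tumor factors, with a tailored gene-set enrichment step
to attach biology to each factor and a closed-form projection to score
new samples or cohorts on a fitted model.

Unlike clustering-based integration, each sample gets a *level* on every
factor rather than a single subtype label, so overlapping programs
(e.g. hormone-receptor signaling, immune infiltration, EMT) can be
active in the same tumor at different strengths.

## Model

Stack the per-data-type matrices into `X = [X_1, ..., X_t]` (N samples x
n features). Each sample vector is modeled as

```
x = Bᵀ z + e,    z ~ N(0, I_k),    e ~ N(0, Ψ)
```

with Ψ diagonal and equal within a data type (one residual variance per
data type), and B (k x n) penalized by an elastic net with one level `l`
per data type: `λ₁ = α·l`, `λ₂ = 1e-6 + (1-α)·l`, α = 0.9 by default.
Fitting is EM:

1. **init** — PCA loadings;
2. **E-step** — posterior moments `E[Z|X]`, `E[ZᵀZ|X]`, then both
   rescaled so every factor has unit sample variance (this stops the
   penalty from shrinking coefficients while factors inflate to
   compensate);
3. **M-step (B)** — one sequential coordinate-descent sweep with
   soft-thresholding;
4. **M-step (Ψ)** — per-data-type residual variance;
5. repeat until the mean absolute change of the reconstruction error
   over 10 iterations drops below 1e-6 (max 5000 iterations).

Penalty levels are selected by grid search minimizing
`BIC = -2·logL + df·log N`, where `logL` is the observed-data likelihood
(factors integrated out) and `df` is the Tibshirani–Taylor active-set
estimate for the elastic net.

Factor interpretation regresses the *full* expression matrix (all genes,
not just the modeled subset) on the factors, normalizes each coefficient
by the gene's standard deviation ("correlation-like" scores), ranks
genes per factor, and computes the weighted Kolmogorov–Smirnov
enrichment statistic per (gene set, factor) pair, with significance from
a sample-permutation test (the whole regression → ranking → enrichment
chain is recomputed per permutation).

New samples are scored from expression alone by
`Z = X_mRNA Bᵀ(BBᵀ + I)⁻¹` with the coefficients held fixed; for a
different expression platform, genes map to their most variable probe
and are centered/variance-matched to the reference cohort, and the
coefficients are divided per gene by the average precision weight used
in training.

## Worked example

```python
import numpy as np
from funcsfa import (SyntheticSpec, generate_dataset, scale_by_datatype_sd,
                     fit_sfa, expand_penalties, explained_variance,
                     match_factors)

spec = SyntheticSpec(n_samples=300, k=4, seed=1)   # mrna/cn/rppa blocks
dataset, Z_true, B_true = generate_dataset(spec)
scaled, scaling = scale_by_datatype_sd(dataset)
fit = fit_sfa(scaled, k=4,
              penalties=expand_penalties(0.9, [0.063, 0.063, 0.063]))
print(f"converged: {fit.trace.converged} after {fit.trace.n_iter} iterations")
print(f"nonzero coefficients: {np.count_nonzero(fit.model.coefficients)} "
      f"of {fit.model.coefficients.size}")
print(explained_variance(scaled, fit.model, fit.posterior).round(3))
m = match_factors(Z_true, fit.posterior.mean)
print("matched |r| to the simulated factors:", np.round(m.correlations, 3))
```

prints

```
converged: True after 48 iterations
nonzero coefficients: 674 of 2400
      factor_0  factor_1  factor_2  factor_3
mrna     0.207     0.183     0.177     0.151
cn       0.162     0.158     0.140     0.310
rppa     0.174     0.243     0.226     0.094
matched |r| to the simulated factors: [0.999 0.999 0.999 0.999]
```

The elastic net keeps 674 of 2400 coefficients; every simulated factor
is recovered essentially exactly (matched absolute Pearson correlation
0.999), and the explained-variance table shows how much of each data
type's variation each factor accounts for.

The same pipeline is available from the shell:

```sh
funcsfa simulate --spec spec.yaml --out synth.h5
funcsfa preprocess --expr expr.tsv --seg cn.seg --regions regions.bed \
        --top-mad 1000 --out dataset.h5
funcsfa select --data dataset.h5 --k 10 --alpha 0.9 --out scores.tsv
funcsfa fit --data dataset.h5 --k 10 --levels 0.06,0.06,0.06 \
        --out model.fsfa --factors-out factors.tsv
funcsfa gsea --data dataset.h5 --model model.fsfa --expr expr_all.tsv \
        --gmt sets.gmt --out enrichment.tsv
funcsfa project --model model.fsfa --expr new_expr.tsv --out new_factors.tsv
```

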