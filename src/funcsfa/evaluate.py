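"""Post-fit quantities: explained variance, factor-mutation association,
and matching of factors across factorizations.

Explained variance of factor j in data type i is the drop in residual
sum of squares when the factor is included, relative to the block's
total sum of squares:

    ( ||X_i - Z_[-j] B_i[-j]||_F^2 - ||X_i - Z B_i||_F^2 ) / ||X_i||_F^2

where the [-j] quantities simply drop factor j without refitting.
Because sparse factors are not orthogonal, individual entries can be
slightly negative; they are reported as computed, not clipped.

The factor-mutation association statistic is the Mann-Whitney U of the
factor values between mutated and wild-type tumors divided by the
product of the group sizes (ties counted 1/2) — identical to the AUC of
the factor as a classifier of mutation status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .data_io import MultiOmicsDataset
from .errors import ValidationError
from .sfa_core import FactorModel, PosteriorFactors

__all__ = [
    "explained_variance",
    "total_explained_variance",
    "factor_mutation_association",
    "association_table",
    "FactorMatch",
    "match_factors",
]


def explained_variance(dataset: MultiOmicsDataset, model: FactorModel,
                       posterior: PosteriorFactors) -> pd.DataFrame:
    """Per (data type, factor) explained-variance fractions."""
    M = posterior.mean
    out = np.empty((dataset.n_types, model.k))
    for i, sl in enumerate(dataset.block_slices):
        Xi = dataset.blocks[i].values
        tot = float(np.sum(Xi ** 2))
        if tot == 0:
            raise ValidationError(
                f"block {dataset.datatype_labels[i]!r} has zero norm")
        Bi = model.coefficients[:, sl]
        full = float(np.sum((Xi - M @ Bi) ** 2))
        for j in range(model.k):
            keep = [f for f in range(model.k) if f != j]
            drop = float(np.sum((Xi - M[:, keep] @ Bi[keep]) ** 2))
            out[i, j] = (drop - full) / tot
    return pd.DataFrame(out, index=dataset.datatype_labels,
                        columns=[f"factor_{j}" for j in range(model.k)])


def total_explained_variance(dataset: MultiOmicsDataset, model: FactorModel,
                             posterior: PosteriorFactors,
                             by_type: bool = False):
    """1 - ||X_i - Z B_i||^2 / ||X_i||^2, per block or overall."""
    M = posterior.mean
    per = []
    for i, sl in enumerate(dataset.block_slices):
        Xi = dataset.blocks[i].values
        Bi = model.coefficients[:, sl]
        per.append(1.0 - np.sum((Xi - M @ Bi) ** 2) / np.sum(Xi ** 2))
    if by_type:
        return np.array(per)
    X = dataset.stacked()
    return float(1.0 - np.sum((X - M @ model.coefficients) ** 2)
                 / np.sum(X ** 2))


def factor_mutation_association(factor_values, mutated) -> tuple[float, float]:
    """(U / (n_mut * n_wt), two-sided rank-sum p-value).

    The statistic equals the probability that a mutated tumor has the
    larger factor value (ties 1/2): 1.0 means complete separation with
    mutated tumors higher, 0.5 means no association.
    """
    x = np.asarray(factor_values, dtype=float)
    m = np.asarray(mutated, dtype=bool)
    if x.shape != m.shape:
        raise ValidationError("factor values and mutation indicator differ in length")
    n1, n0 = int(m.sum()), int((~m).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both mutation groups must be non-empty")
    res = scipy.stats.mannwhitneyu(x[m], x[~m], alternative="two-sided")
    return float(res.statistic) / (n1 * n0), float(res.pvalue)


def association_table(factors: pd.DataFrame, mutations: pd.DataFrame,
                      alpha: float = 0.05, bh: bool = False) -> pd.DataFrame:
    """Effect size and p for every (mutated gene, factor) pair.

    ``factors``: samples x factors; ``mutations``: samples x genes,
    boolean.  By default only pairs with p < ``alpha`` get a reported
    effect (others are NaN), mirroring how such association matrices are
    usually displayed; ``bh`` switches the cutoff to BH-adjusted q.
    """
    mutations = mutations.loc[factors.index]
    rows = []
    for g in mutations.columns:
        for f in factors.columns:
            eff, p = factor_mutation_association(factors[f].to_numpy(),
                                                 mutations[g].to_numpy())
            rows.append({"gene": g, "factor": f, "effect": eff, "p": p})
    tab = pd.DataFrame(rows)
    if bh:
        from statsmodels.stats.multitest import multipletests

        tab["q"] = multipletests(tab["p"], method="fdr_bh")[1]
        tab["effect_shown"] = tab["effect"].where(tab["q"] < alpha)
    else:
        tab["effect_shown"] = tab["effect"].where(tab["p"] < alpha)
    return tab


@dataclass
class FactorMatch:
    permutation: np.ndarray   # index into B's factors, aligned to A's
    signs: np.ndarray
    correlations: np.ndarray  # matched |r| per pair


def match_factors(factors_a, factors_b, method: str = "optimal") -> FactorMatch:
    """Match factor columns of two factorizations up to sign and
    permutation by maximizing the summed |Pearson correlation|.

    ``optimal`` solves the assignment problem exactly; ``greedy`` picks
    the largest remaining |r| repeatedly (for comparison).
    """
    A = np.asarray(factors_a, dtype=float)
    B = np.asarray(factors_b, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValidationError("factor matrices must share the sample axis")
    ka, kb = A.shape[1], B.shape[1]
    r = np.empty((ka, kb))
    for i in range(ka):
        for j in range(kb):
            r[i, j] = scipy.stats.pearsonr(A[:, i], B[:, j]).statistic
    r = np.nan_to_num(r)
    if method == "optimal":
        rows, cols = scipy.optimize.linear_sum_assignment(-np.abs(r))
        perm = cols[np.argsort(rows)]
    elif method == "greedy":
        perm = np.full(ka, -1)
        used: set[int] = set()
        flat = sorted(((abs(r[i, j]), i, j) for i in range(ka)
                       for j in range(kb)), reverse=True)
        for _, i, j in flat:
            if perm[i] == -1 and j not in used:
                perm[i], used = j, used | {j}
    else:
        raise ValidationError(f"unknown matching method {method!r}")
    signs = np.sign(r[np.arange(ka), perm])
    signs[signs == 0] = 1
    return FactorMatch(perm, signs, np.abs(r[np.arange(ka), perm]))
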