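"""Gene-set enrichment tailored to factor-analysis output.

Sparse coefficients zero out most genes, which makes them unusable for
rank-based enrichment.  Instead the full expression matrix (all genes,
not only the modeled subset) is regressed on the factors jointly; the
regression coefficients, divided per gene by that gene's standard
deviation, give "correlation-like" scores (for a single unit-variance
factor they are exactly Pearson correlations).  Genes are ranked per
factor by these scores and the classic weighted Kolmogorov-Smirnov
enrichment statistic is computed per (gene set, factor) pair.

Significance comes from a sample permutation test: factor rows are
permuted across samples and the whole regression -> normalization ->
ranking -> enrichment chain is recomputed per permutation — permuting
samples changes the regression, so recomputing only the enrichment
statistic would be wrong.  NES normalizes by the mean same-sign null
enrichment; FDR follows the enrichment-analysis convention of comparing
tail fractions of pooled null and observed NES (Benjamini-Hochberg on
the permutation p-values is available as an alternative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GeneSetCollection, OmicsMatrix
from .errors import ValidationError
from .sfa_core import PosteriorFactors

logger = logging.getLogger("funcsfa")

__all__ = [
    "FactorExpressionProfile",
    "factor_expression_coefficients",
    "rank_genes",
    "enrichment_score",
    "permutation_null",
    "nes_and_fdr",
    "run_factor_gsea",
]


@dataclass
class FactorExpressionProfile:
    """Joint regression coefficients of genes on factors (k x n_m), plus
    the per-gene-SD-normalized correlation-like version."""

    coefficients: np.ndarray
    normalized: np.ndarray
    gene_ids: list[str]

    @property
    def k(self) -> int:
        return self.coefficients.shape[0]


def _factor_matrix(factors) -> np.ndarray:
    if isinstance(factors, PosteriorFactors):
        return factors.mean
    return np.asarray(factors, dtype=float)


def factor_expression_coefficients(expr_full: OmicsMatrix, factors
                                   ) -> FactorExpressionProfile:
    """Regress every gene on all k factors jointly; normalize per gene.

    Factors and genes are mean-centered before the least-squares solve
    (the model has no intercept term), and the normalizing gene SD is
    the population SD of the same centered expression, so that with a
    single unit-variance factor the normalized coefficient equals the
    Pearson correlation.
    """
    Z = _factor_matrix(factors)
    X = expr_full.values
    if Z.shape[0] != X.shape[0]:
        raise ValidationError("factors and expression sample counts differ")
    Zc = Z - Z.mean(axis=0)
    Xc = X - X.mean(axis=0)
    G = Zc.T @ Zc
    if np.linalg.matrix_rank(G) < Z.shape[1]:
        raise ValidationError("rank-deficient factor matrix")
    C = np.linalg.solve(G, Zc.T @ Xc)
    sd = Xc.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, np.inf)  # constant gene -> score 0
    return FactorExpressionProfile(C, C / sd_safe, list(expr_full.feature_ids))


def rank_genes(profile: FactorExpressionProfile, factor: int
               ) -> pd.Series:
    """Genes sorted by normalized coefficient, descending; ties break by
    gene id (ascending) for determinism."""
    s = pd.Series(profile.normalized[factor], index=profile.gene_ids)
    return s.sort_index().sort_values(ascending=False, kind="stable")


def enrichment_score(ranked: pd.Series, gene_set: set[str],
                     p: float = 1.0) -> tuple[float, int, float]:
    """Weighted KS running-sum enrichment of a gene set in a ranking.

    Hits increment by |score|^p normalized over the set's members; every
    miss decrements by 1/(n - |S|).  Returns (ES, 1-based rank of the
    running-sum extremum, leading-edge proportion).  The leading edge is
    the set fraction at or before the extremum for positive ES, strictly
    after it for negative ES.
    """
    genes = ranked.index.to_numpy()
    member = np.isin(genes, list(gene_set))
    n_hit = int(member.sum())
    n = len(genes)
    if n_hit == 0:
        raise ValidationError("gene set has no overlap with the ranking")
    if n_hit == n:
        raise ValidationError("gene set covers the whole ranking")
    w = np.abs(ranked.to_numpy()) ** p
    hit_total = w[member].sum()
    step = np.where(member,
                    w / hit_total if hit_total > 0 else 1.0 / n_hit,
                    -1.0 / (n - n_hit))
    run = np.cumsum(step)
    idx = int(np.argmax(np.abs(run)))
    es = float(run[idx])
    if es >= 0:
        lead = int(member[:idx + 1].sum())
    else:
        lead = int(member[idx + 1:].sum())
    return es, idx + 1, lead / n_hit


def _es_table(profile: FactorExpressionProfile, sets: dict[str, set[str]],
              p: float) -> np.ndarray:
    out = np.empty((len(sets), profile.k))
    for f in range(profile.k):
        ranked = rank_genes(profile, f)
        for si, genes in enumerate(sets.values()):
            out[si, f] = enrichment_score(ranked, genes, p)[0]
    return out


def permutation_null(expr_full: OmicsMatrix, factors, gene_sets: GeneSetCollection,
                     n_perm: int, seed: int, p: float = 1.0) -> np.ndarray:
    """Null enrichment scores: per permutation, factor rows are shuffled
    across samples and the full regression -> ranking -> ES pipeline is
    recomputed.  Returns an (n_sets, k, n_perm) array."""
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    Z = _factor_matrix(factors)
    rng = np.random.default_rng(seed)
    out = np.empty((len(gene_sets), Z.shape[1], n_perm))
    for b in range(n_perm):
        perm = rng.permutation(Z.shape[0])
        prof = factor_expression_coefficients(expr_full, Z[perm])
        out[:, :, b] = _es_table(prof, gene_sets.sets, p)
    return out


def nes_and_fdr(observed: np.ndarray, null: np.ndarray,
                set_names: list[str], fdr_method: str = "pool"
                ) -> pd.DataFrame:
    """Normalize enrichment scores against the permutation null.

    NES = ES / mean(same-sign null ES).  The permutation p-value uses
    the same-sign tail with the add-one convention.  FDR "pool" compares
    tail fractions of pooled null NES vs observed NES (same sign, capped
    at 1); "bh" applies Benjamini-Hochberg to the permutation p-values.
    Pairs with no same-sign nulls are flagged undefined (NaN scores).
    """
    n_sets, k, n_perm = null.shape
    nes = np.full((n_sets, k), np.nan)
    pval = np.full((n_sets, k), np.nan)
    null_nes = np.full_like(null, np.nan)
    for s in range(n_sets):
        for f in range(k):
            nl = null[s, f]
            pos_mean = nl[nl > 0].mean() if (nl > 0).any() else np.nan
            neg_mean = np.abs(nl[nl < 0]).mean() if (nl < 0).any() else np.nan
            with np.errstate(invalid="ignore", divide="ignore"):
                null_nes[s, f] = np.where(nl >= 0, nl / pos_mean,
                                          nl / neg_mean)
            es = observed[s, f]
            if es >= 0:
                if np.isnan(pos_mean):
                    continue
                nes[s, f] = es / pos_mean
                exceed = int(np.sum(nl >= es))
                n_side = int(np.sum(nl >= 0))
            else:
                if np.isnan(neg_mean):
                    continue
                nes[s, f] = es / neg_mean
                exceed = int(np.sum(nl <= es))
                n_side = int(np.sum(nl < 0))
            # same-sign tail with the add-one convention: the observed
            # statistic is exchangeable with the same-sign nulls, which
            # makes the p-value uniform under the null
            pval[s, f] = (1 + exceed) / (n_side + 1)

    obs_flat = nes.ravel()
    null_flat = null_nes.ravel()
    null_flat = null_flat[np.isfinite(null_flat)]
    fdr = np.full(obs_flat.shape, np.nan)
    if fdr_method == "pool":
        n_null_pos = np.sum(null_flat >= 0)
        n_null_neg = np.sum(null_flat < 0)
        n_obs_pos = np.sum(obs_flat >= 0)
        n_obs_neg = np.sum(obs_flat < 0)
        for i, v in enumerate(obs_flat):
            if not np.isfinite(v):
                continue
            if v >= 0:
                if n_null_pos == 0 or n_obs_pos == 0:
                    continue
                top = np.sum(null_flat >= v) / n_null_pos
                bot = np.sum(obs_flat[np.isfinite(obs_flat)] >= v) / n_obs_pos
            else:
                if n_null_neg == 0 or n_obs_neg == 0:
                    continue
                top = np.sum(null_flat <= v) / n_null_neg
                bot = np.sum(obs_flat[np.isfinite(obs_flat)] <= v) / n_obs_neg
            fdr[i] = min(1.0, top / bot) if bot > 0 else np.nan
    elif fdr_method == "bh":
        from statsmodels.stats.multitest import multipletests

        mask = np.isfinite(pval.ravel())
        if mask.any():
            fdr[mask] = multipletests(pval.ravel()[mask], method="fdr_bh")[1]
    else:
        raise ValidationError(f"unknown fdr_method {fdr_method!r}")

    rows = []
    for s in range(n_sets):
        for f in range(k):
            rows.append({"set": set_names[s], "factor": f,
                         "es": observed[s, f], "nes": nes[s, f],
                         "p": pval[s, f], "fdr": fdr[s * k + f]})
    return pd.DataFrame(rows)


def run_factor_gsea(expr_full: OmicsMatrix, factors, gmt: GeneSetCollection,
                    n_perm: int = 1000, seed: int = 0, p: float = 1.0,
                    fdr_method: str = "pool",
                    fdr_cut: float = 0.25, leading_edge_cut: float = 0.5
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full enrichment pipeline for all (gene set, factor) pairs.

    Returns (full table, filtered report).  The default report keeps
    pairs with FDR < 0.25 and leading-edge proportion < 0.5 — a strongly
    concentrated leading edge usually reflects a handful of extreme
    genes rather than coordinated pathway activity.
    """
    present = set(expr_full.feature_ids)
    usable = {name: genes & present for name, genes in gmt.sets.items()
              if genes & present}
    skipped = len(gmt.sets) - len(usable)
    if skipped:
        logger.warning("run_factor_gsea: %d gene sets with no overlap skipped",
                       skipped)
    if not usable:
        logger.warning("run_factor_gsea: no usable gene sets; empty result")
        cols = ["set", "factor", "es", "nes", "rank_at_max",
                "leading_edge", "p", "fdr"]
        empty = pd.DataFrame(columns=cols)
        return empty, empty.copy()
    collection = GeneSetCollection(usable)
    prof = factor_expression_coefficients(expr_full, factors)
    names = list(usable)
    k = prof.k
    observed = np.empty((len(usable), k))
    rank_at_max = np.empty((len(usable), k), dtype=int)
    leading = np.empty((len(usable), k))
    for f in range(k):
        ranked = rank_genes(prof, f)
        for si, genes in enumerate(usable.values()):
            es, r, le = enrichment_score(ranked, genes, p)
            observed[si, f], rank_at_max[si, f], leading[si, f] = es, r, le
    null = permutation_null(expr_full, factors, collection, n_perm, seed, p)
    table = nes_and_fdr(observed, null, names, fdr_method)
    table["rank_at_max"] = rank_at_max.ravel()
    table["leading_edge"] = leading.ravel()
    table = table[["set", "factor", "es", "nes", "rank_at_max",
                   "leading_edge", "p", "fdr"]]
    report = table[(table["fdr"] < fdr_cut)
                   & (table["leading_edge"] < leading_edge_cut)]
    return table, report.reset_index(drop=True)
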