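"""Single-sample factor scoring and cross-platform model translation.

A fitted model can score new cohorts (or a single new tumor) from gene
expression alone by holding the sparse mRNA coefficients fixed and
solving the factor-model normal equations in closed form:

    Z = X_mRNA B_mRNA^T (B_mRNA B_mRNA^T + I)^-1

Before projection onto a different expression platform the coefficients
and the data are brought onto the reference scale:

* coefficients are divided per gene by the gene's average precision
  weight over the reference cohort, undoing the voom-style weighting
  baked into the training data;
* each gene on the new platform is represented by its most variable
  probe, mean-centered on the new cohort and scaled so its variance
  matches the reference cohort's.

Genes absent from the new platform are dropped from both the data and
the coefficients (count logged); the projection formula is applied
without renormalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .data_io import MultiOmicsDataset, OmicsMatrix
from .errors import ValidationError
from .sfa_core import FactorModel

logger = logging.getLogger("funcsfa")

__all__ = [
    "TransferModel",
    "make_transfer_model",
    "adapt_coefficients",
    "harmonize_expression",
    "project_samples",
]


@dataclass
class TransferModel:
    """The mRNA coefficient block plus the reference statistics needed to
    score new expression data."""

    coefficients: np.ndarray       # k x n_m
    gene_ids: list[str]
    ref_mean: np.ndarray           # per gene, reference cohort
    ref_var: np.ndarray            # per gene, reference cohort

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape[1] != len(self.gene_ids):
            raise ValidationError("coefficient columns != gene ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        used = np.any(self.coefficients != 0, axis=0)
        if np.any(np.asarray(self.ref_var)[used] <= 0):
            raise ValidationError("non-positive reference variance for a used gene")

    @property
    def k(self) -> int:
        return self.coefficients.shape[0]

    def restrict(self, genes: list[str]) -> "TransferModel":
        idx = [self.gene_ids.index(g) for g in genes]
        return TransferModel(self.coefficients[:, idx], list(genes),
                             np.asarray(self.ref_mean)[idx],
                             np.asarray(self.ref_var)[idx])


def make_transfer_model(model: FactorModel, dataset: MultiOmicsDataset,
                        mrna_label: str = "mrna") -> TransferModel:
    """Extract the mRNA block of a fitted model together with the
    reference cohort's per-gene means and variances (on the scale the
    model was fitted on)."""
    if mrna_label not in dataset.datatype_labels:
        raise ValidationError(f"no block labeled {mrna_label!r}")
    i = dataset.datatype_labels.index(mrna_label)
    sl = dataset.block_slices[i]
    blk = dataset.blocks[i]
    return TransferModel(model.coefficients[:, sl].copy(),
                         list(blk.feature_ids),
                         blk.values.mean(axis=0),
                         blk.values.var(axis=0, ddof=0))


def adapt_coefficients(tm: TransferModel, avg_weights) -> TransferModel:
    """Divide each gene's coefficients by that gene's average precision
    weight over the reference samples."""
    if isinstance(avg_weights, dict):
        missing = [g for g in tm.gene_ids if g not in avg_weights]
        if missing:
            raise ValidationError(
                f"missing average weight for genes: {missing[:5]}")
        w = np.array([avg_weights[g] for g in tm.gene_ids], dtype=float)
    else:
        w = np.asarray(avg_weights, dtype=float)
        if w.shape != (len(tm.gene_ids),):
            raise ValidationError("one average weight per modeled gene required")
    if np.any(w <= 0) or not np.isfinite(w).all():
        raise ValidationError("average weights must be positive and finite")
    return TransferModel(tm.coefficients / w, list(tm.gene_ids),
                         tm.ref_mean.copy(), tm.ref_var.copy())


def harmonize_expression(new_expr: OmicsMatrix, tm: TransferModel,
                         probe_map: pd.DataFrame | dict | None = None
                         ) -> OmicsMatrix:
    """Map a new cohort's expression onto the reference gene space.

    Per modeled gene the most variable probe (variance on the new
    cohort) is selected; the gene column is mean-centered on the new
    cohort and multiplied by sqrt(reference variance / new variance).
    Genes without any probe on the new platform are dropped with a
    logged count.  ``probe_map`` maps gene -> candidate probes; omit it
    when the new platform already uses gene identifiers.
    """
    if probe_map is None:
        gene_to_probes = {g: [g] for g in tm.gene_ids
                          if g in set(new_expr.feature_ids)}
    elif isinstance(probe_map, pd.DataFrame):
        gene_to_probes = {g: list(grp["probe"]) for g, grp in
                          probe_map.groupby("gene", sort=False)}
    else:
        gene_to_probes = {g: list(ps) for g, ps in probe_map.items()}
    col_of = {f: j for j, f in enumerate(new_expr.feature_ids)}
    X = new_expr.values
    kept_genes: list[str] = []
    cols: list[np.ndarray] = []
    dropped = 0
    for gi, g in enumerate(tm.gene_ids):
        probes = [p for p in gene_to_probes.get(g, []) if p in col_of]
        if not probes:
            dropped += 1
            continue
        v = [X[:, col_of[p]].var(ddof=0) for p in probes]
        x = X[:, col_of[probes[int(np.argmax(v))]]].astype(float)
        new_var = x.var(ddof=0)
        if new_var <= 0:
            raise ValidationError(f"zero variance on the new cohort for gene {g!r}")
        x = (x - x.mean()) * np.sqrt(tm.ref_var[gi] / new_var)
        kept_genes.append(g)
        cols.append(x)
    if dropped:
        logger.info("harmonize_expression: %d modeled genes without probes "
                    "dropped", dropped)
    if not kept_genes:
        raise ValidationError("no modeled gene could be mapped to a probe")
    return OmicsMatrix(np.column_stack(cols), list(new_expr.sample_ids),
                       kept_genes, "mrna_harmonized")


def project_samples(expr, tm: TransferModel) -> np.ndarray:
    """Closed-form factor scores Z = X B^T (B B^T + I)^-1 for new samples
    (works for a single sample).  ``expr`` columns must be a subset of
    the model's genes, in any order; missing genes are dropped from the
    coefficients without renormalization."""
    if isinstance(expr, OmicsMatrix):
        genes, X = expr.feature_ids, expr.values
    else:
        X = np.atleast_2d(np.asarray(expr, dtype=float))
        genes = list(tm.gene_ids)
        if X.shape[1] != len(genes):
            raise ValidationError("bare-array input must cover all model genes")
    unknown = [g for g in genes if g not in set(tm.gene_ids)]
    if unknown:
        raise ValidationError(f"genes not in the model: {unknown[:5]}")
    sub = tm.restrict(list(genes))
    B = sub.coefficients
    A = B @ B.T + np.eye(sub.k)
    return X @ scipy.linalg.solve(A, B, assume_a="pos").T
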