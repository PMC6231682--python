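"""Feature selection, weighting, copy-number region summarization and scaling.

The pipeline applied to each cohort before factor analysis:

1. keep the expression features with the largest median absolute
   deviation (MAD) across samples;
2. multiply expression by per-entry precision weights (voom-style) to
   account for the count mean-variance trend;
3. summarize segmented copy number to one value per recurrently
   aberrated region (median of overlapping segments);
4. mean-center each feature and divide each data type by one pooled
   standard deviation so no data type dominates the shared penalty.

MAD here is the raw median absolute deviation from the median — no
1.4826 normal-consistency constant.  Ties at the selection cutoff are
broken by original column order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import MultiOmicsDataset, OmicsMatrix, RegionTable, SegmentTable
from .errors import ValidationError

__all__ = [
    "select_top_mad_genes",
    "apply_precision_weights",
    "summarize_cn_regions",
    "scale_by_datatype_sd",
    "ScalingInfo",
]


def select_top_mad_genes(expr: OmicsMatrix, count: int) -> OmicsMatrix:
    """Keep the ``count`` features with largest MAD, preserving column order."""
    if count < 1:
        raise ValidationError(f"count must be >= 1, got {count}")
    med = np.median(expr.values, axis=0)
    mad = np.median(np.abs(expr.values - med), axis=0)
    # stable argsort on -mad: ties resolve to the earlier column
    order = np.argsort(-mad, kind="stable")
    keep = np.sort(order[:min(count, expr.n_features)])
    return expr.subset_features(keep)


def apply_precision_weights(expr: OmicsMatrix) -> OmicsMatrix:
    """Multiply values element-wise by the attached precision weights.

    The weights stay attached to the result so that downstream model
    transfer can undo their average effect per gene.
    """
    if expr.weights is None:
        raise ValidationError("expression matrix has no precision weights")
    return OmicsMatrix(
        values=expr.values * expr.weights,
        sample_ids=list(expr.sample_ids),
        feature_ids=list(expr.feature_ids),
        datatype_label=expr.datatype_label,
        weights=expr.weights.copy(),
    )


def summarize_cn_regions(segments: SegmentTable, regions: RegionTable,
                         sample_ids: list[str],
                         datatype_label: str = "cn") -> OmicsMatrix:
    """Sample x region matrix of median copy number over overlapping segments.

    A segment overlaps a region when they share at least one base pair
    (both intervals 1-based inclusive).  The median is unweighted — no
    length weighting.  A (sample, region) pair with no overlapping
    segment is an error listing all such pairs.
    """
    seg = segments.df
    by_sample_chrom = {k: v for k, v in seg.groupby(["sample", "chrom"], sort=False)}
    reg = regions.df
    out = np.empty((len(sample_ids), len(reg)))
    missing: list[tuple[str, str]] = []
    for si, s in enumerate(sample_ids):
        for ri, r in enumerate(reg.itertuples(index=False)):
            grp = by_sample_chrom.get((s, r.chrom))
            if grp is None:
                missing.append((s, r.region_id))
                continue
            hit = grp[(grp["start"] <= r.end) & (grp["end"] >= r.start)]
            if len(hit) == 0:
                missing.append((s, r.region_id))
                continue
            out[si, ri] = float(np.median(hit["value"].to_numpy()))
    if missing:
        shown = ", ".join(f"({s}, {g})" for s, g in missing[:10])
        raise ValidationError(
            f"{len(missing)} (sample, region) pairs without overlapping "
            f"segments: {shown}{'...' if len(missing) > 10 else ''}")
    return OmicsMatrix(out, list(sample_ids), list(reg["region_id"]),
                       datatype_label)


@dataclass
class ScalingInfo:
    """Centering means and pooled scale factors, kept for model transfer."""

    feature_means: list[np.ndarray]   # per block, length n_i
    scale_factors: np.ndarray         # per block, one scalar
    datatype_labels: list[str]

    def mean_of(self, label: str) -> np.ndarray:
        return self.feature_means[self.datatype_labels.index(label)]

    def scale_of(self, label: str) -> float:
        return float(self.scale_factors[self.datatype_labels.index(label)])


def scale_by_datatype_sd(dataset: MultiOmicsDataset, center: bool = True
                         ) -> tuple[MultiOmicsDataset, ScalingInfo]:
    """Mean-center each feature, then divide each data type by one scalar:
    the pooled standard deviation of all its (centered) entries.

    One scalar per data type — per-feature scaling would erase the
    within-type variance structure the shared per-type penalty acts on.
    """
    blocks, means, scales = [], [], []
    for b in dataset.blocks:
        mu = b.values.mean(axis=0) if center else np.zeros(b.n_features)
        centered = b.values - mu
        sd = float(np.sqrt(np.mean(centered ** 2)))
        if sd <= 0 or not np.isfinite(sd):
            raise ValidationError(
                f"data type {b.datatype_label!r} has zero pooled SD")
        blocks.append(OmicsMatrix(centered / sd, list(b.sample_ids),
                                  list(b.feature_ids), b.datatype_label,
                                  None if b.weights is None else b.weights.copy()))
        means.append(mu)
        scales.append(sd)
    info = ScalingInfo(means, np.array(scales), dataset.datatype_labels)
    return MultiOmicsDataset(blocks), info
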