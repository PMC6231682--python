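"""Readers, writers and containers for the formats the pipeline touches.

All matrices are oriented samples x features (N x n).  A multi-omics
dataset is an ordered stack of per-data-type matrices sharing one sample
order; the stacked matrix ``X = [X_1, ..., X_t]`` is what the factor
model consumes.

Coordinate conventions: SEG records are 1-based inclusive on both ends
(the common SEG dialect); BED-like region files are read with the same
convention by default and a ``zero_based`` flag converts half-open
0-based starts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger("funcsfa")

__all__ = [
    "OmicsMatrix",
    "MultiOmicsDataset",
    "SegmentTable",
    "RegionTable",
    "GeneSetCollection",
    "read_matrix",
    "write_matrix",
    "read_seg",
    "write_seg",
    "read_regions",
    "write_regions",
    "read_gmt",
    "write_gmt",
    "assemble_dataset",
    "save_dataset",
    "load_dataset",
]


def _check_unique(ids, axis_name: str) -> None:
    seen: dict[str, int] = {}
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {axis_name} id: {x!r}")
        seen[x] = 1


@dataclass
class OmicsMatrix:
    """One data type's samples x features matrix with optional precision weights."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    datatype_label: str
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-d matrix")
        n_s, n_f = self.values.shape
        if n_s != len(self.sample_ids):
            raise ValidationError(
                f"{n_s} rows but {len(self.sample_ids)} sample ids")
        if n_f != len(self.feature_ids):
            raise ValidationError(
                f"{n_f} columns but {len(self.feature_ids)} feature ids")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.isfinite(self.values).all():
            raise ValidationError(
                f"non-finite or missing values in {self.datatype_label!r} matrix")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.values.shape:
                raise ValidationError("weights shape does not match values")
            if not (np.isfinite(self.weights).all() and (self.weights > 0).all()):
                raise ValidationError("weights must be strictly positive and finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)

    def subset_samples(self, sample_order: list[str]) -> "OmicsMatrix":
        idx = [self.sample_ids.index(s) for s in sample_order]
        return OmicsMatrix(
            values=self.values[idx],
            sample_ids=list(sample_order),
            feature_ids=list(self.feature_ids),
            datatype_label=self.datatype_label,
            weights=None if self.weights is None else self.weights[idx],
        )

    def subset_features(self, col_idx) -> "OmicsMatrix":
        col_idx = np.asarray(col_idx, dtype=int)
        return OmicsMatrix(
            values=self.values[:, col_idx],
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[j] for j in col_idx],
            datatype_label=self.datatype_label,
            weights=None if self.weights is None else self.weights[:, col_idx],
        )


@dataclass
class MultiOmicsDataset:
    """Sample-aligned stack of per-data-type matrices."""

    blocks: list[OmicsMatrix]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError("dataset needs at least one block")
        ref = self.blocks[0].sample_ids
        for b in self.blocks[1:]:
            if b.sample_ids != ref:
                raise ValidationError(
                    f"block {b.datatype_label!r} sample order differs; "
                    "use assemble_dataset to align blocks")
        labels = [b.datatype_label for b in self.blocks]
        _check_unique(labels, "datatype")

    @property
    def sample_ids(self) -> list[str]:
        return self.blocks[0].sample_ids

    @property
    def n_samples(self) -> int:
        return self.blocks[0].n_samples

    @property
    def n_types(self) -> int:
        return len(self.blocks)

    @property
    def n_features(self) -> int:
        return sum(b.n_features for b in self.blocks)

    @property
    def datatype_labels(self) -> list[str]:
        return [b.datatype_label for b in self.blocks]

    @property
    def block_sizes(self) -> np.ndarray:
        return np.array([b.n_features for b in self.blocks], dtype=int)

    @property
    def block_slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.block_sizes)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    @property
    def datatype_of_feature(self) -> np.ndarray:
        """Map from global column index to data-type index."""
        return np.repeat(np.arange(self.n_types), self.block_sizes)

    @property
    def feature_ids(self) -> list[str]:
        out: list[str] = []
        for b in self.blocks:
            out.extend(b.feature_ids)
        return out

    def stacked(self) -> np.ndarray:
        """The N x n matrix X = [X_1, ..., X_t]."""
        return np.concatenate([b.values for b in self.blocks], axis=1)

    def block(self, i: int) -> OmicsMatrix:
        return self.blocks[i]


_SEG_COLUMNS = ["sample", "chrom", "start", "end", "value"]


@dataclass
class SegmentTable:
    """Segmented copy-number calls, 1-based inclusive coordinates."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _SEG_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"segment table missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["value"] = df["value"].astype(float)
        bad = df["start"] > df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise ValidationError(
                f"segment with start > end: {row['sample']} "
                f"{row['chrom']}:{row['start']}-{row['end']}")
        if not np.isfinite(df["value"]).all():
            raise ValidationError("non-numeric segment value")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


_REGION_COLUMNS = ["region_id", "chrom", "start", "end", "label"]


@dataclass
class RegionTable:
    """Recurrently aberrated regions (gain/loss intervals)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REGION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"region table missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        _check_unique(list(df["region_id"]), "region")
        if (df["start"] > df["end"]).any():
            raise ValidationError("region with start > end")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def read_matrix(path, datatype_label: str, transpose: bool = False,
                weights: np.ndarray | None = None) -> OmicsMatrix:
    """Read a TSV matrix: header row of feature ids, first column sample ids.

    Missing or non-numeric cells are rejected — the factor model has no
    missing-data mechanism.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    feature_ids = header[1:]
    _check_unique(feature_ids, "feature")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    _check_unique(list(df.index), "sample")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"missing value at sample {df.index[r]!r}, feature {df.columns[c]!r}")
    m = OmicsMatrix(values, list(df.index.astype(str)), feature_ids,
                    datatype_label, weights)
    if transpose:
        m = OmicsMatrix(m.values.T, m.feature_ids, m.sample_ids,
                        datatype_label, None)
    return m


def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="sample")


def read_seg(path, value_col: int = 4) -> SegmentTable:
    """Read a SEG-dialect file: >= 5 tab-separated columns
    (sample, chrom, start, end, value), optional single header line."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{ln}: expected >= 5 columns")
            if ln == 1:
                try:
                    int(parts[2])
                except ValueError:
                    continue  # header line
            try:
                rows.append((parts[0], parts[1], int(parts[2]), int(parts[3]),
                             float(parts[value_col])))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return SegmentTable(pd.DataFrame(rows, columns=_SEG_COLUMNS))


def write_seg(segments: SegmentTable, path) -> None:
    segments.df.to_csv(path, sep="\t", index=False, header=True)


def read_regions(path, zero_based: bool = False) -> RegionTable:
    """Read a BED-like region file: chrom, start, end, id, label."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{ln}: expected 5 columns")
            try:
                start = int(parts[1]) + (1 if zero_based else 0)
                rows.append((parts[3], parts[0], start, int(parts[2]), parts[4]))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return RegionTable(pd.DataFrame(rows, columns=_REGION_COLUMNS))


def write_regions(regions: RegionTable, path) -> None:
    df = regions.df[["chrom", "start", "end", "region_id", "label"]]
    df.to_csv(path, sep="\t", index=False, header=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then genes, tab-separated.

    Duplicate genes within a set are collapsed; duplicate set names are
    an error.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ValidationError(f"duplicate gene-set name: {name!r}")
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            sets[name] = genes
            descriptions[name] = parts[1]
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# dataset assembly and serialization


def assemble_dataset(blocks: list[OmicsMatrix]) -> MultiOmicsDataset:
    """Align blocks on the intersection of their sample ids.

    The common sample order follows the first block; samples missing from
    any block are dropped (count logged).
    """
    if not blocks:
        raise ValidationError("need at least one block")
    common = [s for s in blocks[0].sample_ids
              if all(s in set(b.sample_ids) for b in blocks[1:])]
    if not common:
        raise ValidationError("empty sample intersection across blocks")
    dropped = sum(b.n_samples - len(common) for b in blocks)
    if dropped:
        logger.info("assemble_dataset: dropped %d non-shared sample rows", dropped)
    return MultiOmicsDataset([b.subset_samples(common) for b in blocks])


def save_dataset(dataset: MultiOmicsDataset, path) -> None:
    """Write a dataset to HDF5 (one group per data type)."""
    with h5py.File(path, "w") as f:
        f.attrs["datatype_labels"] = json.dumps(dataset.datatype_labels)
        f.create_dataset("sample_ids",
                         data=np.array(dataset.sample_ids, dtype="S"))
        for b in dataset.blocks:
            g = f.create_group(f"block/{b.datatype_label}")
            g.create_dataset("values", data=b.values)
            g.create_dataset("feature_ids",
                             data=np.array(b.feature_ids, dtype="S"))
            if b.weights is not None:
                g.create_dataset("weights", data=b.weights)


def load_dataset(path) -> MultiOmicsDataset:
    with h5py.File(path, "r") as f:
        labels = json.loads(f.attrs["datatype_labels"])
        samples = [s.decode() for s in f["sample_ids"][()]]
        blocks = []
        for lab in labels:
            g = f[f"block/{lab}"]
            blocks.append(OmicsMatrix(
                values=g["values"][()],
                sample_ids=samples,
                feature_ids=[s.decode() for s in g["feature_ids"][()]],
                datatype_label=lab,
                weights=g["weights"][()] if "weights" in g else None,
            ))
    return MultiOmicsDataset(blocks)
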