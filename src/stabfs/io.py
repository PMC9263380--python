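"""Feature-table containers, file readers/writers and ROI feature extraction.

The central in-memory object is :class:`FeatureTable`, an n-subjects x
d-features real matrix with subject and feature identifiers — in the motivating
application the mean image intensity over each atlas region (ROI) per subject.
Tables round-trip through headered CSV/TSV with the subject id in the first
column; labels live in a separate two-column file keyed by subject id.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "FeatureTable",
    "LabelVector",
    "read_feature_table",
    "write_feature_table",
    "write_labels",
    "roi_mean_features",
]


@dataclass
class FeatureTable:
    """An n x d numeric feature matrix with subject and feature identifiers."""

    values: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("feature table must be a 2-D matrix")
        n, d = self.values.shape
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]
        if not self.feature_names:
            self.feature_names = [f"feat_{j + 1:03d}" for j in range(d)]
        if len(self.subject_ids) != n:
            raise DataError(f"{len(self.subject_ids)} subject ids for {n} rows")
        if len(self.feature_names) != d:
            raise DataError(f"{len(self.feature_names)} feature names for {d} columns")
        if len(set(self.subject_ids)) != n:
            raise DataError("subject ids are not unique")
        if len(set(self.feature_names)) != d:
            raise DataError("feature names are not unique")
        if n < 4:
            raise DataError(f"need at least 4 subjects, got {n}")
        if d < 2:
            raise DataError(f"need at least 2 features, got {d}")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite value at row {bad[0]} ({self.subject_ids[bad[0]]}), "
                f"column {bad[1]} ({self.feature_names[bad[1]]})"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.feature_names,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(
            values=df.to_numpy(dtype=float),
            subject_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
        )


@dataclass
class LabelVector:
    """Binary diagnosis labels aligned to a FeatureTable's subject order."""

    labels: np.ndarray
    positive_class_name: str = "case"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise DataError("labels must be a 1-D vector")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {0, 1}:
            raise DataError(f"labels must be 0/1, found {sorted(uniq)}")
        if uniq != {0, 1}:
            raise DataError("both classes must be present in the labels")


def _read_delimited(path: str | os.PathLike) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_feature_table(path: str | os.PathLike,
                       labels_path: str | os.PathLike | None = None,
                       positive_class: str | None = None,
                       ) -> tuple[FeatureTable, LabelVector | None]:
    """Read a feature table (and optionally a label file aligned by subject id).

    The feature file is CSV or TSV (sniffed from the extension) with a header
    row of feature names and the subject id in the first column.  The label
    file maps subject id -> class; classes may be given as 0/1 or as two class
    names, in which case ``positive_class`` (default: lexicographically larger
    name) is coded 1.
    """
    df = _read_delimited(path)
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise DataError(
            f"missing value at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    try:
        table = FeatureTable.from_dataframe(df.astype(float))
    except (TypeError, ValueError) as exc:
        raise DataError(f"non-numeric cell in {path}: {exc}") from exc

    if labels_path is None:
        return table, None

    lab = _read_delimited(labels_path)
    if lab.shape[1] < 1:
        raise DataError(f"label file {labels_path} needs a label column")
    series = lab.iloc[:, 0]
    series.index = series.index.map(str)
    missing = [s for s in table.subject_ids if s not in series.index]
    if missing:
        raise DataError(f"label file missing subjects: {missing}")
    aligned = series.loc[table.subject_ids]
    classes = sorted(set(aligned))
    if set(classes) <= {0, 1}:
        labels = aligned.to_numpy(dtype=int)
        pos_name = positive_class or "1"
    else:
        if len(classes) != 2:
            raise DataError(f"expected 2 classes, found {classes}")
        pos = positive_class if positive_class is not None else classes[1]
        if pos not in classes:
            raise DataError(f"positive class {pos!r} not among {classes}")
        labels = (aligned == pos).to_numpy(dtype=int)
        pos_name = str(pos)
    return table, LabelVector(labels=labels, positive_class_name=pos_name)


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    table.to_dataframe().to_csv(path, sep=sep)


def write_labels(labels: LabelVector, subject_ids: Sequence[str],
                 path: str | os.PathLike) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.Series(labels.labels, index=pd.Index(subject_ids, name="subject_id"),
              name="label").to_csv(path, sep=sep)


def roi_mean_features(intensity: np.ndarray, label_volume: np.ndarray,
                      region_ids: Sequence[int]) -> np.ndarray:
    """Mean intensity per labelled region of a pair of aligned 3-D volumes.

    ``intensity`` and ``label_volume`` must share a voxel grid (alignment and
    resampling are the caller's responsibility).  Returns one mean per entry of
    ``region_ids``, in that order.
    """
    intensity = np.asarray(intensity, dtype=float)
    label_volume = np.asarray(label_volume)
    if intensity.shape != label_volume.shape:
        raise DataError(
            f"shape mismatch: intensity {intensity.shape} vs labels {label_volume.shape}"
        )
    present = set(np.unique(label_volume).tolist())
    missing = [r for r in region_ids if r not in present]
    if missing:
        raise DataError(f"region ids absent from label volume: {missing}")
    return np.array([intensity[label_volume == r].mean() for r in region_ids])
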