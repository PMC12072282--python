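"""Domain containers, tabular I/O and preprocessing.

The universal input is an :class:`OmicsDataset`: a samples x features matrix
of continuous intensities (proteomic/metabolomic) or {0,1} mutation
indicators, with a binary class label per sample.  Cross-validation folds
are planned once (:class:`FoldPlan`) and shared by feature selection and
classifier evaluation, so that every stage sees the same stratified splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsDataset",
    "FoldPlan",
    "PreprocessSpec",
    "read_feature_table",
    "write_feature_table",
    "log2_transform",
    "make_fold_plan",
]


@dataclass(frozen=True)
class OmicsDataset:
    """A samples x features matrix with binary class labels.

    Parameters
    ----------
    sample_ids : list of str
        Opaque per-sample identifiers, one per row of ``values``.
    feature_names : list of str
        Unique feature identifiers, one per column of ``values``.
    values : ndarray of shape (n_samples, n_features)
        Continuous intensities or {0,1} indicators.
    labels : ndarray of shape (n_samples,)
        Binary class codes; by convention 0 = female, 1 = male.
    value_kind : {"continuous", "binary"}
    label_mapping : dict
        Original label string -> {0,1} code, recorded for reporting.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    value_kind: str = "continuous"
    label_mapping: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.sample_ids) != values.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {values.shape[0]} rows"
            )
        if len(self.feature_names) != values.shape[1]:
            raise ValueError(
                f"{len(self.feature_names)} feature names for "
                f"{values.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            dupes = pd.Index(self.feature_names)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate feature names: {dupes[:5]}")
        if labels.shape != (values.shape[0],):
            raise ValueError("labels must be one code per sample")
        classes = np.unique(labels)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(
                f"labels must contain exactly the two classes 0 and 1, got {classes}"
            )
        if self.value_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "binary" and not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("binary dataset contains entries outside {0,1}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(count of class 0, count of class 1)."""
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def restrict(self, feature_indices: "np.ndarray | list[int]") -> "OmicsDataset":
        """Return a copy restricted to the given feature columns (in order)."""
        idx = np.asarray(list(feature_indices), dtype=int)
        return replace(
            self,
            feature_names=[self.feature_names[i] for i in idx],
            values=self.values[:, idx],
        )


@dataclass(frozen=True)
class FoldPlan:
    """Stratified fold membership, fixed by seed and reused everywhere.

    ``assignments[i]`` is the fold index (in ``[0, n_folds)``) in which
    sample ``i`` serves as the held-out test sample.
    """

    n_folds: int
    seed: int
    assignments: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments, dtype=int)
        object.__setattr__(self, "assignments", a)
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if a.min() < 0 or a.max() >= self.n_folds:
            raise ValueError("fold assignment outside [0, n_folds)")

    def splits(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (train_idx, test_idx) per fold, in fold order."""
        for f in range(self.n_folds):
            test = np.flatnonzero(self.assignments == f)
            train = np.flatnonzero(self.assignments != f)
            yield train, test


@dataclass(frozen=True)
class PreprocessSpec:
    """Preprocessing switches.

    ``standardize`` z-scores each feature using statistics fit on the
    training split only, and is applied before LASSO and before the
    scale-sensitive classifiers (SVM, KNN, LR) — never before tree
    ensembles.  ``log2`` applies log2(x + pseudocount) up front.
    """

    log2: bool = False
    pseudocount: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_feature_table(
    path: str | Path,
    label_column: str,
    delimiter: str | None = None,
    orientation: str = "samples_as_rows",
    value_kind: str | None = None,
    label_mapping: dict[str, int] | None = None,
) -> OmicsDataset:
    """Read a CSV/TSV feature table into an :class:`OmicsDataset`.

    Parameters
    ----------
    path : str or Path
        Delimited text file with a header row.
    label_column : str
        Column (or row, under ``features_as_rows``) holding the class label;
        exactly two distinct label values are required.
    delimiter : str, optional
        Field delimiter; inferred from the file suffix when omitted.
    orientation : {"samples_as_rows", "features_as_rows"}
        Omics exports come both ways; ``features_as_rows`` tables are
        transposed on read (first column = feature name, header = sample id).
    value_kind : {"continuous", "binary"}, optional
        Inferred from the data when omitted.
    label_mapping : dict, optional
        Explicit label string -> {0,1} mapping; by default sorted label
        strings map to 0 and 1 (so e.g. F -> 0, M -> 1).

    Returns
    -------
    OmicsDataset
        Validated dataset; the applied label mapping is stored on it and
        logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "features_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if label_column not in df.columns:
        raise ValueError(
            f"label column {label_column!r} not found; columns start with "
            f"{list(df.columns[:5])}"
        )
    raw_labels = df[label_column].astype(str)
    distinct = sorted(raw_labels.unique())
    if len(distinct) != 2:
        raise ValueError(
            f"label column {label_column!r} has {len(distinct)} distinct values "
            f"({distinct[:4]}); exactly two classes are required"
            + (" (more than two classes)" if len(distinct) > 2 else "")
        )
    if label_mapping is None:
        label_mapping = {distinct[0]: 0, distinct[1]: 1}
    elif sorted(label_mapping.keys()) != distinct or sorted(
        label_mapping.values()
    ) != [0, 1]:
        raise ValueError(f"label_mapping must map {distinct} onto {{0, 1}}")
    logger.info("label mapping: %s", label_mapping)

    feat = df.drop(columns=[label_column])
    matrix = np.empty(feat.shape, dtype=float)
    for j, col in enumerate(feat.columns):
        converted = pd.to_numeric(feat[col], errors="coerce")
        bad = converted.isna() & feat[col].notna()
        if bad.any():
            row = feat.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ValueError(
                f"non-numeric value {feat.loc[row, col]!r} at row {row!r}, "
                f"column {col!r}"
            )
        matrix[:, j] = converted.to_numpy(dtype=float)

    if value_kind is None:
        value_kind = "binary" if np.isin(matrix, (0.0, 1.0)).all() else "continuous"
    return OmicsDataset(
        sample_ids=[str(s) for s in df.index],
        feature_names=[str(c) for c in feat.columns],
        values=matrix,
        labels=raw_labels.map(label_mapping).to_numpy(dtype=int),
        value_kind=value_kind,
        label_mapping=dict(label_mapping),
    )


def write_feature_table(
    ds: OmicsDataset,
    path: str | Path,
    label_column: str = "label",
    delimiter: str | None = None,
) -> Path:
    """Write a dataset back to delimited text (samples as rows, header row).

    Labels are written as the original strings when a mapping is recorded,
    otherwise as the 0/1 codes.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    inverse = {v: k for k, v in ds.label_mapping.items()}
    labels = [inverse.get(int(c), int(c)) for c in ds.labels]
    df = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.feature_names)
    df.insert(0, label_column, labels)
    df.to_csv(path, sep=sep, index_label="sample_id")
    return path


def log2_transform(ds: OmicsDataset, pseudocount: float = 1.0) -> OmicsDataset:
    """Replace every entry x by log2(x + pseudocount).

    Standard variance stabilisation for intensity data; shape and labels are
    unchanged.  Raises when any shifted entry is nonpositive, naming the
    offending cell.
    """
    if ds.value_kind != "continuous":
        raise ValueError("log2 transform applies to continuous data only")
    shifted = ds.values + pseudocount
    if (shifted <= 0).any():
        i, j = np.argwhere(shifted <= 0)[0]
        raise ValueError(
            f"log2 undefined for value {ds.values[i, j]} + pseudocount "
            f"{pseudocount} at sample {ds.sample_ids[i]!r}, feature "
            f"{ds.feature_names[j]!r}"
        )
    return replace(ds, values=np.log2(shifted))


def make_fold_plan(labels: np.ndarray, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Plan stratified k-fold membership, deterministic in (labels, n_folds, seed).

    Every fold keeps the full dataset's class proportions to within one
    sample per class, and fold sizes differ by at most one.
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    small = counts < n_folds
    if small.any():
        c = classes[small][0]
        raise ValueError(
            f"class {c} has only {counts[small][0]} members; "
            f"need at least n_folds={n_folds} per class"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(n_folds=n_folds, seed=seed, assignments=assignments)
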