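"""Dataset model, delimited-text I/O, splitting and fold construction.

The central container is :class:`ExpressionDataset`: a samples x
features real matrix with binary labels recoded internally to {+1, -1},
where +1 is always the minority class.  That convention fixes the
"positive" class for every downstream metric and the class-weighting
scheme of the weighted SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split


class DatasetError(ValueError):
    """Base class for dataset validation failures."""


class MissingLabelColumnError(DatasetError):
    pass


class ClassCountError(DatasetError):
    """Raised when the label column does not hold exactly two classes."""


class NonNumericCellError(DatasetError):
    """Raised on a non-numeric expression value; reports its coordinates."""


class EmptyTableError(DatasetError):
    pass


class MissingValueError(DatasetError):
    pass


@dataclass(frozen=True)
class ExpressionDataset:
    """Two-class expression matrix with sample and feature annotation.

    ``labels`` are {+1, -1} with the minority class mapped to +1.
    ``label_names`` records the original label string for each code so
    reports can print the user's class names.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]
    sample_ids: tuple[str, ...]
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", y)
        if m.ndim != 2:
            raise DatasetError("matrix must be 2-dimensional")
        if m.shape[0] != y.shape[0]:
            raise DatasetError(
                f"{m.shape[0]} rows but {y.shape[0]} labels"
            )
        if len(self.feature_names) != m.shape[1]:
            raise DatasetError("feature_names length mismatch")
        if len(self.sample_ids) != m.shape[0]:
            raise DatasetError("sample_ids length mismatch")
        if np.isnan(m).any():
            raise MissingValueError("matrix contains missing values")
        classes = np.unique(y)
        # subsets of a dataset (splits, folds) inherit the coding, so only
        # the code set is enforced here; minority=+1 is established by the
        # loader/generator on the full dataset
        if classes.size != 2 or set(classes) != {-1, 1}:
            raise ClassCountError(
                f"labels must be exactly {{+1, -1}}, got {classes.tolist()}"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset_samples(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            matrix=self.matrix[idx],
            labels=self.labels[idx],
            sample_ids=tuple(self.sample_ids[i] for i in idx),
        )

    def summary(self) -> dict:
        """Per-dataset summary: size, class counts, imbalance ratio."""
        n_pos = int(np.sum(self.labels == 1))
        n_neg = int(np.sum(self.labels == -1))
        return {
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "minority_count": n_pos,
            "majority_count": n_neg,
            "imbalance_ratio": imbalance_ratio(self.labels),
        }


@dataclass(frozen=True)
class SplitSpec:
    """Train/test fraction, fold count and seed for all partitioning."""

    train_fraction: float = 0.8
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise DatasetError("train_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise DatasetError("n_folds must be >= 2")


def encode_labels(raw: pd.Series) -> tuple[np.ndarray, dict[int, str]]:
    """Map the two raw label values to {+1 minority, -1 majority}.

    Ties are broken by assigning +1 to the lexicographically smaller
    label so encoding is deterministic.
    """
    values = raw.astype(str)
    counts = values.value_counts()
    if len(counts) != 2:
        raise ClassCountError(
            f"expected exactly 2 classes, found {len(counts)}: "
            f"{sorted(counts.index.tolist())}"
        )
    a, b = sorted(counts.index.tolist())
    if counts[a] < counts[b]:
        minority, majority = a, b
    elif counts[b] < counts[a]:
        minority, majority = b, a
    else:
        minority, majority = a, b
    y = np.where(values.to_numpy() == minority, 1, -1)
    return y, {1: minority, -1: majority}


def load_expression_table(
    path,
    label_column: str = "class",
    orientation: str = "samples-in-rows",
    sep: str | None = None,
    impute_missing: bool = False,
) -> ExpressionDataset:
    """Read a delimited expression table into an :class:`ExpressionDataset`.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    label_column
        Column (or, for ``features-in-rows``, row index entry) holding
        the class label.
    orientation
        ``samples-in-rows`` (default) or ``features-in-rows``; microarray
        files are commonly shipped genes x samples, so orientation is an
        explicit flag and never guessed.
    sep
        Field separator; inferred from the file extension when None.
    impute_missing
        Replace missing expression values by the feature mean instead of
        rejecting the file.
    """
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise DatasetError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise EmptyTableError(f"{path}: empty file") from exc
    if df.empty:
        raise EmptyTableError(f"{path}: table has no data rows")
    if orientation == "features-in-rows":
        df = df.T
    if label_column not in df.columns:
        raise MissingLabelColumnError(
            f"label column {label_column!r} not found; columns start with "
            f"{df.columns[:5].tolist()}"
        )
    labels_raw = df[label_column]
    expr = df.drop(columns=[label_column])
    numeric = expr.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & expr.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise NonNumericCellError(
            f"non-numeric expression value {expr.iat[r, c]!r} at "
            f"sample {expr.index[r]!r}, feature {expr.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        if impute_missing:
            numeric = numeric.fillna(numeric.mean())
        else:
            raise MissingValueError(
                f"{path}: missing expression values (pass impute_missing=True "
                "to mean-impute)"
            )
    y, names = encode_labels(labels_raw)
    return ExpressionDataset(
        matrix=numeric.to_numpy(dtype=float),
        labels=y,
        feature_names=tuple(str(c) for c in numeric.columns),
        sample_ids=tuple(str(i) for i in numeric.index),
        label_names=names,
    )


def write_expression_table(ds: ExpressionDataset, path, label_column: str = "class") -> None:
    """Write a dataset back to delimited text (inverse of the loader)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.DataFrame(ds.matrix, index=list(ds.sample_ids), columns=list(ds.feature_names))
    raw = [ds.label_names.get(int(y), str(int(y))) for y in ds.labels]
    df[label_column] = raw
    df.to_csv(path, sep=sep, index_label="sample_id")


def split_train_test(
    ds: ExpressionDataset, spec: SplitSpec
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Stratified train/test split, deterministic for a fixed seed."""
    counts = np.bincount((ds.labels == 1).astype(int), minlength=2)
    if counts.min() < 2:
        raise ClassCountError("each class needs >= 2 samples to split")
    idx = np.arange(ds.n_samples)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=ds.labels,
        random_state=spec.seed,
    )
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    return ds.subset_samples(train_idx), ds.subset_samples(test_idx)


def make_cv_folds(
    ds: ExpressionDataset, spec: SplitSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified K-fold partition of the sample indices."""
    minority = int(np.sum(ds.labels == 1))
    if spec.n_folds > minority:
        raise ClassCountError(
            f"n_folds={spec.n_folds} exceeds minority class count {minority}"
        )
    skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    return [
        (np.sort(tr), np.sort(va))
        for tr, va in skf.split(ds.matrix, ds.labels)
    ]


def imbalance_ratio(labels: np.ndarray) -> float:
    """Majority count over minority count, rounded to 2 decimals.

    Rounding is round-half-to-even (Python's built-in).
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.size < 2:
        raise ClassCountError("imbalance ratio undefined for a single class")
    if counts.size > 2:
        raise ClassCountError("imbalance ratio defined for two classes only")
    return round(counts.max() / counts.min(), 2)
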