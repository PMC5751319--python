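"""Labeled feature datasets and their tab-separated on-disk form.

A :class:`LabeledDataset` is the in-memory container every stage of the
pipeline consumes: ``N`` feature vectors of common dimension ``p`` split
into ``C`` nonempty classes.  On disk a dataset is a TSV table with a
header row, one sample per row: ``id``, ``label``, then the features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset", "load_features_tsv", "save_features_tsv"]


@dataclass
class LabeledDataset:
    """N feature vectors with class labels over C >= 2 classes.

    Parameters
    ----------
    X : ndarray of shape (N, p)
        Feature vectors; must be finite.
    y : ndarray of shape (N,)
        Integer class indices ``0..C-1``.
    ids : list of str, optional
        Per-sample identifiers (defaults to ``"s0".."s{N-1}"``).
    class_names : list of str, optional
        Human-readable names, one per class index.
    """

    X: np.ndarray
    y: np.ndarray
    ids: list[str] | None = None
    class_names: list[str] | None = None
    _class_sizes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must have one label per row of X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        classes = np.unique(self.y)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        if not np.array_equal(classes, np.arange(classes.size)):
            raise ValueError("labels must be consecutive integers starting at 0")
        if self.X.shape[0] < classes.size:
            raise ValueError("need at least one sample per class")
        self._class_sizes = np.bincount(self.y)
        if self.ids is None:
            self.ids = [f"s{i}" for i in range(self.X.shape[0])]
        elif len(self.ids) != self.X.shape[0]:
            raise ValueError("ids must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self._class_sizes.size)

    @property
    def class_sizes(self) -> np.ndarray:
        """Number of samples in each class (sums to N)."""
        return self._class_sizes.copy()

    def class_indices(self, c: int) -> np.ndarray:
        """Row indices of the samples belonging to class ``c``."""
        return np.flatnonzero(self.y == c)

    def largest_class(self) -> int:
        """Index of the class with the most samples (ties: lowest index)."""
        return int(np.argmax(self._class_sizes))

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        """Dataset restricted to ``rows`` (labels are NOT re-indexed)."""
        rows = np.asarray(rows)
        return LabeledDataset(
            self.X[rows],
            self.y[rows],
            ids=[self.ids[i] for i in rows],
            class_names=self.class_names,
        )


def load_features_tsv(path) -> LabeledDataset:
    """Read a feature table: header row, then ``id<TAB>label<TAB>features...``.

    Labels may be arbitrary strings; they are mapped to class indices in
    sorted order and the original names kept in ``class_names``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected at least 3 columns (id, label, features)")
    ids = df.iloc[:, 0].tolist()
    raw_labels = df.iloc[:, 1].astype(str)
    names = sorted(raw_labels.unique())
    index = {name: i for i, name in enumerate(names)}
    y = raw_labels.map(index).to_numpy()
    X = df.iloc[:, 2:].to_numpy(dtype=float)
    return LabeledDataset(X, y, ids=ids, class_names=names)


def save_features_tsv(path, data: LabeledDataset, feature_names: list[str] | None = None) -> None:
    """Write a dataset as a TSV feature table (inverse of :func:`load_features_tsv`)."""
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(data.n_features)]
    if len(feature_names) != data.n_features:
        raise ValueError("feature_names length must equal the feature dimension")
    if data.class_names is not None:
        labels = [data.class_names[c] for c in data.y]
    else:
        labels = [str(c) for c in data.y]
    df = pd.DataFrame(data.X, columns=feature_names)
    df.insert(0, "label", labels)
    df.insert(0, "id", data.ids)
    df.to_csv(path, sep="\t", index=False)
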