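"""Dataset container and resampling primitives.

Everything downstream (hyperparameter tuning, ensemble building,
permutation testing) indexes into a single :class:`LabeledDataset`.
Three resampling operations are defined here:

* stratified holdout — the outer train/test partition that isolates an
  independent test set for each ensemble member,
* bootstrap resampling — training-set-sized draws with replacement whose
  out-of-bag (OOB) complements serve as internal test sets during
  hyperparameter optimisation,
* label permutation — the shuffling primitive behind the permutation test.

All indices are 0-based. All randomness flows through an explicit
:class:`numpy.random.Generator`, so equal seeds give bit-identical splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "HoldoutSplit",
    "BootstrapSplit",
    "stratified_holdout",
    "bootstrap_split",
    "permute_labels",
    "DatasetError",
]


class DatasetError(ValueError):
    """Structured validation error for datasets and splits."""


@dataclass(frozen=True)
class LabeledDataset:
    """A numeric sample × variable matrix with one class label per sample.

    Parameters
    ----------
    matrix
        Real-valued array of shape ``(n_samples, n_variables)``. Missing or
        non-finite values are rejected outright: any imputation or other
        preprocessing belongs upstream of this package.
    labels
        Categorical vector of length ``n_samples``. At least two distinct
        classes, each with at least two samples.
    sample_ids, variable_ids
        Optional string identifiers; generated (``S0..``, ``V0..``) when
        omitted.
    """

    matrix: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray | None = None
    variable_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels)
        if matrix.ndim != 2:
            raise DatasetError(f"matrix must be 2-D, got shape {matrix.shape}")
        n, p = matrix.shape
        if n < 4:
            raise DatasetError(f"need at least 4 samples, got {n}")
        if p < 1:
            raise DatasetError("need at least 1 variable")
        if not np.isfinite(matrix).all():
            bad = np.argwhere(~np.isfinite(matrix))[0]
            raise DatasetError(
                f"matrix contains missing/non-finite value at row {bad[0]}, "
                f"column {bad[1]}; impute or filter before loading"
            )
        if labels.shape != (n,):
            raise DatasetError(
                f"labels length {labels.shape} does not match {n} samples"
            )
        classes, counts = np.unique(labels, return_counts=True)
        if classes.size < 2:
            raise DatasetError("need at least 2 distinct classes")
        small = classes[counts < 2]
        if small.size:
            raise DatasetError(
                f"class {small[0]!r} has fewer than 2 samples"
            )
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", labels)
        if self.sample_ids is None:
            object.__setattr__(
                self, "sample_ids", np.array([f"S{i}" for i in range(n)])
            )
        else:
            sids = np.asarray(self.sample_ids)
            if sids.shape != (n,):
                raise DatasetError("sample_ids length mismatch")
            if np.unique(sids).size != n:
                raise DatasetError("duplicate sample IDs")
            object.__setattr__(self, "sample_ids", sids)
        if self.variable_ids is None:
            object.__setattr__(
                self, "variable_ids", np.array([f"V{j}" for j in range(p)])
            )
        else:
            vids = np.asarray(self.variable_ids)
            if vids.shape != (p,):
                raise DatasetError("variable_ids length mismatch")
            object.__setattr__(self, "variable_ids", vids)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variables(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_counts(self) -> dict:
        classes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(classes.tolist(), counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a DataFrame indexed by sample ID, labels appended."""
        df = pd.DataFrame(
            self.matrix, index=self.sample_ids, columns=self.variable_ids
        )
        df.insert(0, "class", self.labels)
        return df


@dataclass(frozen=True)
class HoldoutSplit:
    """Stratified train/test partition of a dataset's sample indices."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    test_fraction: float

    def __post_init__(self) -> None:
        train = np.asarray(self.train_idx, dtype=np.intp)
        test = np.asarray(self.test_idx, dtype=np.intp)
        if np.intersect1d(train, test).size:
            raise DatasetError("train and test indices overlap")
        object.__setattr__(self, "train_idx", train)
        object.__setattr__(self, "test_idx", test)


@dataclass(frozen=True)
class BootstrapSplit:
    """One bootstrap draw: in-bag multiset and its out-of-bag complement."""

    in_bag: np.ndarray
    oob: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "in_bag", np.asarray(self.in_bag, dtype=np.intp))
        object.__setattr__(self, "oob", np.asarray(self.oob, dtype=np.intp))
        if self.oob.size == 0:
            raise DatasetError("out-of-bag set must be non-empty")


def _per_class_test_count(class_count: int, test_fraction: float) -> int:
    # half-up rounding, then clamp so every class keeps >=1 sample on
    # each side of the partition
    k = int(np.floor(class_count * test_fraction + 0.5))
    return min(max(k, 1), class_count - 1)


def stratified_holdout(
    data: LabeledDataset,
    test_fraction: float = 1.0 / 3.0,
    rng: np.random.Generator | None = None,
) -> HoldoutSplit:
    """Partition samples into train/test preserving class proportions.

    Per-class test count is ``round(class_count * test_fraction)`` clamped
    to leave at least one sample per class on each side; within each class
    the test members are drawn uniformly without replacement. The held-out
    test set is untouched by all subsequent optimisation.
    """
    if not 0.0 < test_fraction < 1.0:
        raise DatasetError(f"test_fraction must lie in (0,1), got {test_fraction}")
    rng = np.random.default_rng(rng)
    test_parts: list[np.ndarray] = []
    train_parts: list[np.ndarray] = []
    for cls in data.classes:
        idx = np.flatnonzero(data.labels == cls)
        if idx.size < 2:
            raise DatasetError(f"class {cls!r} has fewer than 2 samples")
        k = _per_class_test_count(idx.size, test_fraction)
        chosen = rng.choice(idx, size=k, replace=False)
        test_parts.append(np.sort(chosen))
        train_parts.append(np.setdiff1d(idx, chosen))
    return HoldoutSplit(
        train_idx=np.sort(np.concatenate(train_parts)),
        test_idx=np.sort(np.concatenate(test_parts)),
        test_fraction=test_fraction,
    )


def bootstrap_split(
    train_idx: np.ndarray,
    rng: np.random.Generator | None = None,
    max_retries: int = 100,
) -> BootstrapSplit:
    """Draw one bootstrap sample of the training indices.

    The in-bag multiset has exactly ``len(train_idx)`` members drawn with
    replacement; the out-of-bag set is the complement of the in-bag
    uniques. Draws whose OOB set would be empty (possible at tiny n) are
    redrawn up to ``max_retries`` times.
    """
    train_idx = np.asarray(train_idx, dtype=np.intp)
    if train_idx.size < 2:
        raise DatasetError(
            f"need at least 2 training samples to bootstrap, got {train_idx.size}"
        )
    rng = np.random.default_rng(rng)
    for _ in range(max_retries):
        in_bag = rng.choice(train_idx, size=train_idx.size, replace=True)
        oob = np.setdiff1d(train_idx, in_bag)
        if oob.size:
            return BootstrapSplit(in_bag=in_bag, oob=oob)
    raise DatasetError(
        f"could not draw a bootstrap sample with non-empty OOB set "
        f"in {max_retries} attempts"
    )


def permute_labels(
    labels: np.ndarray, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Return a uniformly random permutation of the label vector.

    Per-class counts are preserved exactly — only the association between
    rows and classes is broken.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise DatasetError("cannot permute an empty label vector")
    rng = np.random.default_rng(rng)
    return labels[rng.permutation(labels.size)]
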