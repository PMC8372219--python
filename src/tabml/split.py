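"""Reproducible train/test partitions.

Three methods are provided:

* ``stratified`` — preserves the outcome-class proportions of the full
  dataset on both sides (continuous outcomes are stratified on quartile
  bins);
* ``grouped`` — whole groups (batch, site, ...) are assigned to one side
  only, so no group label leaks across the split;
* ``simple`` — uniform random split, as a fallback for degenerate inputs.

All randomness flows from the explicit seed through a dedicated
``numpy.random.Generator``; the same seed always yields the same split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import DataError


@dataclass
class DataSplit:
    """A train/test partition with its provenance."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    method: str  # "stratified" | "grouped" | "simple"
    training_frac: float

    def __post_init__(self) -> None:
        train = np.asarray(self.train_indices, dtype=int)
        test = np.asarray(self.test_indices, dtype=int)
        self.train_indices = train
        self.test_indices = test
        if len(train) == 0 or len(test) == 0:
            raise DataError("both train and test sides must be non-empty")
        if np.intersect1d(train, test).size > 0:
            raise DataError("train and test indices overlap")

    @property
    def sizes(self):
        return (len(self.train_indices), len(self.test_indices))

    def to_frame(self) -> pd.DataFrame:
        n = len(self.train_indices) + len(self.test_indices)
        part = np.empty(n, dtype=object)
        part[self.train_indices] = "train"
        part[self.test_indices] = "test"
        return pd.DataFrame({"sample_index": np.arange(n), "partition": part})


def _quartile_bins(values: Sequence[float]) -> np.ndarray:
    """Quartile-bin a continuous outcome for stratification."""
    s = pd.Series(np.asarray(values, dtype=float))
    return pd.qcut(s.rank(method="first"), q=4, labels=False, duplicates="drop").to_numpy()


def stratified_split(
    outcome: Sequence,
    training_frac: float,
    seed: int,
    outcome_kind: str = "binary",
) -> DataSplit:
    """Outcome-stratified split.

    Per class ``c`` with ``n_c`` samples, the training side receives
    ``round(training_frac * n_c)`` samples (round-half-even) chosen uniformly
    at random under ``seed``.  If the summed training size drifts more than
    one sample from ``round(training_frac * n)``, the class whose rounding
    error has the matching sign is nudged by one, so the per-class training
    fraction never deviates from ``training_frac`` by more than one sample.
    """
    if not (0.0 < training_frac < 1.0):
        raise DataError("training_frac must be in (0, 1)")
    outcome = np.asarray(outcome, dtype=object)
    n = len(outcome)
    if outcome_kind == "continuous":
        labels = _quartile_bins(outcome)
    else:
        labels = np.array([str(v) for v in outcome], dtype=object)

    classes = sorted(set(labels.tolist()))
    class_idx = {c: np.flatnonzero(labels == c) for c in classes}
    for c, idx in class_idx.items():
        if len(idx) < 2:
            raise DataError(
                f"outcome class {c!r} has a single sample; remove it or use a simple split"
            )

    n_train = {c: int(round(training_frac * len(class_idx[c]))) for c in classes}
    for c in classes:
        n_train[c] = min(max(n_train[c], 0), len(class_idx[c]))

    # nudge toward the global target while keeping per-class deviation <= 1
    target = int(round(training_frac * n))
    while abs(sum(n_train.values()) - target) > 1:
        drift = sum(n_train.values()) - target
        err = {c: n_train[c] - training_frac * len(class_idx[c]) for c in classes}
        if drift > 0:
            movable = [c for c in classes if n_train[c] > 0]
            c = max(movable, key=lambda c: (err[c], -classes.index(c)))
            n_train[c] -= 1
        else:
            movable = [c for c in classes if n_train[c] < len(class_idx[c])]
            c = min(movable, key=lambda c: (err[c], classes.index(c)))
            n_train[c] += 1

    # never leave a side globally empty
    if sum(n_train.values()) == 0:
        c = max(classes, key=lambda c: len(class_idx[c]))
        n_train[c] = 1
    if sum(n_train.values()) == n:
        c = max(classes, key=lambda c: len(class_idx[c]))
        n_train[c] -= 1

    rng = np.random.default_rng(seed)
    train = []
    for c in classes:
        perm = rng.permutation(class_idx[c])
        train.append(perm[: n_train[c]])
    train = np.sort(np.concatenate(train))
    test = np.setdiff1d(np.arange(n), train)
    return DataSplit(train, test, seed=seed, method="stratified", training_frac=training_frac)


def grouped_split(groups: Sequence, training_frac: float, seed: int) -> DataSplit:
    """Group-aware split: no group label appears on both sides.

    Groups are shuffled under ``seed`` and assigned whole to the training
    side until the cumulative sample count first reaches
    ``training_frac * n``; the remaining groups form the test side.
    """
    if not (0.0 < training_frac < 1.0):
        raise DataError("training_frac must be in (0, 1)")
    labels = np.array([str(g) for g in groups], dtype=object)
    n = len(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) < 2:
        raise DataError("grouped split requires at least 2 distinct groups")

    rng = np.random.default_rng(seed)
    order = [uniq[i] for i in rng.permutation(len(uniq))]
    target = training_frac * n
    train_groups, cum = [], 0
    it = iter(order)
    for g in it:
        train_groups.append(g)
        cum += int((labels == g).sum())
        if cum >= target:
            break
    test_groups = [g for g in order if g not in train_groups]
    if not test_groups:
        moved = train_groups.pop()
        test_groups = [moved]
        warnings.warn(
            f"grouped split left the test side empty; moved group {moved!r} to test"
        )
    train = np.flatnonzero(np.isin(labels, train_groups))
    test = np.flatnonzero(np.isin(labels, test_groups))
    return DataSplit(train, test, seed=seed, method="grouped", training_frac=training_frac)


def simple_split(n: int, training_frac: float, seed: int) -> DataSplit:
    """Uniform random split without stratification."""
    if not (0.0 < training_frac < 1.0):
        raise DataError("training_frac must be in (0, 1)")
    if n < 2:
        raise DataError("need at least 2 samples to split")
    n_train = min(max(int(round(training_frac * n)), 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return DataSplit(
        np.sort(perm[:n_train]),
        np.sort(perm[n_train:]),
        seed=seed,
        method="simple",
        training_frac=training_frac,
    )
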