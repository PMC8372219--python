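"""Feature preprocessing with full bookkeeping.

The pipeline applies, in order:

1. removal of constant features (constant over non-missing values),
2. re-factoring of categorical features into binary indicator columns,
3. centering/scaling of continuous features (median-imputing missing values),
4. near-zero-variance removal (frequency-ratio + unique-percentage rule),
5. collapsing of perfectly correlated features, keeping one representative
   per group (the group is what permutation importance later permutes
   together).

Preprocessing statistics are computed on the FULL dataset before any
train/test split.  This mirrors the reference pipeline's preprocess-then-
split order and is a documented information-leakage caveat: test samples
contribute to the normalization means/SDs and to filter decisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .core_data import DataError, Dataset

#: Frequency ratio (most common count / second most common count) at or
#: above which a feature is a near-zero-variance candidate.  95/5 = 19.
DEFAULT_FREQ_CUT = 95.0 / 5.0

#: Percentage of distinct values at or below which a feature is a
#: near-zero-variance candidate.
DEFAULT_UNIQUE_CUT = 10.0

#: Numerical tolerance for "perfect" correlation when corr_threshold = 1.
_CORR_TOL = 1e-10

#: Columns whose mean/sd are already (0, 1) within this tolerance are left
#: untouched by center_scale, so preprocessing is exactly idempotent.
_STANDARDIZED_TOL = 1e-12


@dataclass
class PreprocessConfig:
    """Options for :func:`preprocess_data`."""

    normalize_method: str = "center_scale"  # or "none"
    remove_variance: str = "near_zero"  # "near_zero" | "non_zero_only" | "none"
    collapse_correlated: bool = True
    corr_threshold: float = 1.0
    freq_cut: float = DEFAULT_FREQ_CUT
    unique_cut: float = DEFAULT_UNIQUE_CUT

    def __post_init__(self) -> None:
        if self.normalize_method not in ("center_scale", "none"):
            raise DataError("normalize_method must be 'center_scale' or 'none'")
        if self.remove_variance not in ("near_zero", "non_zero_only", "none"):
            raise DataError(
                "remove_variance must be 'near_zero', 'non_zero_only' or 'none'"
            )
        if not (0.0 <= self.corr_threshold <= 1.0):
            raise DataError("corr_threshold must be in [0, 1]")
        if self.freq_cut < 1:
            raise DataError("freq_cut must be >= 1")
        if not (0.0 <= self.unique_cut <= 100.0):
            raise DataError("unique_cut must be in [0, 100]")


@dataclass
class PreprocessResult:
    """Transformed dataset plus complete accounting of what happened.

    Every original feature appears in exactly one of: the surviving table
    (possibly renamed by indicator encoding), ``removed_features``, or as a
    non-kept member of a correlated group.
    """

    dataset: Dataset
    removed_features: Dict[str, List[str]] = field(default_factory=dict)
    correlated_groups: Dict[str, List[str]] = field(default_factory=dict)
    normalization_params: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    encoding_map: Dict[str, List[str]] = field(default_factory=dict)

    def to_report(self) -> dict:
        return {
            "removed_features": self.removed_features,
            "correlated_groups": self.correlated_groups,
            "normalization_params": {
                k: [float(m), float(s)] for k, (m, s) in self.normalization_params.items()
            },
            "encoding_map": self.encoding_map,
        }


# ----------------------------------------------------------------------
# stage 1: constant features
# ----------------------------------------------------------------------
def remove_constant_features(dataset: Dataset) -> Tuple[Dataset, List[str]]:
    """Drop features whose non-missing values are all identical."""
    removed = []
    for name in dataset.feature_names:
        if dataset.table[name].dropna().nunique() <= 1:
            removed.append(name)
    if removed and len(removed) == len(dataset.feature_names):
        raise DataError("no features remain: all features are constant")
    table = dataset.table.drop(columns=removed)
    kinds = {k: v for k, v in dataset.feature_kinds.items() if k not in removed}
    return dataset.with_table(table, kinds), removed


# ----------------------------------------------------------------------
# stage 2: categorical encoding
# ----------------------------------------------------------------------
def _unique_name(base: str, taken: set) -> str:
    if base not in taken:
        return base
    k = 1
    while f"{base}_{k}" in taken:
        k += 1
    warnings.warn(f"derived column name {base!r} collides; using {base}_{k!r}")
    return f"{base}_{k}"


def encode_categorical(dataset: Dataset) -> Tuple[Dataset, Dict[str, List[str]]]:
    """Re-factor categorical features into binary indicator columns.

    A feature with L > 2 levels becomes L indicator columns named
    ``<feature>_<level>``; a two-level feature becomes ONE column named after
    the lexicographically second level.  Missing categorical values propagate
    to missing in every derived indicator.
    """
    name_map: Dict[str, List[str]] = {}
    pieces = []
    taken = set(dataset.table.columns)
    kinds = {}
    for name in dataset.table.columns:
        if name == dataset.outcome_name:
            pieces.append(dataset.table[[name]])
            continue
        if dataset.feature_kinds.get(name) != "categorical":
            pieces.append(dataset.table[[name]])
            name_map[name] = [name]
            kinds[name] = "continuous"
            continue
        col = dataset.table[name].astype("object")
        levels = sorted(col.dropna().astype(str).unique())
        miss = col.isna().to_numpy()
        if len(levels) == 2:
            use_levels = [levels[1]]  # single indicator for the second level
        else:
            use_levels = levels
        derived = []
        block = {}
        for lev in use_levels:
            new_name = _unique_name(f"{name}_{lev}", taken)
            taken.add(new_name)
            vals = (col.astype(str) == lev).astype(float)
            vals[miss] = np.nan
            block[new_name] = vals
            derived.append(new_name)
            kinds[new_name] = "continuous"
        pieces.append(pd.DataFrame(block, index=dataset.table.index))
        name_map[name] = derived
    table = pd.concat(pieces, axis=1)
    return dataset.with_table(table, kinds), name_map


# ----------------------------------------------------------------------
# stage 3: normalization
# ----------------------------------------------------------------------
def _is_binary_column(values: pd.Series) -> bool:
    nonmiss = pd.unique(values.dropna())
    return len(nonmiss) <= 2 and set(np.asarray(nonmiss, dtype=float)) <= {0.0, 1.0}


def normalize_continuous(
    dataset: Dataset, method: str = "center_scale"
) -> Tuple[Dataset, Dict[str, Tuple[float, float]]]:
    """Center/scale continuous features; median-impute missing values first.

    Binary 0/1 indicator columns are never normalized.  A column whose sd is
    zero after imputation is dropped with a warning (constants should already
    have been removed).  Columns already standardized to mean 0, sd 1 within
    1e-12 are left bit-identical so that preprocessing is idempotent.
    """
    if method == "none":
        return dataset, {}
    table = dataset.table.copy()
    params: Dict[str, Tuple[float, float]] = {}
    dropped = []
    for name in dataset.feature_names:
        col = pd.to_numeric(table[name], errors="coerce")
        if _is_binary_column(col):
            table[name] = col
            continue
        if col.isna().any():
            col = col.fillna(col.median())
        mean = float(col.mean())
        sd = float(col.std(ddof=1))
        if sd == 0.0:
            warnings.warn(f"feature {name!r} has zero variance after imputation; dropping")
            dropped.append(name)
            continue
        if abs(mean) < _STANDARDIZED_TOL and abs(sd - 1.0) < _STANDARDIZED_TOL:
            table[name] = col
            params[name] = (0.0, 1.0)
            continue
        table[name] = (col - mean) / sd
        params[name] = (mean, sd)
    if dropped:
        table = table.drop(columns=dropped)
    kinds = {k: "continuous" for k in table.columns if k != dataset.outcome_name}
    return dataset.with_table(table, kinds), params


def impute_missing(dataset: Dataset) -> Dataset:
    """Median-impute continuous features; fill indicator missing values with 0."""
    table = dataset.table.copy()
    warned = False
    for name in dataset.feature_names:
        col = pd.to_numeric(table[name], errors="coerce")
        if not col.isna().any():
            table[name] = col
            continue
        if _is_binary_column(col):
            if not warned:
                warnings.warn("missing indicator values imputed as 0")
                warned = True
            table[name] = col.fillna(0.0)
        else:
            table[name] = col.fillna(col.median())
    return dataset.with_table(table)


# ----------------------------------------------------------------------
# stage 4: near-zero variance
# ----------------------------------------------------------------------
def remove_near_zero_variance(
    dataset: Dataset,
    freq_cut: float = DEFAULT_FREQ_CUT,
    unique_cut: float = DEFAULT_UNIQUE_CUT,
) -> Tuple[Dataset, List[str]]:
    """Drop near-zero-variance features.

    A feature is removed iff its frequency ratio (most common value count /
    second most common value count; +inf when only one distinct value) is
    >= ``freq_cut`` AND its percentage of distinct values is <= ``unique_cut``.
    Zero-variance features are always removed.
    """
    n = dataset.n_samples
    removed = []
    for name in dataset.feature_names:
        counts = dataset.table[name].dropna().value_counts().to_numpy()
        if len(counts) == 0:
            removed.append(name)
            continue
        if len(counts) == 1:
            removed.append(name)  # zero variance: always out
            continue
        freq_ratio = counts[0] / counts[1]
        unique_pct = 100.0 * len(counts) / n
        if freq_ratio >= freq_cut and unique_pct <= unique_cut:
            removed.append(name)
    if removed and len(removed) == len(dataset.feature_names):
        raise DataError("no features remain after near-zero-variance filtering")
    table = dataset.table.drop(columns=removed)
    kinds = {k: v for k, v in dataset.feature_kinds.items() if k not in removed}
    return dataset.with_table(table, kinds), removed


# ----------------------------------------------------------------------
# stage 5: correlated-feature collapse
# ----------------------------------------------------------------------
class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def collapse_correlated(
    dataset: Dataset, corr_threshold: float = 1.0
) -> Tuple[Dataset, Dict[str, List[str]]]:
    """Keep one representative per group of (near-)perfectly correlated features.

    Builds a graph with an edge wherever |Pearson r| >= ``corr_threshold``
    (with a 1e-10 tolerance when the threshold is 1, so exact copies survive
    floating-point round-off) and keeps, per connected component, the feature
    first in the original column order.  The returned groups — including
    singletons — are the units that permutation importance permutes jointly.
    """
    names = dataset.feature_names
    p = len(names)
    groups: Dict[str, List[str]] = {}
    if p == 0:
        return dataset, groups
    X = dataset.table[names].to_numpy(dtype=float)
    thr = corr_threshold
    if thr >= 1.0:
        thr = 1.0 - _CORR_TOL
    uf = _UnionFind(p)
    if p > 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)  # zero-variance columns: no edges
        ii, jj = np.where(np.abs(np.triu(corr, k=1)) >= thr)
        for i, j in zip(ii, jj):
            uf.union(int(i), int(j))
    comp: Dict[int, List[int]] = {}
    for i in range(p):
        comp.setdefault(uf.find(i), []).append(i)
    keep = []
    for root in sorted(comp):
        members = sorted(comp[root])
        kept = names[members[0]]
        keep.append(kept)
        groups[kept] = [names[m] for m in members]
    drop = [n for n in names if n not in groups]
    table = dataset.table.drop(columns=drop)
    kinds = {k: v for k, v in dataset.feature_kinds.items() if k not in drop}
    return dataset.with_table(table, kinds), groups


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------
def preprocess_data(dataset: Dataset, config: PreprocessConfig = None) -> PreprocessResult:
    """Run the full preprocessing pipeline with complete bookkeeping.

    Stage order: constant removal -> categorical encoding -> imputation &
    normalization -> near-zero-variance removal -> correlated collapse.
    Re-applying the pipeline to its own output leaves the feature table
    unchanged.
    """
    if config is None:
        config = PreprocessConfig()
    removed: Dict[str, List[str]] = {}

    ds = dataset
    if config.remove_variance != "none":
        ds, const = remove_constant_features(ds)
        if const:
            removed["constant"] = const

    ds, name_map = encode_categorical(ds)
    ds = impute_missing(ds)
    ds, norm_params = normalize_continuous(ds, config.normalize_method)

    if config.remove_variance == "near_zero":
        ds, nzv = remove_near_zero_variance(ds, config.freq_cut, config.unique_cut)
        if nzv:
            removed["near_zero_variance"] = nzv

    if config.collapse_correlated:
        ds, groups = collapse_correlated(ds, config.corr_threshold)
    else:
        groups = {name: [name] for name in ds.feature_names}

    if not ds.feature_names:
        raise DataError("no features remain after preprocessing")
    return PreprocessResult(
        dataset=ds,
        removed_features=removed,
        correlated_groups=groups,
        normalization_params=norm_params,
        encoding_map=name_map,
    )
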