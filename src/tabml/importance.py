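"""Permutation-test feature importance on the held-out test set.

For each feature group (singletons, or sets of perfectly correlated features
identified during preprocessing) the rows of all member columns are permuted
jointly with ONE shared permutation — preserving intra-group correlation
while breaking the group's link to the outcome — the test set is re-scored,
and the metric change is recorded.  The empirical p-value uses the add-one
rule, p = (#{permuted >= original} + 1) / (nperm + 1) for larger-is-better
metrics (inequality reversed otherwise), so p is never zero and lies exactly
on the lattice {k/(nperm+1)}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .core_data import DataError
from .evaluate import GREATER_IS_BETTER, compute_metric


@dataclass
class ImportanceRecord:
    """Permutation-importance statistics for one feature group."""

    group_name: str
    members: List[str]
    perf_metric: float  # mean performance over permutations
    perf_metric_diff: float  # original performance - perf_metric
    pvalue: float
    nperm: int
    metric_name: str

    def to_row(self, **extra) -> dict:
        row = {
            "group_name": self.group_name,
            "members": ";".join(self.members),
            "perf_metric": self.perf_metric,
            "perf_metric_diff": self.perf_metric_diff,
            "pvalue": self.pvalue,
            "nperm": self.nperm,
            "metric": self.metric_name,
        }
        row.update(extra)
        return row


def permutation_importance(
    model_handle,
    test_features: pd.DataFrame,
    test_outcome: Sequence,
    groups: Optional[Dict[str, List[str]]] = None,
    metric: str = "auroc",
    nperm: int = 100,
    seed: int = 1,
    outcome_kind: str = "binary",
) -> List[ImportanceRecord]:
    """Grouped permutation importance with empirical p-values.

    ``groups`` maps a kept-feature name to all features permuted together
    with it; when omitted, every model feature is its own group.  The
    caller's ``test_features`` frame is never mutated (columns are restored
    after each group).  Records are sorted by descending performance drop,
    with the group name breaking ties.
    """
    if nperm < 1:
        raise DataError("nperm must be >= 1")
    if metric not in GREATER_IS_BETTER:
        raise DataError(f"unknown metric {metric!r}; known: {sorted(GREATER_IS_BETTER)}")
    if groups is None:
        groups = {name: [name] for name in model_handle.feature_names}
    for gname, members in groups.items():
        if not members:
            raise DataError(f"importance group {gname!r} has no members")
        missing = [m for m in members if m not in test_features.columns]
        if missing:
            raise DataError(f"importance group {gname!r} references missing columns: {missing}")

    y = np.asarray(test_outcome)
    original = compute_metric(metric, model_handle, test_features, y, outcome_kind)
    maximize = GREATER_IS_BETTER[metric]
    n = len(test_features)

    work = test_features.copy()
    records = []
    for gname in groups:
        members = groups[gname]
        saved = work[members].to_numpy(copy=True)
        permuted = np.empty(nperm, dtype=float)
        for it in range(nperm):
            perm = np.random.default_rng(derive_seed(seed, "perm", gname, it)).permutation(n)
            work.loc[:, members] = saved[perm]
            permuted[it] = compute_metric(metric, model_handle, work, y, outcome_kind)
        work.loc[:, members] = saved  # restore-after-measure contract
        if maximize:
            k = int(np.sum(permuted >= original))
        else:
            k = int(np.sum(permuted <= original))
        # mean of all-identical values is kept exact so a feature the model
        # ignores reports a performance difference of exactly zero
        mean_perm = original if np.all(permuted == original) else float(permuted.mean())
        records.append(
            ImportanceRecord(
                group_name=gname,
                members=list(members),
                perf_metric=float(mean_perm),
                perf_metric_diff=float(original - mean_perm),
                pvalue=(k + 1) / (nperm + 1),
                nperm=nperm,
                metric_name=metric,
            )
        )
    records.sort(key=lambda r: (-r.perf_metric_diff, r.group_name))
    return records


def importance_frame(records: List[ImportanceRecord], **extra) -> pd.DataFrame:
    """Flatten importance records into a tidy table."""
    return pd.DataFrame([r.to_row(**extra) for r in records])
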