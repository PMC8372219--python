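"""End-to-end pipeline runs and multi-seed orchestration.

``run_ml`` performs one full pass — split, tune, evaluate, optional
permutation importance — under a single run seed; every stage derives its
own sub-seed deterministically from it, so a run is reproducible bit-for-bit
and identical whether seeds are executed serially or in parallel.

Because a single train/test split gives a noisy picture of generalization,
``run_many`` repeats the whole pipeline over many seeds (each seed drawing a
different split) and ``summarize_performance`` aggregates the spread of
held-out metrics across splits.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from ._seeds import derive_seed
from .core_data import DataError, Dataset, RunConfig
from .evaluate import GREATER_IS_BETTER, PerformanceReport, calc_performance
from .importance import ImportanceRecord, importance_frame, permutation_importance
from .preprocess import PreprocessConfig, PreprocessResult, preprocess_data
from .split import DataSplit, grouped_split, stratified_split
from .train_tune import HyperparameterGrid, TrainResult, tune_and_train

logger = logging.getLogger("tabml")


@dataclass
class RunRecord:
    """Everything one (seed, model_type) pipeline run produced."""

    seed: int
    model_type: str
    best_params: dict
    cv_metric: float
    test_metrics: Dict[str, float]
    split_sizes: tuple
    perf_metric: str
    importance: Optional[List[ImportanceRecord]] = None
    cv_table: pd.DataFrame = field(default=None, repr=False)
    performance: PerformanceReport = field(default=None, repr=False)

    def to_row(self) -> dict:
        row = {
            "seed": self.seed,
            "model_type": self.model_type,
            "perf_metric": self.perf_metric,
            "cv_metric": self.cv_metric,
            "n_train": self.split_sizes[0],
            "n_test": self.split_sizes[1],
        }
        for k, v in sorted(self.best_params.items()):
            row[f"param_{k}"] = v
        for k, v in sorted(self.test_metrics.items()):
            row[f"test_{k}"] = v
        return row


def _prepare(dataset: Dataset, preprocess_result: Optional[PreprocessResult]):
    """Resolve the all-numeric table and importance groups for a run."""
    if preprocess_result is not None:
        return preprocess_result.dataset, preprocess_result.correlated_groups
    if dataset.is_all_numeric():
        return dataset, {name: [name] for name in dataset.feature_names}
    logger.info("dataset has categorical features; applying default preprocessing")
    result = preprocess_data(dataset, PreprocessConfig())
    return result.dataset, result.correlated_groups


def run_ml(
    dataset: Dataset,
    config: RunConfig,
    preprocess_result: Optional[PreprocessResult] = None,
    grid: Optional[HyperparameterGrid] = None,
) -> RunRecord:
    """One full pipeline run under ``config.seed``.

    The dataset must be all-numeric (pass a :class:`PreprocessResult` to use
    its table and correlated groups); a raw dataset with categorical
    features is auto-preprocessed with default options.
    """
    t0 = time.perf_counter()
    ds, groups = _prepare(dataset, preprocess_result)
    metric = config.resolved_metric(ds.outcome_kind)

    try:
        if config.group_split:
            if ds.group_labels is None:
                raise DataError("group_split requested but the dataset has no group labels")
            split = grouped_split(
                ds.group_labels, config.training_frac, derive_seed(config.seed, "split")
            )
        else:
            split = stratified_split(
                ds.outcome.to_numpy(),
                config.training_frac,
                derive_seed(config.seed, "split"),
                outcome_kind=ds.outcome_kind,
            )
    except DataError as exc:
        raise DataError(f"split stage failed: {exc}") from exc
    logger.info("split: %d train / %d test", *split.sizes)

    train = ds.subset(split.train_indices)
    test = ds.subset(split.test_indices)

    try:
        if grid is None and config.hyperparameters is not None:
            grid = HyperparameterGrid(config.model_type, config.hyperparameters)
        tr = tune_and_train(
            train,
            config.model_type,
            grid=grid,
            kfold=config.kfold,
            cv_times=config.cv_times,
            metric=metric,
            seed=derive_seed(config.seed, "tune"),
        )
    except DataError as exc:
        raise DataError(f"training stage failed: {exc}") from exc
    logger.info("tuning done in %.2fs: best %s", time.perf_counter() - t0, tr.best_params)

    try:
        report = calc_performance(tr.model_handle, test, ds.outcome_kind)
    except DataError as exc:
        raise DataError(f"evaluation stage failed: {exc}") from exc

    imp = None
    if config.find_importance:
        # collapsed group members were dropped from the table; permute the
        # surviving columns but report the full group membership
        present = set(tr.model_handle.feature_names)
        permute_groups = {
            k: [m for m in v if m in present]
            for k, v in groups.items()
            if k in present
        }
        try:
            imp = permutation_importance(
                tr.model_handle,
                test.features,
                test.outcome.to_numpy(),
                groups=permute_groups,
                metric=metric,
                nperm=config.nperm,
                seed=derive_seed(config.seed, "importance"),
                outcome_kind=ds.outcome_kind,
            )
        except DataError as exc:
            raise DataError(f"importance stage failed: {exc}") from exc
        for rec in imp:
            rec.members = list(groups.get(rec.group_name, rec.members))

    logger.info("run_ml(seed=%d) finished in %.2fs", config.seed, time.perf_counter() - t0)
    return RunRecord(
        seed=config.seed,
        model_type=config.model_type,
        best_params=tr.best_params,
        cv_metric=tr.best_mean,
        test_metrics=dict(report.metrics),
        split_sizes=split.sizes,
        perf_metric=metric,
        importance=imp,
        cv_table=tr.cv_table,
        performance=report,
    )


def run_many(
    dataset: Dataset,
    config: RunConfig,
    seeds: Sequence[int],
    preprocess_result: Optional[PreprocessResult] = None,
    n_jobs: int = 1,
) -> List[RunRecord]:
    """Run the pipeline once per seed; each seed draws its own train/test split.

    Records carry no cross-seed state, so serial and parallel execution are
    result-identical.
    """
    seeds = list(seeds)
    if not seeds:
        raise DataError("seeds must be non-empty")
    if len(set(seeds)) != len(seeds):
        raise DataError("seeds must be unique")

    import dataclasses as _dc

    def one(seed):
        return run_ml(dataset, _dc.replace(config, seed=int(seed)), preprocess_result)

    if n_jobs == 1:
        return [one(s) for s in seeds]
    return Parallel(n_jobs=n_jobs)(delayed(one)(s) for s in seeds)


def records_frame(records: List[RunRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


def importance_table(records: List[RunRecord]) -> pd.DataFrame:
    frames = [
        importance_frame(r.importance, seed=r.seed, model_type=r.model_type)
        for r in records
        if r.importance
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def summarize_performance(records: List[RunRecord]) -> pd.DataFrame:
    """Long-format five-number + mean/sd summary per model type and metric.

    The cross-validation tuning metric is included as ``cv_<metric>``.  With
    a single record the sd is reported as 0.
    """
    if not records:
        raise DataError("need at least one run record to summarize")
    rows = []
    for r in records:
        rows.append({"model_type": r.model_type, "metric": f"cv_{r.perf_metric}", "value": r.cv_metric})
        for k, v in r.test_metrics.items():
            rows.append({"model_type": r.model_type, "metric": k, "value": v})
    long = pd.DataFrame(rows)
    out = (
        long.groupby(["model_type", "metric"], sort=True)["value"]
        .agg(
            mean="mean",
            sd=lambda v: float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            median="median",
            min="min",
            max="max",
            n="count",
        )
        .reset_index()
    )
    return out


def hp_performance_table(records: List[RunRecord], param_name: str) -> pd.DataFrame:
    """Cross-validation performance as a function of one hyperparameter.

    Aggregates every record's CV table over the values of ``param_name``.
    The ``boundary_warning`` column is True when the best mean sits on the
    edge of the searched range — the signal that the grid should be widened.
    """
    if not records:
        raise DataError("need at least one run record")
    model_types = {r.model_type for r in records}
    if len(model_types) > 1:
        raise DataError(f"records mix model types: {sorted(model_types)}")
    tables = [r.cv_table for r in records if r.cv_table is not None]
    if not tables:
        raise DataError("records carry no CV tables")
    param_cols = [c for c in tables[0].columns if c not in ("mean_perf", "sd_perf", "n_resamples")]
    if param_name not in param_cols:
        raise DataError(f"unknown parameter {param_name!r}; grid parameters: {param_cols}")
    allcv = pd.concat(tables, ignore_index=True)
    agg = (
        allcv.groupby(param_name, sort=True)["mean_perf"]
        .agg(mean="mean", sd=lambda v: float(v.std(ddof=1)) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    metric = records[0].perf_metric
    maximize = GREATER_IS_BETTER.get(metric, True)
    best_pos = int(agg["mean"].idxmax() if maximize else agg["mean"].idxmin())
    agg["boundary_warning"] = best_pos in (0, len(agg) - 1)
    return agg
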