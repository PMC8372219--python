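"""Model-object front end to the pipeline.

:class:`PipelineModel` bundles a dataset with a run configuration the way a
statsmodels model bundles data with a design; ``fit()`` executes the whole
pipeline (preprocess, split, repeated-CV tuning, held-out evaluation,
optional permutation importance) for one or many seeds and returns a
:class:`PipelineResults` carrying the estimates, their split-to-split
spread, diagnostics, and plotting helpers.

Example
-------
>>> from tabml import PipelineModel
>>> model = PipelineModel.from_dataframe(df, outcome="dx",
...                                      model_type="glmnet_logistic")
>>> res = model.fit(seeds=range(1, 11), find_importance=True)
>>> print(res.summary())
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import pandas as pd

from .core_data import Dataset, RunConfig, read_dataset
from .preprocess import PreprocessConfig, PreprocessResult, preprocess_data
from .workflow import (
    RunRecord,
    hp_performance_table,
    importance_table,
    records_frame,
    run_many,
    run_ml,
    summarize_performance,
)


class PipelineModel:
    """A supervised-ML pipeline bound to one dataset.

    Parameters
    ----------
    dataset : Dataset
        The feature table with its outcome column.
    config : RunConfig, optional
        Run configuration; keyword arguments override individual fields.
    preprocess_config : PreprocessConfig, optional
        Options for the preprocessing stage (fit on the full dataset before
        splitting; see the methods documentation for the leakage caveat).
    """

    def __init__(
        self,
        dataset: Dataset,
        config: Optional[RunConfig] = None,
        preprocess_config: Optional[PreprocessConfig] = None,
        **config_kwargs,
    ) -> None:
        self.dataset = dataset
        base = config if config is not None else RunConfig()
        if config_kwargs:
            base = dataclasses.replace(base, **config_kwargs)
        self.config = base
        self.preprocess_config = preprocess_config or PreprocessConfig()
        self._preprocess_result: Optional[PreprocessResult] = None

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, group_labels=None,
                       outcome_kind=None, **kwargs) -> "PipelineModel":
        ds = Dataset.from_dataframe(
            df, outcome_name=outcome, group_labels=group_labels, outcome_kind=outcome_kind
        )
        return cls(ds, **kwargs)

    @classmethod
    def from_csv(cls, path, outcome: str, group_column=None, delimiter=None,
                 **kwargs) -> "PipelineModel":
        ds = read_dataset(path, outcome_name=outcome, delimiter=delimiter,
                          group_column=group_column)
        return cls(ds, **kwargs)

    # ------------------------------------------------------------------
    @property
    def preprocess_result(self) -> PreprocessResult:
        """Preprocessing of the full table (computed once, then cached)."""
        if self._preprocess_result is None:
            self._preprocess_result = preprocess_data(self.dataset, self.preprocess_config)
        return self._preprocess_result

    def fit(self, seeds: Optional[Sequence[int]] = None, n_jobs: int = 1,
            **config_kwargs) -> "PipelineResults":
        """Run the pipeline for one seed (``config.seed``) or many.

        Each seed draws its own train/test split; the spread of held-out
        metrics across seeds is the pipeline's uncertainty estimate.
        """
        config = self.config
        if config_kwargs:
            config = dataclasses.replace(config, **config_kwargs)
        pre = self.preprocess_result
        if seeds is None:
            records = [run_ml(self.dataset, config, preprocess_result=pre)]
        else:
            records = run_many(self.dataset, config, list(seeds),
                               preprocess_result=pre, n_jobs=n_jobs)
        return PipelineResults(self, config, records)


class PipelineResults:
    """Results of one or many pipeline runs.

    Attributes
    ----------
    records : list of RunRecord
        One record per seed.
    """

    def __init__(self, model: PipelineModel, config: RunConfig,
                 records: Sequence[RunRecord]) -> None:
        self.model = model
        self.config = config
        self.records = list(records)

    # -- tabular views --------------------------------------------------
    @property
    def runs(self) -> pd.DataFrame:
        """One row per seed: best hyperparameters, CV and test metrics."""
        return records_frame(self.records)

    @property
    def importances(self) -> pd.DataFrame:
        """Permutation-importance records across all seeds (may be empty)."""
        return importance_table(self.records)

    def performance_summary(self) -> pd.DataFrame:
        return summarize_performance(self.records)

    def hp_performance(self, param_name: str) -> pd.DataFrame:
        return hp_performance_table(self.records, param_name)

    # -- presentation ---------------------------------------------------
    def summary(self) -> str:
        """Human-readable account of the fitted pipeline."""
        lines = []
        r0 = self.records[0]
        lines.append("Supervised ML pipeline results")
        lines.append("=" * 34)
        lines.append(f"model type:        {r0.model_type}")
        lines.append(f"tuning metric:     {r0.perf_metric}")
        lines.append(f"seeds:             {len(self.records)}")
        lines.append(f"train/test sizes:  {r0.split_sizes[0]}/{r0.split_sizes[1]}")
        pre = self.model._preprocess_result
        if pre is not None:
            removed = sum(len(v) for v in pre.removed_features.values())
            collapsed = sum(len(v) - 1 for v in pre.correlated_groups.values())
            lines.append(
                f"features:          {len(pre.dataset.feature_names)} "
                f"(removed {removed}, collapsed {collapsed})"
            )
        lines.append("")
        summ = self.performance_summary()
        lines.append(summ.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        imp = self.importances
        if len(imp):
            lines.append("")
            lines.append("Top feature groups by mean permutation importance:")
            top = (
                imp.groupby("group_name")[["perf_metric_diff", "pvalue"]]
                .mean()
                .sort_values("perf_metric_diff", ascending=False)
                .head(10)
                .reset_index()
            )
            lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PipelineResults: {len(self.records)} run(s), {self.config.model_type}>"

    # -- plotting -------------------------------------------------------
    def plot_performance(self, metric: Optional[str] = None, ax=None):
        from .plot import plot_model_performance

        return plot_model_performance(self.records, metric=metric, ax=ax)

    def plot_hp_performance(self, param_name: str, ax=None):
        from .plot import plot_hp_performance

        return plot_hp_performance(self.hp_performance(param_name), param_name,
                                   metric=self.records[0].perf_metric, ax=ax)
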