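"""Thin plotting layer over the pipeline's plot-ready tables.

The canonical outputs are the CSV tables (runs, summary, hp_performance);
these helpers render them with matplotlib for quick inspection.  Headless
environments need no display: figures are returned, never shown.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import pandas as pd

from .workflow import records_frame


def plot_model_performance(records, metric: Optional[str] = None, ax=None):
    """Box plot of a held-out metric across seeds, one box per model type."""
    df = records_frame(records)
    if metric is None:
        metric = records[0].perf_metric
    col = f"test_{metric}"
    if col not in df.columns:
        raise ValueError(f"metric {metric!r} not present in run records")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    groups = df.groupby("model_type")[col]
    labels, data = zip(*[(name, vals.to_numpy()) for name, vals in groups])
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel(f"test {metric}")
    ax.set_xlabel("model type")
    ax.set_title(f"Held-out {metric} across {df['seed'].nunique()} train/test splits")
    return ax.figure, ax


def plot_hp_performance(hp_table: pd.DataFrame, param_name: str,
                        metric: str = "metric", ax=None):
    """Mean +/- sd of the CV tuning metric as a function of one hyperparameter."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = hp_table[param_name].to_numpy(dtype=float)
    ax.errorbar(x, hp_table["mean"], yerr=hp_table["sd"], marker="o", capsize=3)
    if (x > 0).all() and x.max() / max(x.min(), 1e-300) > 50:
        ax.set_xscale("log")
    ax.set_xlabel(param_name)
    ax.set_ylabel(f"mean CV {metric}")
    if bool(hp_table["boundary_warning"].iloc[0]):
        ax.set_title(f"{param_name}: best value on grid edge — widen the range")
    else:
        ax.set_title(param_name)
    return ax.figure, ax
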