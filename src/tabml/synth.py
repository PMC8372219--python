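"""Synthetic tabular datasets with planted structure.

The generator emulates the statistical structure the pipeline assumes in
real feature tables (e.g. microbiome OTU relative-abundance tables joined to
clinical metadata): continuous features with planted linear/logistic
effects, categorical features, perfectly correlated feature pairs (exact
affine copies, so |r| = 1 holds deterministically), near-zero-variance and
constant features, MCAR missingness, and optional batch-style group labels.
Every planted coefficient and structural role is returned as ground truth
for recovery tests.

Binary outcomes are drawn from a logistic model with intercept 0; since the
features are symmetric standard normals this yields ~50% prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core_data import DataError, Dataset


@dataclass
class SynthSpec:
    """Recipe for one synthetic dataset.

    ``effect_sizes`` is a scalar applied to every informative feature or a
    list of per-feature coefficients (log-odds for binary outcomes, linear
    coefficients for continuous ones).
    """

    n_samples: int = 200
    n_continuous: int = 20
    n_categorical: int = 0
    n_informative: int = 5
    effect_sizes: Union[float, Sequence[float]] = 1.0
    n_correlated_pairs: int = 0
    n_nzv: int = 0
    n_constant: int = 0
    missing_rate: float = 0.0
    outcome_kind: str = "binary"
    n_classes: int = 3  # multiclass outcomes only
    n_groups: Optional[int] = None
    categorical_levels: int = 3  # drawn uniformly from 3..5 when 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise DataError("n_samples must be >= 4")
        if min(self.n_continuous, self.n_categorical, self.n_informative,
               self.n_correlated_pairs, self.n_nzv, self.n_constant) < 0:
            raise DataError("all counts must be >= 0")
        if self.n_informative > self.n_continuous + self.n_categorical:
            raise DataError(
                "n_informative exceeds the number of continuous + categorical features"
            )
        if self.n_correlated_pairs > self.n_continuous:
            raise DataError("n_correlated_pairs exceeds n_continuous")
        if not (0.0 <= self.missing_rate < 1.0):
            raise DataError("missing_rate must be in [0, 1)")
        if self.outcome_kind not in ("binary", "multiclass", "continuous"):
            raise DataError("outcome_kind must be binary, multiclass or continuous")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate(spec: SynthSpec) -> Tuple[Dataset, dict]:
    """Draw one dataset under ``spec``; returns (dataset, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    # continuous block: informative features first
    cont_names = [f"feat_{i + 1:03d}" for i in range(spec.n_continuous)]
    X = rng.standard_normal((n, spec.n_continuous))

    n_inf_cont = min(spec.n_informative, spec.n_continuous)
    if np.isscalar(spec.effect_sizes):
        all_effects = np.full(spec.n_informative, float(spec.effect_sizes))
    else:
        all_effects = np.asarray(list(spec.effect_sizes), dtype=float)
        if len(all_effects) != spec.n_informative:
            raise DataError("effect_sizes list must have length n_informative")
    coef = np.zeros(spec.n_continuous)
    coef[:n_inf_cont] = all_effects[:n_inf_cont]
    linpred = X @ coef

    # categorical features; remaining informative slots get level effects
    n_inf_cat = spec.n_informative - n_inf_cont
    cat_cols = {}
    cat_effects = {}
    for j in range(spec.n_categorical):
        name = f"cat_{j + 1}"
        L = spec.categorical_levels or int(rng.integers(3, 6))
        levels = [f"l{k}" for k in range(L)]
        draws = rng.integers(0, L, size=n)
        cat_cols[name] = np.array(levels, dtype=object)[draws]
        if j < n_inf_cat:
            eff = float(all_effects[n_inf_cont + j])
            # level 0 is the reference; the last level carries the effect
            linpred = linpred + np.where(draws == L - 1, eff, 0.0)
            cat_effects[name] = {levels[-1]: eff}

    # outcome
    if spec.outcome_kind == "binary":
        p = _sigmoid(linpred)
        y = np.where(rng.random(n) < p, "pos", "neg").astype(object)
    elif spec.outcome_kind == "multiclass":
        K = spec.n_classes
        logits = np.zeros((n, K))
        for k in range(1, K):
            sign = 1.0 if k % 2 == 1 else -1.0
            logits[:, k] = sign * linpred
        ex = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = ex / ex.sum(axis=1, keepdims=True)
        cum = probs.cumsum(axis=1)
        draws = (rng.random(n)[:, None] > cum).sum(axis=1)
        y = np.array([f"c{k}" for k in draws], dtype=object)
    else:
        y = linpred + rng.standard_normal(n)

    table = pd.DataFrame(X, columns=cont_names)

    # exact affine copies of the first n_correlated_pairs continuous features
    corr_pairs = {}
    for j in range(spec.n_correlated_pairs):
        src = cont_names[j]
        dup = f"{src}_dup"
        a = 2.0 if j % 2 == 0 else -1.5
        table[dup] = a * table[src] + 3.0
        corr_pairs[src] = dup

    # near-zero-variance: dominant value in >=98% of rows, 2 distinct values
    nzv_names = []
    for j in range(spec.n_nzv):
        name = f"nzv_{j + 1}"
        col = np.zeros(n)
        n_minor = max(1, int(np.floor(0.02 * n)))
        minor_idx = rng.choice(n, size=n_minor, replace=False)
        col[minor_idx] = 1.0
        table[name] = col
        nzv_names.append(name)

    const_names = []
    for j in range(spec.n_constant):
        name = f"const_{j + 1}"
        table[name] = float(j + 7)
        const_names.append(name)

    for name, vals in cat_cols.items():
        table[name] = vals

    # MCAR missingness over feature cells, keeping >= 2 non-missing per column
    if spec.missing_rate > 0:
        mask = rng.random(table.shape) < spec.missing_rate
        for c in range(table.shape[1]):
            col_mask = mask[:, c]
            if col_mask.sum() > n - 2:
                keep = rng.choice(np.flatnonzero(col_mask), size=col_mask.sum() - (n - 2), replace=False)
                col_mask[keep] = False
                mask[:, c] = col_mask
        table = table.mask(mask)

    table["outcome"] = y

    groups = None
    if spec.n_groups:
        if spec.n_groups < 2:
            raise DataError("n_groups must be >= 2 when set")
        groups = np.array([f"g{k}" for k in rng.integers(0, spec.n_groups, size=n)], dtype=object)

    dataset = Dataset.from_dataframe(
        table, outcome_name="outcome", group_labels=groups, outcome_kind=spec.outcome_kind
    )
    truth = {
        "coefficients": {name: float(c) for name, c in zip(cont_names, coef)},
        "informative": cont_names[:n_inf_cont] + list(cat_effects),
        "categorical_effects": cat_effects,
        "correlated_pairs": corr_pairs,
        "nzv": nzv_names,
        "constant": const_names,
        "intercept": 0.0,
        "prevalence": float(np.mean(np.asarray(y) == "pos")) if spec.outcome_kind == "binary" else None,
    }
    return dataset, truth
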