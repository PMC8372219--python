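"""Independent brute-force oracles used to check the pipeline.

Everything here is written from the definitions with plain loops, not by
calling the package's code paths, so the tests compare two independent
routes to the same answer.
"""

from collections import Counter
from math import sqrt

import numpy as np
import pandas as pd


def oracle_auroc(scores, labels_pos) -> float:
    """Pairwise concordance: P(score_pos > score_neg), ties counted 1/2."""
    scores = list(scores)
    labels_pos = list(labels_pos)
    pos = [s for s, y in zip(scores, labels_pos) if y]
    neg = [s for s, y in zip(scores, labels_pos) if not y]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_is_constant(values) -> bool:
    nonmiss = [v for v in values if not pd.isna(v)]
    return len(set(map(str, nonmiss))) <= 1


def oracle_nzv_removed(values, n, freq_cut, unique_cut) -> bool:
    """Frequency-ratio + unique-percentage rule, by explicit counting."""
    nonmiss = [v for v in values if not pd.isna(v)]
    counts = sorted(Counter(nonmiss).values(), reverse=True)
    if len(counts) <= 1:
        return True  # zero variance: always removed
    freq_ratio = counts[0] / counts[1]
    unique_pct = 100.0 * len(counts) / n
    return freq_ratio >= freq_cut and unique_pct <= unique_cut


def oracle_zscore(values):
    """Median-impute then (x - mean) / sd with sample sd (n-1 denominator)."""
    vals = [float(v) for v in values if not pd.isna(v)]
    vals_sorted = sorted(vals)
    m = len(vals_sorted)
    median = (
        vals_sorted[m // 2]
        if m % 2 == 1
        else 0.5 * (vals_sorted[m // 2 - 1] + vals_sorted[m // 2])
    )
    filled = [median if pd.isna(v) else float(v) for v in values]
    mean = sum(filled) / len(filled)
    var = sum((v - mean) ** 2 for v in filled) / (len(filled) - 1)
    sd = sqrt(var)
    return [(v - mean) / sd for v in filled], mean, sd


def oracle_pearson(x, y) -> float:
    """Direct product-moment formula (independent of np.corrcoef)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.sum() / len(x)
    dy = y - y.sum() / len(y)
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0 or syy == 0:
        return 0.0
    return float(dx @ dy) / sqrt(sxx * syy)


def oracle_corr_groups(df: pd.DataFrame, threshold: float) -> dict:
    """Connected components of the |r| >= threshold graph via BFS;
    keeps the member first in column order."""
    names = list(df.columns)
    thr = threshold if threshold < 1.0 else 1.0 - 1e-10
    adj = {n: set() for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if abs(oracle_pearson(df[a], df[b])) >= thr:
                adj[a].add(b)
                adj[b].add(a)
    seen = set()
    groups = {}
    for name in names:
        if name in seen:
            continue
        comp, queue = [], [name]
        seen.add(name)
        while queue:
            cur = queue.pop()
            comp.append(cur)
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comp = sorted(comp, key=names.index)
        groups[comp[0]] = comp
    return groups


def random_mixed_table(rng: np.random.Generator, n_max=200, p_max=50) -> pd.DataFrame:
    """A random mixed-type feature table exercising every preprocessing rule.

    Independent of the package's synthetic generator: built column by column
    with its own rules (continuous, categorical, constant, near-constant,
    exact duplicates, missing cells).
    """
    n = int(rng.integers(10, n_max + 1))
    p = int(rng.integers(2, p_max + 1))
    cols = {}
    prev_cont = []
    for j in range(p):
        kind = rng.choice(
            ["continuous", "categorical", "constant", "near_constant", "duplicate"],
            p=[0.45, 0.2, 0.1, 0.15, 0.1],
        )
        name = f"c{j:02d}"
        if kind == "duplicate" and prev_cont:
            src = cols[prev_cont[int(rng.integers(len(prev_cont)))]]
            a = float(rng.choice([-2.0, 0.5, 3.0]))
            cols[name] = a * np.asarray(src, dtype=float) + float(rng.normal())
        elif kind == "continuous":
            vals = rng.normal(size=n)
            cols[name] = vals
            prev_cont.append(name)
        elif kind == "categorical":
            L = int(rng.integers(2, 5))
            cols[name] = rng.choice([f"v{k}" for k in range(L)], size=n)
        elif kind == "constant":
            cols[name] = np.full(n, float(rng.integers(0, 5)))
        else:  # near constant
            vals = np.zeros(n)
            n_minor = max(1, int(rng.integers(1, max(2, n // 30))))
            vals[rng.choice(n, size=n_minor, replace=False)] = 1.0
            cols[name] = vals
    df = pd.DataFrame(cols)
    # sprinkle missing values into float columns, keeping >= 3 non-missing
    for name in df.columns:
        if df[name].dtype.kind == "f" and rng.random() < 0.3:
            k = int(rng.integers(1, max(2, len(df) // 10)))
            idx = rng.choice(len(df), size=min(k, len(df) - 3), replace=False)
            df.loc[idx, name] = np.nan
    # guarantee at least one clean continuous feature so preprocessing
    # always has something to keep
    df["keep"] = rng.normal(size=n) + np.linspace(0, 1, n)
    df["outcome"] = rng.choice(["a", "b"], size=n)
    while df["outcome"].nunique() < 2:
        df["outcome"] = rng.choice(["a", "b"], size=n)
    return df
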