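"""Dataset container and delimited-table I/O.

A :class:`Dataset` is a samples x columns table with one designated outcome
column, any number of feature columns (continuous or categorical), and
optional per-sample group labels (batch, site, ...) used by grouped
train/test splitting.

Column kinds are inferred: a column is *continuous* when every non-missing
entry parses as a number, otherwise *categorical*.  Missing-value tokens
("", "NA", "NaN", "null", case-insensitive) are mapped to missing on read.
"""

from __future__ import annotations

import csv
import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Tokens (lower-cased) treated as missing when reading delimited files.
MISSING_TOKENS = frozenset({"", "na", "nan", "null"})

#: Supported model identifiers, in canonical order.
SUPPORTED_MODELS = (
    "glmnet_logistic",
    "glmnet_linear",
    "svm_rbf",
    "decision_tree",
    "random_forest",
    "xgboost",
)

OUTCOME_KINDS = ("binary", "multiclass", "continuous")

#: Maximum number of distinct values for an all-numeric outcome to still be
#: treated as categorical rather than continuous.
_MAX_CATEGORICAL_LEVELS = 10


class DataError(ValueError):
    """Raised for malformed input tables or invalid dataset configurations."""


def _is_numeric_series(s: pd.Series) -> bool:
    """True when every non-missing entry of ``s`` parses as a number."""
    nonmiss = s.dropna()
    if nonmiss.empty:
        return False
    converted = pd.to_numeric(nonmiss, errors="coerce")
    return not converted.isna().any()


@dataclass
class Dataset:
    """A feature table with a designated outcome column.

    Parameters
    ----------
    table : pandas.DataFrame
        Samples x columns table containing the outcome column and all
        feature columns.  The row index is positional (0..n-1).
    outcome_name : str
        Name of the outcome column in ``table``.
    outcome_kind : {"binary", "multiclass", "continuous"}
        Kind of the outcome; inferred by :meth:`from_dataframe` when not
        given explicitly.
    group_labels : pandas.Series, optional
        One categorical label per sample, for grouped splitting.
    feature_kinds : dict
        Mapping feature name -> {"continuous", "categorical"}.
    sample_ids : pandas.Series, optional
        Sample identifiers carried as metadata (never used as a feature).
    """

    table: pd.DataFrame
    outcome_name: str
    outcome_kind: str
    group_labels: Optional[pd.Series] = None
    feature_kinds: dict = field(default_factory=dict)
    sample_ids: Optional[pd.Series] = None
    #: Row subsets (train/test sides) may legitimately lose outcome levels;
    #: the level-count invariant is only enforced on full datasets.
    is_subset: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome_name: str,
        group_labels: Optional[Sequence] = None,
        outcome_kind: Optional[str] = None,
        sample_ids: Optional[Sequence] = None,
    ) -> "Dataset":
        """Build a Dataset from an in-memory DataFrame, inferring column kinds."""
        if outcome_name not in df.columns:
            raise DataError(f"outcome column {outcome_name!r} not found in table")
        if df.columns.duplicated().any():
            dups = sorted(set(df.columns[df.columns.duplicated()]))
            raise DataError(f"duplicate column names: {dups}")
        df = df.reset_index(drop=True)

        feature_kinds = {}
        for col in df.columns:
            if col == outcome_name:
                continue
            s = df[col]
            if pd.api.types.is_numeric_dtype(s):
                feature_kinds[col] = "continuous"
            elif _is_numeric_series(s.astype("string")):
                df[col] = pd.to_numeric(s, errors="coerce")
                feature_kinds[col] = "continuous"
            else:
                n_num = pd.to_numeric(s.dropna().astype(str), errors="coerce").notna().sum()
                if 0 < n_num < s.dropna().shape[0]:
                    warnings.warn(
                        f"column {col!r} mixes numeric and non-numeric values; "
                        "treating it as categorical"
                    )
                feature_kinds[col] = "categorical"

        if outcome_kind is None:
            outcome_kind = _infer_outcome_kind(df[outcome_name])
        if outcome_kind == "continuous":
            df[outcome_name] = pd.to_numeric(df[outcome_name], errors="coerce")

        groups = None
        if group_labels is not None:
            groups = pd.Series(list(group_labels), name="group").reset_index(drop=True)
        ids = None
        if sample_ids is not None:
            ids = pd.Series(list(sample_ids), name="sample_id").reset_index(drop=True)
        return cls(
            table=df,
            outcome_name=outcome_name,
            outcome_kind=outcome_kind,
            group_labels=groups,
            feature_kinds=feature_kinds,
            sample_ids=ids,
        )

    # ------------------------------------------------------------------
    # invariants
    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.outcome_name not in self.table.columns:
            raise DataError(f"outcome column {self.outcome_name!r} not found in table")
        if self.table.columns.duplicated().any():
            dups = sorted(set(self.table.columns[self.table.columns.duplicated()]))
            raise DataError(f"duplicate column names: {dups}")
        if len(self.table) < 2:
            raise DataError("dataset must have at least 2 rows")
        if self.outcome_kind not in OUTCOME_KINDS:
            raise DataError(
                f"outcome_kind must be one of {OUTCOME_KINDS}, got {self.outcome_kind!r}"
            )
        outcome = self.table[self.outcome_name]
        if outcome.isna().all():
            raise DataError(f"outcome column {self.outcome_name!r} is entirely missing")
        n_levels = outcome.dropna().astype(str).nunique()
        if self.outcome_kind == "binary" and not self.is_subset and n_levels != 2:
            raise DataError(
                f"binary outcome requires exactly 2 distinct values, found {n_levels}"
            )
        if self.group_labels is not None and len(self.group_labels) != len(self.table):
            raise DataError(
                "group_labels must have exactly one label per sample "
                f"({len(self.group_labels)} labels for {len(self.table)} samples)"
            )

    # ------------------------------------------------------------------
    # views
    # ------------------------------------------------------------------
    @property
    def feature_names(self) -> list:
        return [c for c in self.table.columns if c != self.outcome_name]

    @property
    def features(self) -> pd.DataFrame:
        return self.table[self.feature_names]

    @property
    def outcome(self) -> pd.Series:
        return self.table[self.outcome_name]

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def is_all_numeric(self) -> bool:
        return all(k == "continuous" for k in self.feature_kinds.values())

    def subset(self, indices: Sequence[int]) -> "Dataset":
        """Row-subset by positional indices (train or test side of a split)."""
        idx = np.asarray(indices, dtype=int)
        return dataclasses.replace(
            self,
            is_subset=True,
            table=self.table.iloc[idx].reset_index(drop=True),
            group_labels=(
                self.group_labels.iloc[idx].reset_index(drop=True)
                if self.group_labels is not None
                else None
            ),
            sample_ids=(
                self.sample_ids.iloc[idx].reset_index(drop=True)
                if self.sample_ids is not None
                else None
            ),
        )

    def with_table(self, table: pd.DataFrame, feature_kinds: Optional[dict] = None) -> "Dataset":
        """Return a copy with a replaced table (same outcome/groups)."""
        if feature_kinds is None:
            feature_kinds = {
                c: self.feature_kinds.get(c, "continuous")
                for c in table.columns
                if c != self.outcome_name
            }
        return dataclasses.replace(self, table=table, feature_kinds=feature_kinds)


def _infer_outcome_kind(outcome: pd.Series) -> str:
    """Infer the outcome kind from its values.

    All-numeric with more than 10 distinct values -> continuous; otherwise
    categorical: binary with exactly two levels, multiclass above that.
    """
    nonmiss = outcome.dropna()
    if nonmiss.empty:
        raise DataError("outcome column is entirely missing")
    n_distinct = nonmiss.astype(str).nunique()
    numeric = _is_numeric_series(nonmiss.astype("string"))
    if numeric and n_distinct > _MAX_CATEGORICAL_LEVELS:
        return "continuous"
    if n_distinct < 2:
        raise DataError("outcome has a single distinct value; nothing to predict")
    return "binary" if n_distinct == 2 else "multiclass"


def _detect_delimiter(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(
    path,
    outcome_name: str,
    delimiter: Optional[str] = None,
    group_column: Optional[str] = None,
    id_column: Optional[str] = None,
    outcome_kind: Optional[str] = None,
) -> Dataset:
    """Read a delimited feature table with an outcome column.

    The delimiter is auto-detected from the extension (.csv -> comma,
    .tsv -> tab) unless given explicitly.  ``group_column`` / ``id_column``
    are popped out of the feature set into dataset metadata.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    sep = _detect_delimiter(path, delimiter)

    # check the raw header before pandas de-duplicates repeated names
    with open(path) as fh:
        header = next(csv.reader(fh, delimiter=sep))
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise DataError(f"duplicate column names in {path.name}: {dups}")

    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, skipinitialspace=False)
    if outcome_name not in raw.columns:
        raise DataError(
            f"outcome column {outcome_name!r} not found in {path.name}; "
            f"available columns: {list(raw.columns)}"
        )
    raw = raw.apply(
        lambda s: s.map(lambda v: np.nan if str(v).strip().lower() in MISSING_TOKENS else v)
    )

    group_labels = None
    if group_column is not None:
        if group_column not in raw.columns:
            raise DataError(f"group column {group_column!r} not found in {path.name}")
        group_labels = raw.pop(group_column)
    sample_ids = None
    if id_column is not None:
        if id_column not in raw.columns:
            raise DataError(f"id column {id_column!r} not found in {path.name}")
        sample_ids = raw.pop(id_column)

    return Dataset.from_dataframe(
        raw,
        outcome_name=outcome_name,
        group_labels=group_labels,
        outcome_kind=outcome_kind,
        sample_ids=sample_ids,
    )


def write_table(rows, path, delimiter: str = ",") -> None:
    """Write tabular records as an RFC-4180-style CSV with a header row.

    ``rows`` may be a DataFrame or a list of dicts sharing a schema.  Values
    containing the delimiter or quotes are quoted; the output round-trips
    through :func:`read_dataset` / ``pandas.read_csv``.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    path = Path(path)
    try:
        df.to_csv(path, index=False, sep=delimiter)
    except OSError as exc:
        raise DataError(f"cannot write table to {path}: {exc}") from exc


@dataclass
class RunConfig:
    """Configuration for a single end-to-end pipeline run.

    ``perf_metric=None`` resolves by outcome kind: AUROC for binary,
    mean one-vs-rest AUROC for multiclass, RMSE for continuous outcomes.
    ``cv_times`` defaults to 100 repeated cross-validations (the reference
    default; the command line uses 10 for desk-scale runs).
    """

    model_type: str = "glmnet_logistic"
    training_frac: float = 0.8
    kfold: int = 5
    cv_times: int = 100
    perf_metric: Optional[str] = None
    seed: int = 1
    find_importance: bool = False
    nperm: int = 100
    group_split: bool = False
    hyperparameters: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.model_type not in SUPPORTED_MODELS:
            raise DataError(
                f"unknown model_type {self.model_type!r}; supported: {list(SUPPORTED_MODELS)}"
            )
        if not (0.0 < self.training_frac < 1.0):
            raise DataError("training_frac must be in (0, 1)")
        if self.kfold < 2:
            raise DataError("kfold must be >= 2")
        if self.cv_times < 1:
            raise DataError("cv_times must be >= 1")
        if self.nperm < 1:
            raise DataError("nperm must be >= 1")

    def resolved_metric(self, outcome_kind: str) -> str:
        if self.perf_metric is not None:
            return self.perf_metric
        return "rmse" if outcome_kind == "continuous" else "auroc"
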