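"""Patient-level dataset container and delimited-text I/O.

A :class:`Dataset` is one row per individual: a binary outcome (1 = event,
e.g. death within 28 days), a numeric predictor matrix with named columns,
and optional cluster and subgroup label columns. The contract is
complete-case: predictors must contain no missing values. All validation
strategies in this package consume this one container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateOutcomeError


@dataclass
class Dataset:
    outcome: np.ndarray
    predictors: pd.DataFrame
    cluster_id: pd.Series | None = None
    subgroup_labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome)
        uniq = np.unique(self.outcome)
        if not np.isin(uniq, [0, 1]).all():
            raise DataError(f"outcome must contain only 0/1, found values {uniq[:5]}")
        self.outcome = self.outcome.astype(np.int8)
        if len(self.outcome) != len(self.predictors):
            raise DataError(
                f"outcome length {len(self.outcome)} != predictor rows {len(self.predictors)}"
            )
        if self.predictors.isna().any().any():
            bad = self.predictors.columns[self.predictors.isna().any()].tolist()
            raise DataError(f"predictors contain missing values in columns {bad} "
                            "(complete-case input required)")
        if self.cluster_id is not None:
            self.cluster_id = pd.Series(np.asarray(self.cluster_id),
                                        index=self.predictors.index)
            if self.cluster_id.isna().any():
                raise DataError("cluster_id contains missing labels")
        if self.subgroup_labels is not None and len(self.subgroup_labels) != self.n:
            raise DataError("subgroup_labels row count mismatch")

    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def n_events(self) -> int:
        return int(self.outcome.sum())

    @property
    def predictor_names(self) -> list[str]:
        return list(self.predictors.columns)

    def require_both_classes(self) -> None:
        if self.n_events == 0 or self.n_events == self.n:
            raise DegenerateOutcomeError(
                f"outcome has {self.n_events} events out of {self.n}; "
                "model fitting requires both classes"
            )

    def subset(self, mask_or_index) -> "Dataset":
        """Row subset, preserving cluster and subgroup columns."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Dataset(
            outcome=self.outcome[idx],
            predictors=self.predictors.iloc[idx].reset_index(drop=True),
            cluster_id=None if self.cluster_id is None
            else self.cluster_id.iloc[idx].reset_index(drop=True),
            subgroup_labels=None if self.subgroup_labels is None
            else self.subgroup_labels.iloc[idx].reset_index(drop=True),
        )

    def to_frame(self, outcome_col: str = "outcome",
                 cluster_col: str = "cluster") -> pd.DataFrame:
        df = self.predictors.copy()
        df.insert(0, outcome_col, self.outcome)
        if self.cluster_id is not None:
            df[cluster_col] = self.cluster_id.values
        if self.subgroup_labels is not None:
            for c in self.subgroup_labels.columns:
                df[c] = self.subgroup_labels[c].values
        return df

    def write_csv(self, path, outcome_col: str = "outcome",
                  cluster_col: str = "cluster", sep: str = ",") -> None:
        self.to_frame(outcome_col, cluster_col).to_csv(path, index=False, sep=sep)


def dataset_from_frame(df: pd.DataFrame, outcome_col: str,
                       cluster_col: str | None = None,
                       subgroup_cols: list[str] | None = None) -> Dataset:
    """Split a flat table into outcome / predictors / labels by column name."""
    for col in [outcome_col] + ([cluster_col] if cluster_col else []) + (subgroup_cols or []):
        if col not in df.columns:
            raise DataError(f"column '{col}' not found in data")
    special = {outcome_col} | ({cluster_col} if cluster_col else set()) | set(subgroup_cols or [])
    predictors = df[[c for c in df.columns if c not in special]]
    return Dataset(
        outcome=df[outcome_col].to_numpy(),
        predictors=predictors.reset_index(drop=True),
        cluster_id=df[cluster_col].reset_index(drop=True) if cluster_col else None,
        subgroup_labels=df[subgroup_cols].reset_index(drop=True) if subgroup_cols else None,
    )


def read_dataset(path, outcome_col: str, cluster_col: str | None = None,
                 subgroup_cols: list[str] | None = None, sep: str = ",") -> Dataset:
    """Read a delimited text file (header row required) into a Dataset."""
    df = pd.read_csv(path, sep=sep)
    return dataset_from_frame(df, outcome_col, cluster_col, subgroup_cols)
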