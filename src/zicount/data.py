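"""Container for count-regression data (outcome, design matrices, offset)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RegressionData", "read_dataset_csv"]

#: column order used by the plain-text dataset interchange format
DATASET_COLUMNS = ["y", "treatment", "age_ge2", "risk2", "risk3", "offset_log"]


@dataclass
class RegressionData:
    """Outcome counts plus count-part and zero-part design matrices.

    Attributes
    ----------
    outcome : ndarray of int
        Non-negative counts, length n.
    count_covariates : ndarray, shape (n, q)
        Design matrix for the log-mean (count) part; first column all ones.
    logit_covariates : ndarray, shape (n, s)
        Design matrix for the structural-zero (logit) part; first column all
        ones.  May have zero columns for families without a zero part.
    offset_log : ndarray, length n
        Log exposure (e.g. log follow-up days) added to the linear predictor
        with coefficient one.
    count_names, logit_names : list of str
        Column labels, used by summaries.
    """

    outcome: np.ndarray
    count_covariates: np.ndarray
    logit_covariates: np.ndarray = None
    offset_log: np.ndarray = None
    count_names: list = field(default=None)
    logit_names: list = field(default=None)

    def __post_init__(self):
        y = np.asarray(self.outcome, dtype=float)
        if y.ndim != 1:
            raise ValueError("outcome must be a 1-d vector")
        if np.any(y < 0) or np.any(y != np.floor(y)) or np.any(~np.isfinite(y)):
            raise ValueError("outcome must contain non-negative integers")
        self.outcome = y.astype(np.int64)
        n = y.shape[0]

        X = np.atleast_2d(np.asarray(self.count_covariates, dtype=float))
        if X.shape[0] != n:
            raise ValueError("count_covariates must have one row per outcome")
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("count_covariates must start with an intercept column of ones")
        self.count_covariates = X

        if self.logit_covariates is None:
            Z = np.empty((n, 0))
        else:
            Z = np.atleast_2d(np.asarray(self.logit_covariates, dtype=float))
            if Z.shape[1] and Z.shape[0] != n:
                raise ValueError("logit_covariates must have one row per outcome")
            if Z.shape[1] and not np.allclose(Z[:, 0], 1.0):
                raise ValueError("logit_covariates must start with an intercept column of ones")
        self.logit_covariates = Z

        off = np.zeros(n) if self.offset_log is None else np.asarray(self.offset_log, dtype=float)
        if off.shape != (n,):
            raise ValueError("offset_log must be a length-n vector")
        self.offset_log = off

        if self.count_names is None:
            self.count_names = [f"x{j}" for j in range(X.shape[1])]
        if self.logit_names is None:
            self.logit_names = [f"z{j}" for j in range(Z.shape[1])]

    @property
    def n(self) -> int:
        return self.outcome.shape[0]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RegressionData":
        """Build from a table with the standard trial columns.

        Expects ``y, treatment, age_ge2, risk2, risk3`` and optionally
        ``offset_log``; the count design is ``[1, treatment, age_ge2, risk2,
        risk3]`` and the zero part is ``[1, treatment]``.
        """
        missing = [c for c in DATASET_COLUMNS[:-1] if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        n = len(df)
        ones = np.ones(n)
        X = np.column_stack(
            [ones, df["treatment"], df["age_ge2"], df["risk2"], df["risk3"]]
        )
        Z = np.column_stack([ones, df["treatment"]])
        off = df["offset_log"].to_numpy(float) if "offset_log" in df.columns else None
        return cls(
            outcome=df["y"].to_numpy(),
            count_covariates=X,
            logit_covariates=Z,
            offset_log=off,
            count_names=["const", "treatment", "age_ge2", "risk2", "risk3"],
            logit_names=["infl_const", "infl_treatment"],
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Inverse of :meth:`from_dataframe` for the standard trial layout."""
        X = self.count_covariates
        if X.shape[1] != 5:
            raise ValueError("to_dataframe expects the standard 5-column count design")
        return pd.DataFrame(
            {
                "y": self.outcome,
                "treatment": X[:, 1].astype(int),
                "age_ge2": X[:, 2].astype(int),
                "risk2": X[:, 3].astype(int),
                "risk3": X[:, 4].astype(int),
                "offset_log": self.offset_log,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_dataset_csv(path) -> RegressionData:
    """Read a dataset written by :meth:`RegressionData.to_csv`."""
    return RegressionData.from_dataframe(pd.read_csv(path))
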