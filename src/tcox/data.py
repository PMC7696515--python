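"""Core data containers and the delimited-text readers/writers shared by all modules.

Expression tables are samples x genes (a flag transposes genes-in-rows files);
clinical tables carry one row per sample with follow-up time in days and an
event indicator (1 = dead/event observed, 0 = alive/censored).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SurvivalDataset",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "align_expression_clinical",
]


@dataclass
class ExpressionMatrix:
    """An n-samples x p-genes expression matrix for one tissue condition.

    Invariants enforced at construction: no missing values, unique gene
    identifiers, at least two genes. Zero-variance genes are rejected by
    :meth:`require_variable_genes` (callers that build correlation matrices
    must call it, or use :meth:`drop_zero_variance`).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    condition: str = "tumor"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, p = self.values.shape
        if p != len(self.gene_ids):
            raise ValueError(f"{p} columns but {len(self.gene_ids)} gene ids")
        if n != len(self.sample_ids):
            raise ValueError(f"{n} rows but {len(self.sample_ids)} sample ids")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene identifiers are not unique")
        if p < 2:
            raise ValueError("need at least two genes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def zero_variance_genes(self) -> list[str]:
        sd = self.values.std(axis=0)
        return [g for g, s in zip(self.gene_ids, sd) if s == 0.0]

    def require_variable_genes(self) -> None:
        bad = self.zero_variance_genes()
        if bad:
            raise ValueError(
                "zero-variance gene(s) — remove before correlation: " + ", ".join(bad)
            )

    def drop_zero_variance(self) -> "ExpressionMatrix":
        sd = self.values.std(axis=0)
        keep = sd > 0.0
        return ExpressionMatrix(
            self.values[:, keep],
            [g for g, k in zip(self.gene_ids, keep) if k],
            self.sample_ids,
            self.condition,
        )

    def transform(self, func: Callable[[np.ndarray], np.ndarray]) -> "ExpressionMatrix":
        """Apply a preprocessing hook (e.g. log1p) to the values; identity by default."""
        return ExpressionMatrix(func(self.values), self.gene_ids, self.sample_ids, self.condition)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class SurvivalDataset:
    """Covariates plus right-censored survival outcome for n samples.

    ``time`` is follow-up in days (strictly positive); ``status`` is 1 where
    the event (death) was observed and 0 where follow-up was censored.
    """

    X: np.ndarray
    time: np.ndarray
    status: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status)
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, p = self.X.shape
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.time) != n or len(self.status) != n or len(self.sample_ids) != n:
            raise ValueError("time/status/sample_ids length must match rows of X")
        if p != len(self.gene_ids):
            raise ValueError("gene_ids length must match columns of X")
        if np.any(self.time <= 0):
            raise ValueError("follow-up times must be strictly positive")
        status = np.asarray(self.status, dtype=float)
        if not np.all(np.isin(status, (0.0, 1.0))):
            raise ValueError("status must be coded 0 (censored) / 1 (event)")
        self.status = status.astype(int)
        if self.status.sum() == 0:
            raise ValueError("dataset contains no observed events")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return SurvivalDataset(
            self.X[idx],
            self.time[idx],
            self.status[idx],
            self.gene_ids,
            [self.sample_ids[i] for i in np.atleast_1d(idx)],
        )


def read_expression(
    path: str | Path,
    condition: str = "tumor",
    sep: str = "\t",
    genes_in_rows: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression table.

    Default orientation is samples-in-rows: header row of gene identifiers,
    first column sample identifiers. ``genes_in_rows=True`` transposes.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#", float_precision="round_trip")
    if genes_in_rows:
        df = df.T
    if df.isna().any().any():
        na_cols = df.columns[df.isna().any()].tolist()
        raise ValueError(f"{path}: missing values in columns {na_cols[:5]}")
    return ExpressionMatrix(
        df.to_numpy(dtype=float), list(df.columns), list(df.index), condition
    )


def write_expression(expr: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    # %.17g guarantees a bit-identical float round-trip through the reader
    expr.to_frame().to_csv(path, sep=sep, index_label="sample_id", float_format="%.17g")


def read_clinical(
    path: str | Path,
    sep: str = "\t",
    time_col: str = "time",
    status_col: str = "status",
    status_map: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Read a clinical table with columns sample_id, time, status.

    ``status_map`` converts string-coded vital status (e.g. {"dead": 1,
    "alive": 0}) to the fixed 1 = event / 0 = censored coding.
    """
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    sid = cols.get("sample_id", df.columns[0])
    for col in (time_col, status_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    out = df[[sid, time_col, status_col]].copy()
    out.columns = ["sample_id", "time", "status"]
    if status_map is not None:
        out["status"] = out["status"].map(
            lambda v: status_map.get(str(v).lower(), v)
        )
    out["sample_id"] = out["sample_id"].astype(str)
    out["time"] = pd.to_numeric(out["time"], errors="raise")
    out["status"] = pd.to_numeric(out["status"], errors="raise").astype(int)
    if not out["status"].isin([0, 1]).all():
        raise ValueError(f"{path}: status must be 0/1 (use status_map for string codes)")
    return out.set_index("sample_id")


def write_clinical(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index_label="sample_id", float_format="%.17g")


def align_expression_clinical(
    expr: ExpressionMatrix, clinical: pd.DataFrame
) -> tuple[SurvivalDataset, int]:
    """Join expression and clinical tables by sample-identifier intersection.

    Returns the joined :class:`SurvivalDataset` (expression-sample order) and
    the number of samples dropped from the union for lacking one of the two
    tables. Samples with non-positive follow-up are also dropped and counted.
    """
    common = [s for s in expr.sample_ids if s in clinical.index]
    clin = clinical.loc[common]
    ok = clin["time"] > 0
    kept = clin.index[ok].tolist()
    n_dropped = len(set(expr.sample_ids) | set(clinical.index)) - len(kept)
    pos = {s: i for i, s in enumerate(expr.sample_ids)}
    rows = [pos[s] for s in kept]
    data = SurvivalDataset(
        expr.values[rows],
        clin.loc[kept, "time"].to_numpy(float),
        clin.loc[kept, "status"].to_numpy(int),
        expr.gene_ids,
        kept,
    )
    return data, n_dropped
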