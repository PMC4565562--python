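"""Model-quality metrics and error bookkeeping.

The central metric is the normalized root-mean-squared error (NRMSE): the
RMSE over all genes and time points divided by the global range
(max − min) of the *observed* data.  Training error is the NRMSE of the
fitted model simulated from the training set's initial condition;
validation error re-simulates the model from an independent series'
initial condition and measures the NRMSE there, i.e. predictive power.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .data import TimeCourseDataset
from .rate_laws import GRNModelParameters
from .simulate import simulate

__all__ = [
    "nrmse",
    "nrmse_values",
    "validate_model",
    "ErrorRecord",
    "aggregate",
    "interval_rollup",
    "summary_table",
    "PENALTY_ERROR",
]

# Objective value assigned to unintegrable candidates: far above any
# attainable NRMSE, finite so the swarm keeps moving.
PENALTY_ERROR = 1e3


def nrmse_values(predicted: np.ndarray, observed: np.ndarray, per_gene: bool = False) -> float:
    """NRMSE between two equally shaped (T, n) arrays.

    Normalization is by the observed array's global range; with
    ``per_gene=True`` each gene's residuals are normalized by that gene's
    own range before pooling.
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {observed.shape}")
    if per_gene:
        rng = observed.max(axis=0) - observed.min(axis=0)
        if np.any(rng == 0):
            raise ValueError("a gene with constant observed values has undefined NRMSE")
        return float(np.sqrt(np.mean(((predicted - observed) / rng) ** 2)))
    rng = observed.max() - observed.min()
    if rng == 0:
        raise ValueError("constant observed data: NRMSE normalization undefined")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)) / rng)


def nrmse(predicted: TimeCourseDataset, observed: TimeCourseDataset, per_gene: bool = False) -> float:
    """NRMSE between two datasets on identical time grids and gene sets."""
    if not np.array_equal(predicted.times, observed.times):
        raise ValueError("time grids differ")
    if predicted.gene_names != observed.gene_names:
        raise ValueError("gene sets differ")
    return nrmse_values(predicted.values, observed.values, per_gene=per_gene)


def validate_model(
    params: GRNModelParameters,
    validation: TimeCourseDataset,
    per_gene: bool = False,
) -> float:
    """Predictive NRMSE of ``params`` on an independent series.

    The model is simulated from the validation set's own first row over its
    time grid; an integration failure warns and returns the penalty value.
    """
    if params.gene_names != validation.gene_names:
        raise ValueError("model genes do not match dataset genes")
    sim = simulate(params, validation.x0, validation.times)
    if sim.meta.get("failed"):
        warnings.warn("validation simulation failed; returning penalty error")
        return PENALTY_ERROR
    return nrmse(sim, validation, per_gene=per_gene)


@dataclass
class ErrorRecord:
    """One inference cell of the factorial experiment."""

    system_id: str
    system_rate_law: str
    system_omega_magnitude: float
    model_rate_law: str
    model_omega_interval: tuple[float, float]
    replication_index: int
    seed: int
    training_error: float
    validation_error: float
    n_evaluations: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.training_error) and self.training_error >= 0):
            raise ValueError("training_error must be finite and >= 0")
        if not (np.isfinite(self.validation_error) and self.validation_error >= 0):
            raise ValueError("validation_error must be finite and >= 0")
        self.model_omega_interval = (
            float(self.model_omega_interval[0]),
            float(self.model_omega_interval[1]),
        )


def records_frame(records: list[ErrorRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    df["model_omega_interval"] = df["model_omega_interval"].map(
        lambda iv: f"[{iv[0]:g},{iv[1]:g}]"
    )
    return df


def aggregate(
    records: list[ErrorRecord] | pd.DataFrame,
    group_by: list[str],
    error: str = "validation_error",
) -> pd.DataFrame:
    """Group means and sample (n−1) standard deviations of an error column.

    Singleton groups report ``s = 0`` and set the ``singleton`` flag.
    Grouping by an empty list yields the grand mean over all records.
    """
    df = records_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    if df.empty:
        raise ValueError("no records to aggregate")
    if not group_by:
        df["_all"] = 0
        group_by = ["_all"]
    g = df.groupby(group_by, sort=True)[error]
    out = g.agg(mean="mean", s=lambda v: v.std(ddof=1), n="count").reset_index()
    out["singleton"] = out["n"] == 1
    if out["singleton"].any():
        warnings.warn("singleton group(s): standard deviation reported as 0")
    out.loc[out["singleton"], "s"] = 0.0
    return out.drop(columns=["_all"], errors="ignore")


def summary_table(
    records: list[ErrorRecord] | pd.DataFrame, error: str = "training_error"
) -> pd.DataFrame:
    """Benchmark-style summary: one row per (system, generating law,
    magnitude), one column per (model law, omega interval), cells holding
    the mean error over replications, plus trailing row-wise mean and s."""
    df = records_frame(records) if not isinstance(records, pd.DataFrame) else records
    pivot = df.pivot_table(
        index=["system_id", "system_rate_law", "system_omega_magnitude"],
        columns=["model_rate_law", "model_omega_interval"],
        values=error,
        aggfunc="mean",
    )
    pivot[("row", "mean")] = pivot.mean(axis=1)
    pivot[("row", "s")] = pivot.drop(columns=[("row", "mean")]).std(axis=1, ddof=1)
    return pivot


def interval_rollup(
    records: list[ErrorRecord] | pd.DataFrame, error: str = "training_error"
) -> pd.DataFrame:
    """Average of the per-interval means and standard deviations for every
    system-rate-law x model-rate-law configuration.

    This is the "S(X) -> M(X): average mean +/- average sd" roll-up across
    the omega-interval columns of the error tables.
    """
    per_interval = aggregate(
        records,
        ["system_rate_law", "model_rate_law", "model_omega_interval"],
        error=error,
    )
    roll = (
        per_interval.groupby(["system_rate_law", "model_rate_law"])
        .agg(avg_mean=("mean", "mean"), avg_s=("s", "mean"))
        .reset_index()
    )
    return roll
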