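"""Structure-activity regression: ordinary least squares with R^2.

One response (hemolysis % at a stated concentration) against one named
structural parameter, with optional row exclusion by peptide id.  Plain OLS
with intercept, no weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SarTable", "RegressionResult", "linear_fit", "fit_with_exclusion"]


@dataclass
class SarTable:
    """Per-peptide activity and structural parameter columns."""

    peptide_ids: list[str]
    activity: np.ndarray
    parameters: pd.DataFrame

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if not (len(self.peptide_ids) == len(self.activity) == len(self.parameters)):
            raise ValueError("peptide_ids, activity and parameters must have equal length")
        if len(set(self.peptide_ids)) != len(self.peptide_ids):
            raise ValueError("duplicate peptide ids")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, activity_column: str) -> "SarTable":
        params = frame.drop(columns=[activity_column])
        ids = list(frame.index.astype(str))
        return cls(
            peptide_ids=ids,
            activity=frame[activity_column].to_numpy(dtype=float),
            parameters=params.reset_index(drop=True),
        )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    excluded_ids: tuple[str, ...] = field(default=())
    slope_stderr: float = float("nan")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def linear_fit(x, y) -> RegressionResult:
    """OLS with intercept; R^2 = 1 - SS_res / SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: variance(x) is zero")
    x_mean, y_mean = x.mean(), y.mean()
    sxx = np.sum((x - x_mean) ** 2)
    sxy = np.sum((x - x_mean) * (y - y_mean))
    slope = sxy / sxx
    intercept = y_mean - slope * x_mean
    residuals = y - (slope * x + intercept)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y_mean) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    stderr = (
        float(np.sqrt(ss_res / (n - 2) / sxx)) if n > 2 else float("nan")
    )
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
        n_points=n,
        slope_stderr=stderr,
    )


def fit_with_exclusion(
    table: SarTable, parameter: str, exclude: list[str] | tuple[str, ...] = ()
) -> RegressionResult:
    """OLS of activity against one parameter column, dropping excluded ids."""
    if parameter not in table.parameters.columns:
        raise KeyError(
            f"unknown parameter {parameter!r}; available: {list(table.parameters.columns)}"
        )
    unknown = sorted(set(exclude) - set(table.peptide_ids))
    if unknown:
        raise ValueError(f"unknown peptide ids in exclusion list: {', '.join(unknown)}")
    keep = [pid not in set(exclude) for pid in table.peptide_ids]
    x = table.parameters[parameter].to_numpy(dtype=float)[keep]
    y = table.activity[keep]
    result = linear_fit(x, y)
    return RegressionResult(
        slope=result.slope,
        intercept=result.intercept,
        r_squared=result.r_squared,
        n_points=result.n_points,
        excluded_ids=tuple(exclude),
        slope_stderr=result.slope_stderr,
    )
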