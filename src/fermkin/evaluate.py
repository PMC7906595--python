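"""Descriptive error statistics for comparing simulated and observed courses.

MSE, RMSE, AAD (sum of absolute deviations by default) and the coefficient
of determination, computed per state variable and per model.  Simulated
trajectories are linearly interpolated at the observation times; pairs with
a missing observation are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .simulate import Trajectory

__all__ = ["mse", "rmse", "aad", "r_squared", "compare_models",
           "ComparisonReport", "VARIABLE_COLUMNS"]

#: observed-course column -> report variable name
VARIABLE_COLUMNS = {
    "glucose_g_L": "substrate",
    "biomass_g_L": "biomass",
    "ethanol_g_L": "product",
    "byproduct_g_L": "byproducts",
}


def _paired(obs, pred) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape:
        raise ValidationError(
            f"length mismatch: obs has {o.size} values, pred has {p.size}")
    if o.size == 0:
        raise ValidationError("empty series")
    return o, p


def mse(obs, pred) -> float:
    """Mean squared residual, (g/L)^2."""
    o, p = _paired(obs, pred)
    return float(np.mean((o - p) ** 2))


def rmse(obs, pred) -> float:
    """Root-mean-square residual, g/L; exactly sqrt(mse)."""
    return math.sqrt(mse(obs, pred))


def aad(obs, pred, mode: str = "sum") -> float:
    """Aggregate absolute deviation, g/L: sum (default) or mean of |residuals|."""
    o, p = _paired(obs, pred)
    dev = np.abs(o - p)
    if mode == "sum":
        return float(dev.sum())
    if mode == "mean":
        return float(dev.mean())
    raise ValidationError(f"aad mode must be 'sum' or 'mean', got {mode!r}")


def r_squared(obs, pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    o, p = _paired(obs, pred)
    if o.size < 2:
        raise ValidationError("r_squared needs at least 2 observations")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError(
            "r_squared undefined: observations have zero variance")
    ss_res = float(np.sum((o - p) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class ComparisonReport:
    """Per-variable, per-model error statistics for two candidate models.

    ``table`` has one row per (statistic, variable) pair and one column per
    model label; ``n`` counts the observation pairs used per variable.
    """

    table: pd.DataFrame
    n: dict[str, int]
    labels: tuple[str, str]

    def get(self, statistic: str, variable: str, model: str) -> float:
        row = self.table[(self.table["statistic"] == statistic)
                         & (self.table["variable"] == variable)]
        if row.empty:
            raise KeyError(f"no entry for ({statistic}, {variable})")
        return float(row.iloc[0][model])

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_models(obs_course: pd.DataFrame, model_a: Trajectory,
                   model_b: Trajectory,
                   labels: tuple[str, str] = ("modified", "monod"),
                   aad_mode: str = "sum") -> ComparisonReport:
    """Tabulate MSE, RMSE, AAD and R^2 of two models against one observed course.

    ``obs_course`` must carry ``time_h`` plus any of the standard variable
    columns; each trajectory is interpolated at the observation times (which
    must lie inside both simulated horizons).
    """
    if "time_h" not in obs_course.columns:
        raise ValidationError("observed course lacks column 'time_h'")
    if len(obs_course) == 0:
        raise ValidationError("observed course is empty")
    t_obs = obs_course["time_h"].to_numpy(dtype=float)
    sim_a = model_a.sample(t_obs)
    sim_b = model_b.sample(t_obs)

    rows = []
    counts: dict[str, int] = {}
    for col, variable in VARIABLE_COLUMNS.items():
        if col not in obs_course.columns:
            continue
        o = obs_course[col].to_numpy(dtype=float)
        keep = np.isfinite(o)
        if not keep.any():
            continue
        o = o[keep]
        pa = sim_a[col].to_numpy(dtype=float)[keep]
        pb = sim_b[col].to_numpy(dtype=float)[keep]
        counts[variable] = int(keep.sum())
        stats = {
            "MSE": (mse(o, pa), mse(o, pb)),
            "RMSE": (rmse(o, pa), rmse(o, pb)),
            "AAD": (aad(o, pa, aad_mode), aad(o, pb, aad_mode)),
        }
        if o.size >= 2 and np.ptp(o) > 0:
            stats["R2"] = (r_squared(o, pa), r_squared(o, pb))
        for stat, (va, vb) in stats.items():
            rows.append({"statistic": stat, "variable": variable,
                         labels[0]: va, labels[1]: vb})
    if not rows:
        raise ValidationError(
            "observed course carries no usable variable columns")
    return ComparisonReport(table=pd.DataFrame(rows), n=counts, labels=labels)
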