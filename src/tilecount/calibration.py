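"""Linear bias correction of raw pipeline counts and count-error metrics.

Raw totals systematically underestimate the reference counts (occlusion,
out-of-frame flowers); an ordinary least-squares line mapping raw totals to
reference counts corrects the bias.  Three fitting modes are offered:
full-data OLS, leave-one-out prediction, and an explicit subset of points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationModel",
    "ErrorReport",
    "UnfittableError",
    "fit_ols",
    "apply_model",
    "loo_predictions",
    "error_metrics",
]


class UnfittableError(ValueError):
    """The regression cannot be fitted (too few points or constant x)."""


@dataclass(frozen=True)
class CalibrationModel:
    """OLS line ``corrected = slope * raw + intercept`` with 95% CIs."""

    slope: float
    intercept: float
    slope_ci: Tuple[float, float]
    intercept_ci: Tuple[float, float]
    n: int
    residual_variance: float

    def predict(self, raw) -> np.ndarray:
        """Corrected count(s), floored at zero."""
        raw = np.asarray(raw, dtype=float)
        return np.maximum(self.slope * raw + self.intercept, 0.0)


@dataclass(frozen=True)
class ErrorReport:
    mae: float
    mape: float          # percent
    ape_std: float       # percent, population (divisor n) std of the APEs
    r2: float


def fit_ols(x: Sequence[float], y: Sequence[float],
            confidence: float = 0.95) -> CalibrationModel:
    """Least-squares slope/intercept with t-based confidence intervals
    (n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise UnfittableError(f"need at least 3 points, got {n}")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise UnfittableError("x has zero variance")
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (slope * x + intercept)
    dof = n - 2
    s2 = np.sum(resid ** 2) / dof  # residual variance
    se_slope = np.sqrt(s2 / sxx)
    se_intercept = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    tcrit = stats.t.ppf(0.5 + confidence / 2, dof)
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        slope_ci=(float(slope - tcrit * se_slope),
                  float(slope + tcrit * se_slope)),
        intercept_ci=(float(intercept - tcrit * se_intercept),
                      float(intercept + tcrit * se_intercept)),
        n=int(n),
        residual_variance=float(s2),
    )


def apply_model(model: CalibrationModel, raw: float) -> float:
    """slope * raw + intercept, floored at zero."""
    return float(model.predict(raw))


def loo_predictions(x: Sequence[float], y: Sequence[float]) -> np.ndarray:
    """Leave-one-out corrected value for each point: refit without point i,
    then predict point i."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise UnfittableError(f"leave-one-out needs at least 4 points, got {x.size}")
    out = np.empty_like(x)
    mask = np.ones(x.size, dtype=bool)
    for i in range(x.size):
        mask[i] = False
        try:
            model = fit_ols(x[mask], y[mask])
        except UnfittableError as exc:
            raise UnfittableError(f"fold {i} unfittable: {exc}") from None
        out[i] = model.predict(x[i])
        mask[i] = True
    return out


def error_metrics(predicted: Sequence[float],
                  truth: Sequence[float]) -> ErrorReport:
    """MAE, MAPE (%), population std of the absolute percentage errors (%),
    and R² = 1 - SS_res / SS_tot of predictions against truth."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("predicted and truth must be 1-D arrays of equal length")
    if np.any(t == 0):
        raise ValueError("MAPE undefined: truth contains zero values")
    ape = np.abs(p - t) / np.abs(t) * 100.0
    ss_tot = np.sum((t - t.mean()) ** 2)
    r2 = 1.0 - np.sum((p - t) ** 2) / ss_tot if ss_tot > 0 else (
        1.0 if np.allclose(p, t) else -np.inf)
    return ErrorReport(
        mae=float(np.mean(np.abs(p - t))),
        mape=float(np.mean(ape)),
        ape_std=float(np.std(ape)),  # divisor n
        r2=float(r2),
    )
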