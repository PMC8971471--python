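"""Model evaluation statistics: R^2, RMSE, nRMSE and the consistency classes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PairedSeries",
    "UndefinedStatisticError",
    "r_squared",
    "rmse",
    "nrmse",
    "consistency_class",
    "evaluation_report",
]


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given data."""


@dataclass(frozen=True)
class PairedSeries:
    """Paired measured (x) and estimated (y) values."""

    x: np.ndarray
    y: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if x.size == 0:
            raise ValueError("empty series")
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            raise ValueError("series contain non-finite values")


def _as_pair(p) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, PairedSeries):
        return p.x, p.y
    x, y = p
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def r_squared(p, mode: str = "conventional") -> float:
    """Coefficient of determination.

    ``conventional`` (default) is the squared Pearson correlation of the
    two series.  ``literal`` evaluates the ratio
    sum((y - ybar)^2) / sum((x - ybar)^2), which is not bounded by 1; it is
    kept only for fidelity to the printed formula.
    """
    x, y = _as_pair(p)
    if mode == "literal":
        ybar = y.mean()
        denom = float(np.sum((x - ybar) ** 2))
        if denom == 0.0:
            raise UndefinedStatisticError("literal R^2 undefined: zero denominator")
        return float(np.sum((y - ybar) ** 2) / denom)
    if mode != "conventional":
        raise ValueError(f"unknown mode {mode!r}")
    if x.size < 2 or np.var(x) == 0.0 or np.var(y) == 0.0:
        raise UndefinedStatisticError("R^2 undefined: zero variance")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def rmse(p) -> float:
    """Root-mean-square error between the paired series."""
    x, y = _as_pair(p)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def nrmse(p) -> float:
    """RMSE normalized by the mean of the model estimates, in percent."""
    x, y = _as_pair(p)
    ybar = float(y.mean())
    if ybar == 0.0:
        raise UndefinedStatisticError("nRMSE undefined: mean estimate is zero")
    return 100.0 * rmse((x, y)) / ybar


def consistency_class(nrmse_pct: float) -> str:
    """Classify an nRMSE percentage: <10 high, [10,20) good, [20,30) medium, >=30 poor."""
    if nrmse_pct < 10.0:
        return "high"
    if nrmse_pct < 20.0:
        return "good"
    if nrmse_pct < 30.0:
        return "medium"
    return "poor"


def evaluation_report(p) -> dict:
    """R^2, RMSE, nRMSE and consistency class for one paired series."""
    n = nrmse(p)
    return {
        "r2": r_squared(p),
        "rmse": rmse(p),
        "nrmse_pct": n,
        "class": consistency_class(n),
    }
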