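"""Measure-length characterisation of the group network.

The central quantity is the ordinary least-squares fit of conduction delay
on connection length: under a constant-velocity regime the relation is a
line through the origin with slope 1/v, so the reciprocal of the fitted
slope is the *implied constant conduction velocity* of the network.  The
module also provides the constant-velocity delay matrix built from that
velocity, interval band fractions (e.g. the share of connections with mean
diameter between 3 and 4 um) and Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import DomainError, RegressionError

__all__ = [
    "RegressionSummary",
    "linear_fit",
    "fit_delay_length",
    "constant_velocity_delays",
    "band_fraction",
    "pearson",
]


@dataclass(frozen=True)
class RegressionSummary:
    """OLS fit of delay (s) on length (m) plus the implied velocity.

    ``implied_velocity`` (m/s) is ``1/slope`` and is ``None`` whenever the
    slope is not strictly positive.
    """

    slope: float            # s/m
    intercept: float        # s
    r_squared: float
    n_edges: int
    implied_velocity: Optional[float]

    def __str__(self) -> str:
        v = ("undefined" if self.implied_velocity is None
             else f"{self.implied_velocity:.4f} m/s")
        return (
            f"delay ~ length OLS over {self.n_edges} edges: "
            f"slope={self.slope:.6g} s/m, intercept={self.intercept:.3g} s, "
            f"R^2={self.r_squared:.4f}, implied velocity {v}"
        )


def linear_fit(x, y, *, through_origin: bool = False):
    """OLS of ``y`` on ``x``; returns (slope, intercept, r_squared).

    ``r_squared`` is the squared correlation between fitted and observed
    values (for the intercept model this equals the usual R^2).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise RegressionError("x and y must have equal length")
    if x.size < 3:
        raise RegressionError("need at least 3 points")
    if np.ptp(x) == 0:
        raise RegressionError("degenerate predictor: zero variance")
    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
    fitted = slope * x + intercept
    if np.ptp(fitted) == 0 or np.ptp(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    return slope, intercept, r2


def fit_delay_length(delays, lengths, *,
                     through_origin: bool = False) -> RegressionSummary:
    """Fit delay (s) on length (m) and report the implied velocity.

    The regression keeps its intercept by default even though the implied
    velocity uses only the slope; pass ``through_origin=True`` to force the
    physically motivated zero intercept.
    """
    delays = np.asarray(delays, dtype=float).ravel()
    lengths = np.asarray(lengths, dtype=float).ravel()
    slope, intercept, r2 = linear_fit(lengths, delays,
                                      through_origin=through_origin)
    implied = 1.0 / slope if slope > 0 else None
    return RegressionSummary(slope=slope, intercept=intercept, r_squared=r2,
                             n_edges=int(delays.size),
                             implied_velocity=implied)


def constant_velocity_delays(lengths, v_const, adjacency) -> np.ndarray:
    """Delay matrix ``length / v_const`` on adjacent edges, 0 elsewhere."""
    if v_const is None or v_const <= 0:
        raise DomainError("v_const must be > 0")
    lengths = np.asarray(lengths, dtype=float)
    adjacency = np.asarray(adjacency, dtype=bool)
    tau = np.where(adjacency, lengths / v_const, 0.0)
    np.fill_diagonal(tau, 0.0)
    return tau


def band_fraction(values, lo, hi) -> float:
    """Fraction of entries with ``lo <= value <= hi`` (closed interval)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise RegressionError("band_fraction of an empty vector")
    if not lo < hi:
        raise DomainError("band requires lo < hi")
    return float(np.mean((values >= lo) & (values <= hi)))


def pearson(x, y) -> float:
    """Pearson correlation coefficient of two edge vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise RegressionError("x and y must have equal length")
    if x.size < 3:
        raise RegressionError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise RegressionError("zero-variance input to Pearson correlation")
    return float(stats.pearsonr(x, y).statistic)
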