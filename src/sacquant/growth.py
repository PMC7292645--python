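"""Doubling-time estimation from 96-well OD600 growth curves.

A culture growing exponentially satisfies log10(OD) = log10(OD0) +
slope * t, so the doubling time is log10(2)/slope.  The procedure here
mirrors standard plate-reader practice: pick the linear section of each
curve as the readings whose OD falls inside a fixed OD range (the same
range for every curve of an experiment), regress log10(OD) on time over
that window by ordinary least squares, and convert the slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress
from sklearn.base import BaseEstimator

__all__ = [
    "GrowthCurve",
    "DoublingTimeEstimate",
    "DoublingTimeEstimator",
    "InsufficientWindowError",
    "select_linear_window",
    "fit_doubling_time",
    "percent_change",
    "fit_experiment",
]

LOG10_2 = math.log10(2.0)


class InsufficientWindowError(ValueError):
    """Fewer than the minimum number of readings fall inside the OD range."""


def _median3(x: np.ndarray) -> np.ndarray:
    """3-point running median with edge padding (a monotone trace is a
    fixed point, so smoothing never perturbs clean curves)."""
    padded = np.pad(x, 1, mode="edge")
    stacked = np.stack([padded[:-2], padded[1:-1], padded[2:]])
    return np.median(stacked, axis=0)


@dataclass
class GrowthCurve:
    """Time-stamped OD600 readings for one well."""

    times: np.ndarray  # minutes, strictly increasing
    od: np.ndarray
    well: str = ""
    strain: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD readings must be non-negative")


@dataclass
class DoublingTimeEstimate:
    slope: float  # log10(OD) per minute
    window: tuple[int, int]  # half-open index interval used for the fit
    doubling_time: float  # minutes; nan when not growing
    r_squared: float
    od_range: tuple[float, float]
    growing: bool = True
    intercept: float = math.nan  # log10(OD) at t = 0


def select_linear_window(
    curve: GrowthCurve,
    od_range: tuple[float, float] = (0.1, 0.5),
    min_points: int = 4,
    smooth: bool = True,
) -> tuple[int, int]:
    """Maximal contiguous run of readings whose OD lies inside ``od_range``.

    Selection tests a 3-point median-smoothed copy of the OD trace so a
    single spiky read cannot break the run; the fit itself always uses the
    raw readings.  Returns a half-open (start, stop) index interval.
    """
    lo, hi = od_range
    if lo >= hi:
        raise ValueError("od_range must be (low, high) with low < high")
    od = curve.od
    test = _median3(od) if (smooth and od.size >= 3) else od
    inside = (test >= lo) & (test <= hi)
    best = (0, 0)
    start = None
    for i, flag in enumerate(np.append(inside, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if best[1] - best[0] < min_points:
        raise InsufficientWindowError(
            f"only {best[1] - best[0]} contiguous readings inside OD range "
            f"[{lo}, {hi}]; need {min_points}"
        )
    return best


def fit_doubling_time(
    curve: GrowthCurve,
    window: tuple[int, int],
    od_range: tuple[float, float] = (0.1, 0.5),
) -> DoublingTimeEstimate:
    """OLS of log10(OD) on time over the window; doubling time = log10(2)/slope.

    A non-positive slope flags the well as non-growing (doubling_time nan)
    rather than raising, so batch fits can proceed past dead wells.
    """
    i0, i1 = window
    if i1 - i0 < 4:
        raise ValueError("window must contain at least 4 points")
    t = curve.times[i0:i1]
    od = curve.od[i0:i1]
    if np.any(od <= 0):
        raise ValueError("OD must be positive inside the fit window")
    res = linregress(t, np.log10(od))
    slope = float(res.slope)
    r2 = float(res.rvalue**2)
    icpt = float(res.intercept)
    if slope <= 0:
        return DoublingTimeEstimate(
            slope, window, math.nan, r2, od_range, growing=False, intercept=icpt
        )
    return DoublingTimeEstimate(
        slope, window, LOG10_2 / slope, r2, od_range, intercept=icpt
    )


def percent_change(t_test: float, t_reference: float) -> float:
    """100 * (t_test - t_reference) / t_reference."""
    if t_reference <= 0:
        raise ValueError("reference doubling time must be positive")
    return 100.0 * (t_test - t_reference) / t_reference


def fit_experiment(
    curves: list[GrowthCurve],
    od_range: tuple[float, float] = (0.1, 0.5),
    min_points: int = 4,
) -> pd.DataFrame:
    """Fit every curve of an experiment with the identical OD range.

    Applying one range to all wells is the batch discipline that makes
    doubling times comparable across strains.  Returns a tidy frame with
    one row per well; wells without a usable window get NaN estimates.
    """
    rows = []
    for curve in curves:
        try:
            window = select_linear_window(curve, od_range, min_points)
            est = fit_doubling_time(curve, window, od_range)
            rows.append(
                dict(
                    well=curve.well,
                    strain=curve.strain,
                    condition=curve.condition,
                    slope=est.slope,
                    r_squared=est.r_squared,
                    doubling_time_min=est.doubling_time,
                    window_start=window[0],
                    window_end=window[1],
                    growing=est.growing,
                )
            )
        except InsufficientWindowError:
            rows.append(
                dict(
                    well=curve.well,
                    strain=curve.strain,
                    condition=curve.condition,
                    slope=math.nan,
                    r_squared=math.nan,
                    doubling_time_min=math.nan,
                    window_start=-1,
                    window_end=-1,
                    growing=False,
                )
            )
    return pd.DataFrame(rows)


class DoublingTimeEstimator(BaseEstimator):
    """Doubling-time regression as an sklearn-style estimator.

    Parameters
    ----------
    od_range : (float, float)
        OD600 interval defining the linear section; the default [0.1, 0.5]
        sits above the usual 0.05 inoculum and below static-culture
        saturation.
    min_points : int
        Minimum readings required inside the window.
    smooth : bool
        Median-smooth the OD trace (3-point) for window selection only.

    Attributes (after :meth:`fit`)
    ------------------------------
    slope_ : float
        log10(OD) per minute over the selected window.
    doubling_time_ : float
        log10(2)/slope_, minutes.
    r_squared_ : float
    window_ : (int, int)
    """

    def __init__(
        self,
        od_range: tuple[float, float] = (0.1, 0.5),
        min_points: int = 4,
        smooth: bool = True,
    ):
        self.od_range = od_range
        self.min_points = min_points
        self.smooth = smooth

    def fit(self, X, y=None):
        """Fit on a :class:`GrowthCurve` or an (times, od) pair."""
        curve = X if isinstance(X, GrowthCurve) else GrowthCurve(*X)
        self.window_ = select_linear_window(
            curve, self.od_range, self.min_points, self.smooth
        )
        est = fit_doubling_time(curve, self.window_, self.od_range)
        self.slope_ = est.slope
        self.intercept_ = est.intercept
        self.doubling_time_ = est.doubling_time
        self.r_squared_ = est.r_squared
        self.growing_ = est.growing
        return self

    def predict(self, times):
        """Model OD600 at the given times under the fitted exponential."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "slope_")
        times = np.asarray(times, dtype=float)
        return 10.0 ** (self.intercept_ + self.slope_ * times)

    def fit_predict(self, X):
        return self.fit(X).predict(X.times if isinstance(X, GrowthCurve) else X[0])
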