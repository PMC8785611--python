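"""Static-balance outcome measures for quiet-stance CoP trajectories.

Two outcomes summarise a quiet-standing window: the area of the ellipse
covering 95% of the two-dimensional CoP scatter, and the mean absolute CoP
velocity. Both are computed over the middle 20 s of a 30 s trial by
default, with the window's mean CoP as the displacement reference.

The 95% ellipse is the covariance-based prediction ellipse: with sample
covariance ``S`` of (AP, ML), the ellipse is the set of points whose
squared Mahalanobis distance from the mean is at most the 0.95 quantile of
a chi-squared distribution with 2 degrees of freedom (5.9915), and its
area is ``pi * 5.9915 * sqrt(det S)``. This is the de-facto standard
construction in posturography; the chi-squared constant is recorded in the
result so an alternative construction can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputWarning, InsufficientDataError
from .signal_io import (CoPTrajectory, TrialRecord, VelocitySeries,
                        cop_velocity, displacement_magnitude)

#: 0.95 quantile of chi-squared with 2 df, the prediction-ellipse scale.
CHI2_95_2 = float(stats.chi2.ppf(0.95, df=2))


@dataclass(frozen=True)
class ConfidenceEllipse:
    """A 95% prediction ellipse of a bivariate CoP scatter."""

    center: tuple  # (ap, ml) mm
    cov: np.ndarray  # 2x2 sample covariance, rows/cols = (ap, ml)
    chi2: float
    area: float  # mm^2

    def mahalanobis_sq(self, ap, ml) -> np.ndarray:
        """Squared Mahalanobis distance of points from the ellipse center."""
        diff = np.stack([np.asarray(ap, float) - self.center[0],
                         np.asarray(ml, float) - self.center[1]])
        sol = np.linalg.solve(self.cov, diff)
        return np.einsum("ij,ij->j", diff, sol)

    def contains(self, ap, ml) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        return self.mahalanobis_sq(ap, ml) <= self.chi2


@dataclass(frozen=True)
class SwayMetrics:
    """Static sway outcomes for one analysis window."""

    ellipse_area: float  # mm^2
    mean_velocity: float  # mm/s
    window: tuple  # (start_s, end_s) trial-relative
    n_samples: int
    chi2: float = CHI2_95_2


def ellipse_95(ap, ml, chi2: float = CHI2_95_2) -> ConfidenceEllipse:
    """Fit the 95% prediction ellipse to AP/ML samples.

    Degenerate scatter (all points identical, or collinear) yields zero
    area with a :class:`DegenerateInputWarning`.
    """
    ap = np.asarray(ap, dtype=float)
    ml = np.asarray(ml, dtype=float)
    if len(ap) < 10:
        raise InsufficientDataError("ellipse fit needs at least 10 samples")
    center = (float(np.mean(ap)), float(np.mean(ml)))
    cov = np.cov(ap, ml, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 0 or not np.isfinite(det):
        warnings.warn("degenerate CoP scatter; ellipse area is 0",
                      DegenerateInputWarning, stacklevel=2)
        return ConfidenceEllipse(center, cov, chi2, 0.0)
    area = float(np.pi * chi2 * np.sqrt(det))
    return ConfidenceEllipse(center, cov, chi2, area)


def ellipse_area_95(traj: CoPTrajectory, chi2: float = CHI2_95_2) -> float:
    """95% prediction-ellipse area (mm^2) of a CoP trajectory."""
    return ellipse_95(traj.ap, traj.ml, chi2=chi2).area


def mean_velocity(v: VelocitySeries, window: tuple | None = None) -> float:
    """Arithmetic mean of absolute velocity over a half-open time window."""
    if window is None:
        vals = v.v
    else:
        start, end = window
        t = v.times
        mask = (t >= start - 1e-9) & (t < end - 1e-9)
        vals = v.v[mask]
    if len(vals) == 0:
        raise InsufficientDataError("empty velocity window")
    return float(np.mean(vals))


def middle_window(duration_s: float, width_s: float = 20.0) -> tuple:
    """The centred ``width_s`` window of a trial, e.g. [5, 25) of 30 s."""
    start = (duration_s - width_s) / 2.0
    return (start, start + width_s)


def sway_metrics(trial: TrialRecord, window: tuple | None = None,
                 min_duration_s: float = 30.0,
                 chi2: float = CHI2_95_2) -> SwayMetrics:
    """Ellipse area and mean velocity of a quiet-stance trial.

    The default window is the middle 20 s of the trial; both outcomes use
    the same window, and the displacement reference is the window's mean
    CoP. Trials shorter than ``min_duration_s`` are rejected.
    """
    if trial.duration < min_duration_s - 0.5 / trial.fs:
        raise InsufficientDataError(
            f"sway trial of {trial.duration:.2f} s is shorter than the "
            f"required {min_duration_s:g} s")
    traj = trial.combined()
    if window is None:
        window = middle_window(trial.duration)
    sub = traj.slice(*window)
    return sway_metrics_from_trajectory(sub, window=window, chi2=chi2)


def sway_metrics_from_trajectory(traj: CoPTrajectory,
                                 window: tuple | None = None,
                                 chi2: float = CHI2_95_2) -> SwayMetrics:
    """Sway outcomes of an already-windowed trajectory segment."""
    if window is None:
        window = (traj.t0, traj.t0 + traj.duration)
    area = ellipse_area_95(traj, chi2=chi2)
    d = displacement_magnitude(traj)  # reference = window mean CoP
    v = cop_velocity(d)
    return SwayMetrics(ellipse_area=area, mean_velocity=float(np.mean(v.v)),
                       window=(float(window[0]), float(window[1])),
                       n_samples=traj.n, chi2=chi2)
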