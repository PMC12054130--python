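"""Logistic fitting of the occluded-eye deviation and the trial metrics.

The deviation signal of a cover-test trial is modelled as a four-parameter
logistic

    f(t) = L0 + a / (1 + exp(-k (t - t0)))

where ``L0`` is the pre-occlusion level, ``a`` the signed deviation angle
(difference between the two asymptotes; exodeviation negative), ``k`` the
steepness (1/s) and ``t0`` the midpoint.  From a converged fit the trial
statistics follow in closed form:

* peak deviation speed ``b = |a|·k/4`` (the logistic's maximum slope,
  attained at ``t0``);
* stabilization time ``t* = t0 + ln(9)/k``, the first time after occlusion
  onset at which the deviation reaches 90% of its asymptotic value;
* overshoot depth ``d' = max(0, |d − L0| − |a|)`` where ``d`` is the most
  extreme post-onset deviation of the lightly smoothed raw signal — a
  symmetric logistic is monotone and cannot overshoot, so the transient is
  measured on the data, not the fit.

A separate detector flags tropic rebound-saccades: a fast refixation
movement followed within a second by a fast movement in the opposite
direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    FitDataError,
    MetricUnavailableError,
    ParameterError,
    SmallDeviationWarning,
    StabilizationWarning,
)
from .trace_io import GazeTrace
from .units import deg_to_pd

__all__ = [
    "LogisticFitResult",
    "DeviationMetrics",
    "deviation_signal",
    "logistic_model",
    "fit_logistic",
    "peak_speed",
    "stabilization_time",
    "overshoot_depth",
    "classify_overshoot",
    "detect_rebound_saccade",
    "compute_metrics",
]

K_BOUNDS = (0.01, 200.0)  # admissible logistic steepness, 1/s
MIN_SAMPLES_PER_SIDE = 8


def logistic_model(t, baseline, a, k, t0):
    """Four-parameter logistic ``L0 + a/(1 + exp(-k(t - t0)))``."""
    z = np.clip(-k * (np.asarray(t, dtype=float) - t0), -700.0, 700.0)
    return baseline + a / (1.0 + np.exp(z))


def deviation_signal(trace: GazeTrace) -> np.ndarray:
    """Signed per-sample deviation in degrees, exodeviation negative.

    The deviation is the difference between the two eyes' gaze, signed so
    that a temporal (outward) excursion of the covered eye is negative
    whichever eye is covered: ``covered − fixating`` when the left eye is
    covered, ``fixating − covered`` when the right eye is covered (gaze
    positive rightward).  Missing samples propagate as NaN.
    """
    if trace.covered_eye_side == "left":
        dev = trace.covered_eye_pos - trace.fixating_eye_pos
    else:
        dev = trace.fixating_eye_pos - trace.covered_eye_pos
    return np.where(trace.missing_mask, np.nan, dev)


@dataclass
class LogisticFitResult:
    """Fitted logistic parameters for one trial's deviation signal."""

    baseline_deg: float
    deviation_a_deg: float
    rate_k_per_s: float
    midpoint_t0_s: float
    rmse_deg: float
    converged: bool
    n_used: int
    small_deviation: bool = False


def _median3(values: np.ndarray) -> np.ndarray:
    """Centered 3-sample running median, NaN-aware at the edges."""
    return (
        pd.Series(values).rolling(3, center=True, min_periods=1).median().to_numpy()
    )


def _initial_guess(t: np.ndarray, y: np.ndarray, window_post_s: float):
    """Data-driven starting point (L0, a, k, t0) for the logistic fit."""
    pre = y[t < 0]
    baseline = float(np.median(pre))
    tail = y[t >= 0.75 * t.max()]
    a = float(np.median(tail) - baseline) if tail.size else 0.0

    t0, k = 1.0, 1.0
    if abs(a) > 1e-12:
        g = (_median3(y) - baseline) / a  # normalized progress toward asymptote
        crossings = {}
        for level in (0.25, 0.5, 0.75):
            idx = np.nonzero(g >= level)[0]
            if idx.size:
                crossings[level] = float(t[idx[0]])
        if 0.5 in crossings:
            t0 = crossings[0.5]
        if 0.25 in crossings and 0.75 in crossings:
            span = max(crossings[0.75] - crossings[0.25], 1e-3)
            k = 2.0 * math.log(3.0) / span
    k = float(np.clip(k, K_BOUNDS[0] * 1.01, K_BOUNDS[1] * 0.99))
    t0 = float(np.clip(t0, t.min(), min(t.max(), window_post_s)))
    return baseline, a, k, t0


def _amplitude_se(res, rmse: float) -> float:
    """Approximate standard error of the amplitude ``a`` from the Jacobian
    at the optimum; infinite when the parameter is unidentified."""
    try:
        jtj = res.jac.T @ res.jac
        cov = rmse**2 * np.linalg.inv(jtj) * res.fun.size / max(res.fun.size - 4, 1)
        return float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        return math.inf


def fit_logistic(
    trace: GazeTrace,
    window_pre_s: float = 10.0,
    window_post_s: float = 10.0,
) -> LogisticFitResult:
    """Least-squares fit of the 4-parameter logistic to the deviation signal.

    Missing samples are excluded from the loss (never interpolated).  The
    steepness is bounded to ``k ∈ (0.01, 200]``/s; the fit is flagged
    non-converged if the optimizer fails or ends on a bound.  If the fitted
    amplitude is not clearly above the residual noise (``|a| < 2·rmse`` or
    below twice its own standard error) a small-deviation flag is set and a
    warning issued.

    Raises
    ------
    FitDataError
        If fewer than 8 usable samples lie on either side of onset within
        the window.
    """
    t_all = trace.sample_times
    dev = deviation_signal(trace)
    ok = (
        ~trace.missing_mask
        & np.isfinite(dev)
        & (t_all >= -window_pre_s - 1e-9)
        & (t_all <= window_post_s + 1e-9)
    )
    t, y = t_all[ok], dev[ok]
    n_pre, n_post = int(np.sum(t < 0)), int(np.sum(t > 0))
    if n_pre < MIN_SAMPLES_PER_SIDE or n_post < MIN_SAMPLES_PER_SIDE:
        raise FitDataError(
            f"need >= {MIN_SAMPLES_PER_SIDE} non-missing samples on each side of "
            f"onset, got {n_pre} pre / {n_post} post"
        )

    x0 = _initial_guess(t, y, window_post_s)
    lb = [-np.inf, -np.inf, K_BOUNDS[0], float(t.min())]
    ub = [np.inf, np.inf, K_BOUNDS[1], float(min(t.max(), window_post_s))]
    x0 = tuple(np.clip(x0, lb, ub))

    def residuals(p):
        return logistic_model(t, *p) - y

    res = least_squares(
        residuals,
        x0,
        bounds=(lb, ub),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=5000,
    )
    baseline, a, k, t0 = (float(v) for v in res.x)
    rmse = float(np.sqrt(np.mean(res.fun**2)))
    on_bound = k <= K_BOUNDS[0] * 1.001 or k >= K_BOUNDS[1] * 0.999
    converged = bool(res.success) and not on_bound
    small = abs(a) < 2.0 * rmse or abs(a) < 2.0 * _amplitude_se(res, rmse)
    if small:
        warnings.warn(
            f"fitted deviation |a|={abs(a):.3f} deg is below twice the residual "
            f"noise (rmse={rmse:.3f} deg); deviation may not be real",
            SmallDeviationWarning,
            stacklevel=2,
        )
    return LogisticFitResult(
        baseline_deg=baseline,
        deviation_a_deg=a,
        rate_k_per_s=k,
        midpoint_t0_s=t0,
        rmse_deg=rmse,
        converged=converged,
        n_used=int(t.size),
        small_deviation=small,
    )


def peak_speed(fit: LogisticFitResult) -> float:
    """Peak deviation speed ``b = |a|·k/4`` in deg/s (maximum slope of the
    fitted logistic, attained at ``t0``)."""
    if not fit.converged:
        raise MetricUnavailableError("peak speed requires a converged fit")
    return abs(fit.deviation_a_deg) * fit.rate_k_per_s / 4.0


def stabilization_time(fit: LogisticFitResult) -> float:
    """Time from occlusion onset for the deviation to reach 90% of its
    asymptotic value: ``t0 + ln(9)/k``.

    If the 90% level was already exceeded at onset (midpoint far before the
    occlusion), returns 0 with a :class:`StabilizationWarning`.
    """
    if not fit.converged:
        raise MetricUnavailableError("stabilization time requires a converged fit")
    t_star = fit.midpoint_t0_s + math.log(9.0) / fit.rate_k_per_s
    if t_star <= 0.0:
        warnings.warn(
            "deviation already at 90% of its asymptote at occlusion onset; "
            "stabilization time reported as 0",
            StabilizationWarning,
            stacklevel=2,
        )
        return 0.0
    return t_star


def _tail_asymptote(
    t: np.ndarray, y: np.ndarray, fit: LogisticFitResult
) -> float:
    """Transient-robust estimate of the asymptote difference ``a``.

    A least-squares logistic leans its asymptote into an overshoot
    transient, which would understate the depth measured against it.  The
    final position is instead estimated from the late tail of the record,
    where the transient has decayed: the median of
    ``(y − L0)/σ(k(t − t0))`` over the last quarter of the window, the
    division undoing whatever fraction of the approach the logistic still
    has to run (exact for slow monotone approaches).  Falls back to the
    fitted ``a`` when the tail is uninformative (midpoint near the window
    end).
    """
    tail = t >= t[-1] - 0.25 * (t[-1] - max(t[0], 0.0))
    sigma = 1.0 / (1.0 + np.exp(-fit.rate_k_per_s * (t - fit.midpoint_t0_s)))
    use = tail & (sigma >= 0.5)
    if np.sum(use) < 4:
        return fit.deviation_a_deg
    return float(np.median((y[use] - fit.baseline_deg) / sigma[use]))


def overshoot_depth(
    trace: GazeTrace,
    fit: LogisticFitResult,
    window_post_s: float = 10.0,
) -> tuple[float, float]:
    """Overshoot depth and maximum post-onset deviation, in degrees.

    The maximum deviation ``d`` is the most extreme post-onset value of the
    3-sample-median-smoothed deviation signal in the direction of the
    fitted ``a``; the depth is how far it goes beyond the final position —
    ``max(0, |d − L0| − |a|)`` with ``a`` re-estimated from the late tail so
    the asymptote does not lean into the transient — and is zero for a
    monotone approach.
    """
    if not fit.converged:
        raise MetricUnavailableError("overshoot depth requires a converged fit")
    t = trace.sample_times
    dev = deviation_signal(trace)
    post = (t > 0) & (t <= window_post_s + 1e-9) & np.isfinite(dev)
    if not np.any(post):
        raise MetricUnavailableError("no usable post-onset samples")
    smoothed = _median3(dev[post])
    if fit.deviation_a_deg < 0:
        max_dev = float(np.nanmin(smoothed))
    else:
        max_dev = float(np.nanmax(smoothed))
    good = np.isfinite(dev)
    a_final = _tail_asymptote(t[good], dev[good], fit)
    depth = max(0.0, abs(max_dev - fit.baseline_deg) - abs(a_final))
    return depth, max_dev


def classify_overshoot(depth_deg: float) -> str:
    """Overshoot category: ``gt1`` (> 1°), ``mid`` (0.5°–1.0°) or ``lt0p5``
    (< 0.5°)."""
    if depth_deg < 0:
        raise ParameterError(f"overshoot depth must be >= 0, got {depth_deg}")
    if depth_deg > 1.0:
        return "gt1"
    if depth_deg >= 0.5:
        return "mid"
    return "lt0p5"


def _finite_difference_speed(t: np.ndarray, x: np.ndarray):
    """Per-interval finite-difference velocity between consecutive finite
    samples; returns (midpoint times, velocities)."""
    good = np.isfinite(x)
    t, x = t[good], x[good]
    if t.size < 2:
        return np.array([]), np.array([])
    v = np.diff(x) / np.diff(t)
    return 0.5 * (t[:-1] + t[1:]), v


def detect_rebound_saccade(
    trace: GazeTrace,
    threshold_deg_s: float = 30.0,
    window_s: float = 1.0,
) -> bool:
    """Detect a corrective rebound-saccade on the refixating eye.

    True iff, after occlusion onset, the (3-sample-median-smoothed)
    refixating-eye velocity first exceeds ``threshold_deg_s`` in one
    direction and subsequently exceeds it in the opposite direction within
    ``window_s`` seconds.
    """
    t = trace.sample_times
    post = t >= 0
    smoothed = _median3(np.where(trace.missing_mask, np.nan, trace.fixating_eye_pos)[post])
    tv, v = _finite_difference_speed(t[post], smoothed)
    fast = np.abs(v) > threshold_deg_s
    idx = np.nonzero(fast)[0]
    if idx.size == 0:
        return False
    first = idx[0]
    s1 = math.copysign(1.0, v[first])
    later = idx[(tv[idx] > tv[first]) & (tv[idx] <= tv[first] + window_s)]
    return bool(np.any(np.sign(v[later]) == -s1))


@dataclass
class DeviationMetrics:
    """The per-trial statistics: deviation angle, peak speed, stabilization
    time and overshoot depth, plus the overshoot category, the
    rebound-saccade flag and the auxiliary raw finite-difference speed."""

    angle_deg: float
    angle_pd: float
    peak_speed_deg_s: float
    stabilization_time_s: float
    overshoot_depth_deg: float
    overshoot_category: str
    rebound_saccade: bool
    max_deviation_deg: float
    raw_peak_speed_deg_s: float = math.nan
    small_deviation: bool = False

    def to_dict(self) -> dict:
        return {
            "angle_deg": self.angle_deg,
            "angle_pd": self.angle_pd,
            "peak_speed_deg_s": self.peak_speed_deg_s,
            "stabilization_time_s": self.stabilization_time_s,
            "overshoot_depth_deg": self.overshoot_depth_deg,
            "overshoot_category": self.overshoot_category,
            "rebound_saccade": self.rebound_saccade,
            "max_deviation_deg": self.max_deviation_deg,
            "raw_peak_speed_deg_s": self.raw_peak_speed_deg_s,
            "small_deviation": self.small_deviation,
        }


def raw_peak_speed(trace: GazeTrace, window_post_s: float = 10.0) -> float:
    """Maximum absolute finite-difference speed of the smoothed deviation
    signal after onset (deg/s) — the model-free companion to
    :func:`peak_speed`, relevant when the refixation is saccadic."""
    t = trace.sample_times
    dev = deviation_signal(trace)
    post = (t >= 0) & (t <= window_post_s + 1e-9)
    _, v = _finite_difference_speed(t[post], _median3(dev[post]))
    return float(np.max(np.abs(v))) if v.size else math.nan


def compute_metrics(
    trace: GazeTrace,
    fit: LogisticFitResult | None = None,
    saccade_threshold_deg_s: float = 30.0,
    window_pre_s: float = 10.0,
    window_post_s: float = 10.0,
) -> DeviationMetrics:
    """Fit (if needed) and assemble all per-trial metrics for one trace."""
    if fit is None:
        fit = fit_logistic(trace, window_pre_s, window_post_s)
    if not fit.converged:
        raise MetricUnavailableError("metrics require a converged fit")
    depth, max_dev = overshoot_depth(trace, fit, window_post_s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", StabilizationWarning)
        t_stab = stabilization_time(fit)
    return DeviationMetrics(
        angle_deg=fit.deviation_a_deg,
        angle_pd=deg_to_pd(fit.deviation_a_deg),
        peak_speed_deg_s=peak_speed(fit),
        stabilization_time_s=t_stab,
        overshoot_depth_deg=depth,
        overshoot_category=classify_overshoot(depth),
        rebound_saccade=detect_rebound_saccade(trace, saccade_threshold_deg_s),
        max_deviation_deg=max_dev,
        raw_peak_speed_deg_s=raw_peak_speed(trace, window_post_s),
        small_deviation=fit.small_deviation,
    )
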