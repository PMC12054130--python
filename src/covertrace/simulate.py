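"""Synthetic video-oculography trace and cohort simulator.

Generates seedable, ground-truth-annotated cover-test gaze traces with the
statistical structure the analysis assumes:

* **Phoric traces** — after occlusion the covered eye drifts slowly to its
  fusion-free position along a logistic time course (deviations of a few
  degrees, peak speeds of order 1–10°/s), optionally with a transient
  "overshoot" excursion beyond the final position.
* **Tropic traces** — the manifest case: at occlusion the previously
  deviated eye takes over fixation with a saccadic refixation (tens of
  degrees per second) and a corrective rebound-saccade, while the covered
  eye settles at the manifest deviation.
* **Cohorts** — subjects whose deviation rate increases with deviation
  amplitude, so that larger deviations move faster and stabilize sooner,
  together with a clinical alternate-prism-cover-test (APCT) value offset
  from the device measurement.

All randomness flows from one explicit seed per call; there is no global
RNG state.  Every trace carries its generating parameters and the analytic
ground-truth metrics (angle, peak speed ``|a|k/4``, stabilization time
``t0 + ln 9 / k``, overshoot depth) for recovery tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import NyquistWarning, ParameterError
from .trace_io import CohortRecord, GazeTrace
from .units import deg_to_pd

__all__ = [
    "PhoriaTraceParams",
    "TropiaTraceParams",
    "CohortSimConfig",
    "simulate_phoria_trace",
    "simulate_tropia_trace",
    "simulate_cohort",
]

#: Latency between occlusion onset and the tropic refixation saccade, s.
SACCADE_LATENCY_S = 0.1
#: Pause between the refixation saccade and the corrective rebound-saccade, s.
REBOUND_PAUSE_S = 0.1
#: Reference logistic rate (1/s) at the reference deviation amplitude.
COHORT_RATE_REF = 2.7
#: Reference deviation amplitude (deg) for the rate coupling.
COHORT_ANGLE_REF = 6.0


def _logistic(t: np.ndarray, k: float, t0: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-k * (t - t0)))


def _pulse_shape(t: np.ndarray, t0: float, tau: float) -> np.ndarray:
    """Unit-peak decaying pulse: ``x·exp(1 − x)`` with ``x = (t − t0)/τ``,
    zero for ``t <= t0``; maximum 1 at ``t = t0 + τ``."""
    x = np.maximum((np.asarray(t, dtype=float) - t0) / tau, 0.0)
    return x * np.exp(1.0 - x)


@dataclass
class PhoriaTraceParams:
    """Generating parameters of a phoric (latent-deviation) trace.

    The covered-eye deviation follows ``baseline + a·σ(k(t − t0))`` plus an
    optional overshoot transient and i.i.d. Gaussian noise; exodeviation is
    negative.
    """

    baseline_deg: float = 0.0
    deviation_deg: float = -6.0
    rate_per_s: float = 2.0
    midpoint_s: float = 1.5
    overshoot_amp_deg: float = 0.0
    overshoot_decay_s: float = 1.0
    noise_sd_deg: float = 0.2
    blink_prob: float = 0.0
    fs_hz: float = 30.0
    pre_s: float = 10.0
    post_s: float = 10.0
    covered_eye_side: str = "left"
    seed: int | None = None

    def validate(self) -> None:
        if not self.rate_per_s > 0:
            raise ParameterError(f"rate_per_s must be > 0, got {self.rate_per_s}")
        if not self.fs_hz > 0:
            raise ParameterError(f"fs_hz must be > 0, got {self.fs_hz}")
        if not 0.0 <= self.blink_prob < 1.0:
            raise ParameterError(f"blink_prob must be in [0, 1), got {self.blink_prob}")
        if self.overshoot_amp_deg < 0:
            raise ParameterError("overshoot_amp_deg must be >= 0")
        if self.overshoot_decay_s <= 0:
            raise ParameterError("overshoot_decay_s must be > 0")
        if self.noise_sd_deg < 0:
            raise ParameterError("noise_sd_deg must be >= 0")
        if self.pre_s <= 0 or self.post_s <= 0:
            raise ParameterError("pre_s and post_s must be > 0")
        if self.covered_eye_side not in ("left", "right"):
            raise ParameterError("covered_eye_side must be 'left' or 'right'")


@dataclass
class TropiaTraceParams:
    """Generating parameters of a tropic (manifest-deviation) trace.

    Before occlusion the fellow eye sits at ``pre_deviation_deg`` while the
    soon-to-be-covered eye fixates; at onset the fellow eye refixates with a
    raised-cosine velocity profile of the given peak speed, overshoots by
    ``rebound_amp_deg`` and corrects back (the rebound-saccade), while the
    covered eye settles so the deviation equals ``final_deviation_deg``.
    """

    pre_deviation_deg: float = -17.0
    saccade_peak_speed_deg_s: float = 93.6
    rebound_amp_deg: float = 2.0
    final_deviation_deg: float = -17.4
    noise_sd_deg: float = 0.2
    fs_hz: float = 30.0
    pre_s: float = 10.0
    post_s: float = 10.0
    covered_eye_side: str = "right"
    seed: int | None = None

    def validate(self) -> None:
        if not self.saccade_peak_speed_deg_s > 0:
            raise ParameterError("saccade_peak_speed_deg_s must be > 0")
        if not self.fs_hz > 0:
            raise ParameterError("fs_hz must be > 0")
        if self.rebound_amp_deg < 0:
            raise ParameterError("rebound_amp_deg must be >= 0")
        if self.noise_sd_deg < 0:
            raise ParameterError("noise_sd_deg must be >= 0")


@dataclass
class CohortSimConfig:
    """Cohort-level simulation settings.

    ``speed_coupling`` is the exponent linking the logistic rate to the
    deviation amplitude (``k ∝ |a|^coupling``), so larger deviations both
    move faster and stabilize sooner.  ``overshoot_frac`` sets the fraction
    of subjects whose overshoot transient exceeds 0.5°; transient amplitude
    is coupled to peak deviation speed.  ``apct_offset_pd`` is the
    systematic APCT-minus-device offset in prism diopters (positive means
    the clinical test reads less exotropic than the device).
    """

    n_subjects: int = 13
    deviation_range_deg: tuple[float, float] = (2.0, 10.0)
    speed_coupling: float = 1.5
    overshoot_frac: float = 7.0 / 13.0
    noise_sd_deg: float = 0.2
    apct_offset_pd: float = 4.45
    apct_noise_pd: float = 2.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError(f"n_subjects must be >= 2, got {self.n_subjects}")
        lo, hi = self.deviation_range_deg
        if not (0 < lo < hi):
            raise ParameterError(
                f"deviation_range_deg bounds must be positive and ordered, got {(lo, hi)}"
            )
        if not 0.0 <= self.overshoot_frac <= 1.0:
            raise ParameterError("overshoot_frac must be in [0, 1]")


def _time_grid(pre_s: float, post_s: float, fs_hz: float) -> np.ndarray:
    """Uniform grid covering at least ``pre_s`` before and ``post_s`` after
    onset, with a sample at t = 0."""
    n_pre = int(math.ceil(pre_s * fs_hz - 1e-9))
    n_post = int(math.ceil(post_s * fs_hz - 1e-9))
    return np.arange(-n_pre, n_post + 1) / fs_hz


def _calibrated_pulse_amp(
    a: float, k: float, t0: float, amp: float, tau: float, t_end: float
) -> float:
    """Pulse coefficient ``c`` such that the realized excursion of
    ``a·σ(k(t−t0)) + sign(a)·c·pulse(t)`` beyond the asymptote ``a`` equals
    ``amp``.

    The raw pulse rides on a logistic that has not fully saturated, so an
    uncalibrated coefficient would understate the depth actually reached;
    the calibration makes the generator's nominal overshoot amplitude equal
    the true beyond-asymptote depth of the noise-free trace.
    """
    if amp == 0.0:
        return 0.0
    tt = t0 + np.linspace(1e-4, max(t_end - t0, 4 * tau), 4000)
    shortfall = abs(a) * (1.0 - _logistic(tt, k, t0))  # distance still short of asymptote
    shape = _pulse_shape(tt, t0, tau)

    def excess(c: float) -> float:
        return float(np.max(c * shape - shortfall)) - amp

    hi = amp + abs(a) + 1.0
    if excess(hi) <= 0:  # pulse decays before the logistic saturates; cap
        return hi
    return float(brentq(excess, 0.0, hi, xtol=1e-10))


def phoria_deviation_model(t: np.ndarray, params: PhoriaTraceParams) -> np.ndarray:
    """Noise-free deviation-signal model of a phoric trace (deg)."""
    a = params.deviation_deg
    base = params.baseline_deg + a * _logistic(t, params.rate_per_s, params.midpoint_s)
    if params.overshoot_amp_deg > 0:
        c = _calibrated_pulse_amp(
            a,
            params.rate_per_s,
            params.midpoint_s,
            params.overshoot_amp_deg,
            params.overshoot_decay_s,
            t[-1] if len(t) else params.post_s,
        )
        base = base + math.copysign(1.0, a) * c * _pulse_shape(
            t, params.midpoint_s, params.overshoot_decay_s
        )
    return base


def _ground_truth_phoria(params: PhoriaTraceParams) -> dict:
    a, k, t0 = params.deviation_deg, params.rate_per_s, params.midpoint_s
    return {
        "model": "phoria",
        "params": asdict(params),
        "baseline_deg": params.baseline_deg,
        "angle_deg": a,
        "rate_k_per_s": k,
        "midpoint_t0_s": t0,
        "peak_speed_deg_s": abs(a) * k / 4.0,
        "stabilization_time_s": max(0.0, t0 + math.log(9.0) / k),
        "overshoot_depth_deg": params.overshoot_amp_deg,
    }


def simulate_phoria_trace(params: PhoriaTraceParams) -> GazeTrace:
    """Simulate one phoric cover-test trial.

    The covered-eye series is ``baseline + a·σ(k(t−t0))`` plus the overshoot
    transient and i.i.d. Gaussian noise; the fixating eye is zero-mean
    noise.  Blink-marked samples are set missing.  The generating parameters
    and analytic metrics are stored on ``trace.ground_truth``.
    """
    params.validate()
    t = _time_grid(params.pre_s, params.post_s, params.fs_hz)
    model = phoria_deviation_model(t, params)

    rng = np.random.default_rng(params.seed)
    n = t.size
    sign = 1.0 if params.covered_eye_side == "left" else -1.0
    if params.noise_sd_deg > 0:
        noise_cov = rng.normal(0.0, params.noise_sd_deg, n)
        noise_fix = rng.normal(0.0, params.noise_sd_deg, n)
    else:
        noise_cov = noise_fix = np.zeros(n)
    covered = sign * model + noise_cov
    fixating = noise_fix

    missing = (
        rng.random(n) < params.blink_prob
        if params.blink_prob > 0
        else np.zeros(n, dtype=bool)
    )
    covered = np.where(missing, np.nan, covered)
    fixating = np.where(missing, np.nan, fixating)

    return GazeTrace(
        sample_times=t,
        fixating_eye_pos=fixating,
        covered_eye_pos=covered,
        covered_eye_side=params.covered_eye_side,
        fs_hz=params.fs_hz,
        missing_mask=missing,
        ground_truth=_ground_truth_phoria(params),
    )


def _raised_cosine_displacement(
    t: np.ndarray, t_start: float, amplitude: float, peak_speed: float, fs_hz: float
) -> np.ndarray:
    """Displacement of a raised-cosine-velocity saccade starting at
    ``t_start``; total amplitude ``amplitude`` (signed), duration
    ``2|amplitude|/peak_speed``."""
    if amplitude == 0.0:
        return np.zeros_like(t)
    duration = 2.0 * abs(amplitude) / peak_speed
    if duration < 2.0 / fs_hz:
        warnings.warn(
            f"saccade of {amplitude:.1f} deg at {peak_speed:.0f} deg/s spans "
            f"{duration * fs_hz:.1f} samples at {fs_hz:.0f} Hz and is not "
            "Nyquist-representable; emitting anyway",
            NyquistWarning,
            stacklevel=3,
        )
    phase = np.clip((t - t_start) / duration, 0.0, 1.0)
    return amplitude * (phase - np.sin(2.0 * np.pi * phase) / (2.0 * np.pi))


def simulate_tropia_trace(params: TropiaTraceParams) -> GazeTrace:
    """Simulate one tropic cover-test trial (manifest deviation).

    Before onset the fixating-eye channel (the fellow eye that will take
    over fixation) sits at ``pre_deviation_deg``; at onset it refixates with
    a raised-cosine velocity profile whose peak speed matches
    ``saccade_peak_speed_deg_s``, overshoots by ``rebound_amp_deg`` and
    corrects back.  The covered eye moves conjugately and settles so the
    signed deviation equals ``final_deviation_deg``.
    """
    params.validate()
    t = _time_grid(params.pre_s, params.post_s, params.fs_hz)

    direction = math.copysign(1.0, -params.pre_deviation_deg) if params.pre_deviation_deg else 1.0
    overshoot_target = direction * params.rebound_amp_deg
    main_amp = overshoot_target - params.pre_deviation_deg
    main_dur = 2.0 * abs(main_amp) / params.saccade_peak_speed_deg_s if main_amp else 0.0

    fix_ideal = params.pre_deviation_deg + _raised_cosine_displacement(
        t, SACCADE_LATENCY_S, main_amp, params.saccade_peak_speed_deg_s, params.fs_hz
    )
    if params.rebound_amp_deg > 0:
        rebound_speed = min(200.0, 30.0 + 25.0 * params.rebound_amp_deg)
        rebound_start = SACCADE_LATENCY_S + main_dur + REBOUND_PAUSE_S
        fix_ideal = fix_ideal + _raised_cosine_displacement(
            t, rebound_start, -overshoot_target, rebound_speed, params.fs_hz
        )

    # Signed deviation transitions smoothly from the manifest pre-occlusion
    # deviation to the fusion-free final deviation, starting exactly at
    # onset (logistic rebased so it is zero for t <= 0).
    sig = _logistic(t, 3.0, 0.4)
    sig0 = 1.0 / (1.0 + math.exp(3.0 * 0.4))
    transition = np.maximum(0.0, (sig - sig0) / (1.0 - sig0))
    dev_model = params.pre_deviation_deg + (
        params.final_deviation_deg - params.pre_deviation_deg
    ) * transition

    sign = 1.0 if params.covered_eye_side == "left" else -1.0
    covered_ideal = fix_ideal + sign * dev_model

    rng = np.random.default_rng(params.seed)
    n = t.size
    if params.noise_sd_deg > 0:
        covered = covered_ideal + rng.normal(0.0, params.noise_sd_deg, n)
        fixating = fix_ideal + rng.normal(0.0, params.noise_sd_deg, n)
    else:
        covered = covered_ideal.copy()
        fixating = fix_ideal.copy()

    truth = {
        "model": "tropia",
        "params": asdict(params),
        "angle_deg": params.final_deviation_deg,
        "pre_deviation_deg": params.pre_deviation_deg,
        "saccade_peak_speed_deg_s": params.saccade_peak_speed_deg_s,
        "rebound_amp_deg": params.rebound_amp_deg,
    }
    return GazeTrace(
        sample_times=t,
        fixating_eye_pos=fixating,
        covered_eye_pos=covered,
        covered_eye_side=params.covered_eye_side,
        fs_hz=params.fs_hz,
        missing_mask=np.zeros(n, dtype=bool),
        ground_truth=truth,
    )


def simulate_cohort(config: CohortSimConfig) -> list[CohortRecord]:
    """Simulate a phoric cohort with coupled deviation amplitude and rate.

    Per subject, the deviation amplitude ``|a|`` is uniform over
    ``deviation_range_deg`` (exodeviation, so ``a = −|a|``) and the logistic
    rate follows ``k = k_ref·(|a|/6)^coupling`` with log-normal scatter, so
    peak speed ``|a|k/4`` rises — and stabilization time ``t0 + ln9/k``
    falls — with deviation amplitude.  Overshoot amplitude is proportional
    to peak speed with log-normal scatter, scaled so about
    ``overshoot_frac`` of subjects exceed 0.5°.  The clinical APCT value is
    the device deviation converted to prism diopters plus
    ``apct_offset_pd`` and Gaussian noise.  Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    lo, hi = config.deviation_range_deg

    amp_abs = rng.uniform(lo, hi, n)
    a = -amp_abs
    k = (
        COHORT_RATE_REF
        * (amp_abs / COHORT_ANGLE_REF) ** config.speed_coupling
        * np.exp(rng.normal(0.0, 0.25, n))
    )
    t0 = np.clip(rng.normal(2.0, 0.3, n), 0.5, 4.0)
    peak_speed = amp_abs * k / 4.0

    pulse_weight = peak_speed * np.exp(rng.normal(0.0, 0.3, n))
    if config.overshoot_frac > 0:
        ref = np.quantile(pulse_weight, 1.0 - config.overshoot_frac)
        gain = 0.5 / max(ref, 1e-9)
        overshoot = np.clip(gain * pulse_weight, 0.0, 1.5)
    else:
        overshoot = np.zeros(n)

    apct = deg_to_pd(a) + config.apct_offset_pd + rng.normal(0.0, config.apct_noise_pd, n)
    trace_seeds = rng.integers(0, 2**31 - 1, n)

    records = []
    for i in range(n):
        params = PhoriaTraceParams(
            baseline_deg=0.0,
            deviation_deg=float(a[i]),
            rate_per_s=float(k[i]),
            midpoint_s=float(t0[i]),
            overshoot_amp_deg=float(overshoot[i]),
            overshoot_decay_s=1.0,
            noise_sd_deg=config.noise_sd_deg,
            seed=int(trace_seeds[i]),
        )
        trace = simulate_phoria_trace(params)
        truth = dict(trace.ground_truth)
        truth["apct_pd"] = float(apct[i])
        records.append(
            CohortRecord(
                subject_id=f"S{i + 1:02d}",
                diagnosis="exophoria",
                apct_pd=float(apct[i]),
                trace=trace,
                ground_truth=truth,
            )
        )
    return records
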