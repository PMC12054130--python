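"""Gaze-trace containers, the trace CSV dialect, and trajectory figures.

A :class:`GazeTrace` holds one trial's horizontal gaze time series for both
eyes around a single occlusion event.  By convention time is in seconds with
occlusion onset at ``t = 0`` (pre-onset samples negative), gaze positions are
in degrees with rightward positive, and blink dropouts are explicit missing
markers rather than zeros.

The on-disk dialect is a four-column CSV (``time_s,fixating_deg,covered_deg,
missing``) with a JSON metadata sidecar carrying the covered-eye side, the
sampling rate and any subject-level fields.  Writing is deterministic: the
same trace always produces a byte-identical file.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .errors import TraceFormatError

logger = logging.getLogger(__name__)

#: Column header of the trace CSV dialect, in order.
TRACE_COLUMNS = ("time_s", "fixating_deg", "covered_deg", "missing")

#: Tolerance on sample spacing uniformity, seconds.
UNIFORMITY_TOL_S = 1e-6


def sidecar_path(csv_path: str | Path) -> Path:
    """Path of the JSON metadata sidecar that accompanies a trace CSV."""
    p = Path(csv_path)
    return p.with_name(p.stem + ".meta.json")


@dataclass
class GazeTrace:
    """One trial's two-eye horizontal gaze record around an occlusion event.

    Parameters
    ----------
    sample_times
        Sample times in seconds on a uniform grid; occlusion onset is 0 and
        lies strictly inside the record (pre-onset times are negative).
    fixating_eye_pos
        Horizontal position of the eye that keeps (or takes over) fixation,
        degrees.  ``NaN`` at missing samples.
    covered_eye_pos
        Horizontal position of the eye occluded at onset, degrees.
    covered_eye_side
        ``"left"`` or ``"right"``; determines the sign mapping from absolute
        gaze to the signed deviation (exodeviation negative).
    fs_hz
        Sampling rate in Hz.
    missing_mask
        Boolean per-sample dropout flags (blinks); missing samples carry no
        usable position.
    ground_truth
        Optional generating parameters and analytic metrics attached by the
        simulator, for recovery tests.  ``None`` for measured data.
    """

    sample_times: np.ndarray
    fixating_eye_pos: np.ndarray
    covered_eye_pos: np.ndarray
    covered_eye_side: str = "left"
    fs_hz: float = 30.0
    missing_mask: np.ndarray | None = None
    ground_truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.fixating_eye_pos = np.asarray(self.fixating_eye_pos, dtype=float)
        self.covered_eye_pos = np.asarray(self.covered_eye_pos, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.sample_times.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        """Check the trace invariants, raising :class:`TraceFormatError`."""
        n = self.sample_times.size
        for name in ("fixating_eye_pos", "covered_eye_pos", "missing_mask"):
            if getattr(self, name).shape != (n,):
                raise TraceFormatError(
                    f"{name} has shape {getattr(self, name).shape}, expected ({n},)"
                )
        if self.covered_eye_side not in ("left", "right"):
            raise TraceFormatError(
                f"covered_eye_side must be 'left' or 'right', got {self.covered_eye_side!r}"
            )
        if not (self.fs_hz > 0):
            raise TraceFormatError(f"fs_hz must be positive, got {self.fs_hz}")
        if n < 3:
            raise TraceFormatError(f"trace needs at least 3 samples, got {n}")
        dt = np.diff(self.sample_times)
        bad = np.nonzero(np.abs(dt - 1.0 / self.fs_hz) >= UNIFORMITY_TOL_S)[0]
        if bad.size:
            i = int(bad[0])
            raise TraceFormatError(
                f"non-uniform sampling at gap index {i}: "
                f"dt={dt[i]:.6f} s, expected {1.0 / self.fs_hz:.6f} s"
            )
        if not (self.sample_times[0] < 0.0 < self.sample_times[-1]):
            raise TraceFormatError(
                "occlusion onset (t=0) must lie strictly inside the record; "
                f"record spans [{self.sample_times[0]:.3f}, {self.sample_times[-1]:.3f}] s"
            )
        ok = ~self.missing_mask
        for name in ("fixating_eye_pos", "covered_eye_pos"):
            vals = getattr(self, name)[ok]
            if not np.all(np.isfinite(vals)):
                raise TraceFormatError(f"non-finite {name} at a non-missing sample")

    @property
    def n_samples(self) -> int:
        return int(self.sample_times.size)

    def equals(self, other: "GazeTrace") -> bool:
        """Field-level equality, missing samples compared by mask only."""
        if (
            self.covered_eye_side != other.covered_eye_side
            or abs(self.fs_hz - other.fs_hz) > 1e-9
            or self.n_samples != other.n_samples
        ):
            return False
        if not np.array_equal(self.missing_mask, other.missing_mask):
            return False
        ok = ~self.missing_mask
        return (
            np.allclose(self.sample_times, other.sample_times, atol=1e-9)
            and np.allclose(self.fixating_eye_pos[ok], other.fixating_eye_pos[ok], atol=1e-9)
            and np.allclose(self.covered_eye_pos[ok], other.covered_eye_pos[ok], atol=1e-9)
        )


@dataclass
class CohortRecord:
    """One subject: diagnosis, clinical prism measurement, trace and metrics."""

    subject_id: str
    diagnosis: str
    apct_pd: float
    trace: GazeTrace
    metrics: Any = None  # DeviationMetrics, optional until computed
    ground_truth: dict[str, Any] | None = field(default=None, repr=False)

    DIAGNOSES = ("exophoria", "intermittent_exotropia", "exotropia")

    def __post_init__(self) -> None:
        if self.diagnosis not in self.DIAGNOSES:
            raise TraceFormatError(
                f"diagnosis {self.diagnosis!r} not in {self.DIAGNOSES}"
            )
        if not math.isfinite(self.apct_pd):
            raise TraceFormatError("apct_pd must be finite")


def write_trace_csv(
    trace: GazeTrace,
    path: str | Path,
    metadata: dict[str, Any] | None = None,
) -> Path:
    """Write a trace to the CSV dialect plus its JSON metadata sidecar.

    Formatting is fixed (six decimal places, ``\\n`` line endings), so
    identical traces produce byte-identical files.  Missing samples are
    written with empty value cells and ``missing=1``.
    """
    path = Path(path)
    lines = [",".join(TRACE_COLUMNS)]
    for t, f, c, m in zip(
        trace.sample_times,
        trace.fixating_eye_pos,
        trace.covered_eye_pos,
        trace.missing_mask,
    ):
        if m:
            lines.append(f"{t:.6f},,,1")
        else:
            lines.append(f"{t:.6f},{f:.6f},{c:.6f},0")
    path.write_text("\n".join(lines) + "\n")

    meta = {"covered_eye_side": trace.covered_eye_side, "fs_hz": trace.fs_hz}
    if metadata:
        meta.update(metadata)
    sidecar_path(path).write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    return path


def read_trace_csv(
    path: str | Path,
    covered_eye_side: str | None = None,
    fs_hz: float | None = None,
) -> GazeTrace:
    """Read a trace CSV (and its sidecar, if present) into a :class:`GazeTrace`.

    ``covered_eye_side`` and ``fs_hz`` override the sidecar; if neither a
    sidecar nor an override provides them, the side defaults to ``"left"``
    and the rate is inferred from the median sample spacing.

    Raises
    ------
    TraceFormatError
        On a malformed header, a non-numeric cell, duplicate timestamps or
        non-uniform sampling, naming the offending row.
    """
    path = Path(path)
    meta: dict[str, Any] = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    side = covered_eye_side or meta.get("covered_eye_side", "left")

    times: list[float] = []
    fix: list[float] = []
    cov: list[float] = []
    missing: list[bool] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TraceFormatError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header) != TRACE_COLUMNS:
            raise TraceFormatError(
                f"{path}: malformed header {header!r}, expected {list(TRACE_COLUMNS)}"
            )
        for row_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise TraceFormatError(
                    f"{path}: row {row_no}: expected 4 cells, got {len(row)}"
                )
            try:
                t = float(row[0])
                m = int(row[3])
            except ValueError as exc:
                raise TraceFormatError(f"{path}: row {row_no}: non-numeric cell ({exc})") from None
            if m not in (0, 1):
                raise TraceFormatError(f"{path}: row {row_no}: missing flag must be 0 or 1")
            if m:
                f_val = c_val = math.nan
            else:
                try:
                    f_val = float(row[1])
                    c_val = float(row[2])
                except ValueError as exc:
                    raise TraceFormatError(
                        f"{path}: row {row_no}: non-numeric cell ({exc})"
                    ) from None
            times.append(t)
            fix.append(f_val)
            cov.append(c_val)
            missing.append(bool(m))

    t_arr = np.asarray(times)
    if t_arr.size >= 2:
        dt = np.diff(t_arr)
        dup = np.nonzero(dt <= 0)[0]
        if dup.size:
            i = int(dup[0])
            raise TraceFormatError(
                f"{path}: duplicate or non-increasing timestamp at data row {i + 2}"
            )
    fs = fs_hz or meta.get("fs_hz") or (
        1.0 / float(np.median(np.diff(t_arr))) if t_arr.size >= 2 else 30.0
    )
    return GazeTrace(
        sample_times=t_arr,
        fixating_eye_pos=np.asarray(fix),
        covered_eye_pos=np.asarray(cov),
        covered_eye_side=side,
        fs_hz=float(fs),
        missing_mask=np.asarray(missing, dtype=bool),
    )


def render_trace_figure(trace, fit, metrics, path: str | Path) -> Path:
    """Render a trajectory figure: both eyes, occlusion bar, fitted overlay.

    The figure shows each eye's horizontal position against time, an
    occlusion indicator along the top (raised while the eye is covered), the
    fitted logistic overlaid on the covered eye, a vertical dotted line at
    the stabilization time, and annotations for the deviation angle ``a``
    and the maximum deviation ``d``.  If the stabilization time falls
    outside the plotted window, the dotted line is omitted with a logged
    warning.
    """
    from matplotlib.figure import Figure

    t = trace.sample_times
    fig = Figure(figsize=(7, 4))
    ax = fig.add_subplot(111)
    ax.plot(t, trace.fixating_eye_pos, color="tab:blue", lw=1.0, label="fixating eye")
    ax.plot(
        t,
        trace.covered_eye_pos,
        color="tab:orange",
        lw=1.0,
        label=f"covered eye ({trace.covered_eye_side})",
    )

    # Fitted deviation mapped back into covered-eye coordinates (fixating
    # eye is near 0, so the mapping is a pure sign flip for the right eye).
    sign = 1.0 if trace.covered_eye_side == "left" else -1.0
    tt = np.linspace(t[0], t[-1], 800)
    curve = fit.baseline_deg + fit.deviation_a_deg / (
        1.0 + np.exp(-fit.rate_k_per_s * (tt - fit.midpoint_t0_s))
    )
    ax.plot(tt, sign * curve, color="black", lw=1.5, label="logistic fit")

    # Occlusion indicator: flat line = non-occlusion, protrusion = occlusion.
    finite = np.concatenate(
        [trace.fixating_eye_pos[~trace.missing_mask], trace.covered_eye_pos[~trace.missing_mask]]
    )
    top = float(np.max(finite)) + 2.0
    ax.plot(t, np.where(t >= 0, top + 1.0, top), color="gray", lw=2.0)

    if metrics is not None:
        ts = metrics.stabilization_time_s
        if t[0] <= ts <= t[-1]:
            ax.axvline(ts, ls=":", color="black")
        else:
            logger.warning(
                "stabilization time %.2f s outside plotted window [%.2f, %.2f]; line omitted",
                ts,
                t[0],
                t[-1],
            )
        ax.annotate(
            f"a = {metrics.angle_deg:.2f}°",
            xy=(0.02, 0.06),
            xycoords="axes fraction",
        )
        ax.annotate(
            f"d = {metrics.max_deviation_deg:.2f}°",
            xy=(0.02, 0.14),
            xycoords="axes fraction",
        )

    ax.set_xlabel("time from occlusion onset (s)")
    ax.set_ylabel("horizontal gaze (deg)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    return path
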