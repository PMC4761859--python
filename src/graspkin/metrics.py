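"""Per-trial spatio-temporal variables and descriptive group summaries.

Implements the classical upper-limb reach metrics on the instrumented
glass's signals:

* **movement units** — acceleration/deceleration pulses of the speed
  profile; one unit per local maximum whose drop to the following
  minimum exceeds a threshold, plus the terminal deceleration to rest.
  The default speed channel is the *rotation speed* |d(eulerY)/dt|
  (threshold 8 °/s); the classical translational channel (threshold
  40 mm/s) is available through the reconstructed path.
* **straightness index** — straight-line endpoint distance over traveled
  arc length of the sagittal-plane path; 1 means perfectly straight.
* **energy expenditure** — accelerometer activity counts: the
  time-weighted sum of gravity-compensated acceleration magnitude over a
  phase window (arbitrary units).
* **velocity statistics** — mean and peak speed over transport.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt

from .errors import ParameterError, UndefinedMetricError
from .imu import ImuTrace, LinearAccTrace, gravity_compensate, lowpass
from .segmentation import TaskEvents

#: default movement-unit thresholds per speed channel
UNIT_THRESHOLD_ROTATIONAL = 8.0    # deg/s
UNIT_THRESHOLD_TRANSLATIONAL = 40.0  # mm/s


@dataclass
class PathTrace:
    """Sagittal-plane positions in millimetres."""

    t: np.ndarray
    xy: np.ndarray   # (n, 2) mm

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (self.t.shape[0], 2):
            raise ParameterError("xy must be (n, 2) matching t")
        if not np.isfinite(self.xy).all():
            raise ParameterError("path contains non-finite positions")


@dataclass
class KinematicMetrics:
    """Scalar outcome variables of one trial."""

    total_s: float
    movement_units: int
    straightness_transport: float
    straightness_return: float
    energy_transport: float
    energy_return: float
    v_mean: float
    v_peak: float
    speed_channel: str = "rotational"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# movement units

def _alternating_extrema(y: np.ndarray) -> list[tuple[int, str]]:
    """Chronological interior extrema of ``y`` with plateaus collapsed.

    Returns (index, "max"|"min") pairs; a flat extremum is reported at
    its first sample.
    """
    keep = np.concatenate(([True], np.diff(y) != 0))
    idx = np.flatnonzero(keep)
    yc = y[keep]
    if yc.size < 3:
        return []
    d = np.sign(np.diff(yc))
    out = []
    for k in range(1, yc.size - 1):
        if d[k - 1] > 0 and d[k] < 0:
            out.append((int(idx[k]), "max"))
        elif d[k - 1] < 0 and d[k] > 0:
            out.append((int(idx[k]), "min"))
    return out


def count_movement_units(speed: np.ndarray, threshold: float = UNIT_THRESHOLD_ROTATIONAL) -> int:
    """Count movement units of a non-negative speed profile.

    One unit per acceleration–deceleration pulse, counted with the
    classical hysteresis rule: a running maximum followed by a drop
    greater than ``threshold`` is one unit, and a subsequent rise
    greater than the threshold re-arms the counter, so sub-threshold
    oscillations are ignored on both flanks.  The terminal deceleration
    to rest counts through its own maximum, and any nonempty profile
    yields at least 1.

    Because the profile is monotone between extrema, the count depends
    only on the alternating extremum sequence (endpoints included),
    which is what this implementation walks.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0:
        raise ParameterError("empty speed profile")
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    if np.any(speed < 0):
        raise ParameterError("speed profile must be non-negative")
    ext = _alternating_extrema(speed)
    vals = np.r_[speed[0], [speed[i] for i, _ in ext], speed[-1]]
    units = 0
    seeking_drop = True
    anchor = vals[0]
    for v in vals[1:]:
        if seeking_drop:
            if v > anchor:
                anchor = v
            elif anchor - v > threshold:
                units += 1
                seeking_drop = False
                anchor = v
        else:
            if v < anchor:
                anchor = v
            elif v - anchor > threshold:
                seeking_drop = True
                anchor = v
    return max(units, 1)


def rotation_speed(trace: ImuTrace, smooth_hz: float | None = 5.0,
                   order: int = 4) -> np.ndarray:
    """|d(eulerY)/dt| in deg/s, the rotational speed surrogate.

    The tilt series is zero-phase low-pass filtered (default 5 Hz —
    voluntary reach movements live well below that) before central
    differencing, so the derivative does not amplify sensor noise into
    spurious movement units.
    """
    if len(trace) < 3:
        raise ParameterError("need at least 3 samples to differentiate")
    angle = trace.euler_y.astype(float)
    if smooth_hz is not None:
        fs = 1.0 / trace.dt
        if smooth_hz >= fs / 2:
            raise ParameterError("smooth_hz at or above Nyquist")
        b, a = butter(order, smooth_hz / (fs / 2))
        padlen = min(len(angle) - 1,
                     max(3 * max(len(a), len(b)), int(3 * fs / smooth_hz)))
        if len(angle) > 3 * max(len(a), len(b)):
            angle = filtfilt(b, a, angle, padlen=padlen)
    return np.abs(np.gradient(angle, trace.t))


def path_speed(path: PathTrace) -> np.ndarray:
    """Tangential speed of a path in mm/s."""
    if len(path.t) < 3:
        raise ParameterError("need at least 3 samples to differentiate")
    v = np.gradient(path.xy, path.t, axis=0)
    return np.linalg.norm(v, axis=1)


# ---------------------------------------------------------------------------
# path reconstruction and straightness

def _check_uniform(t: np.ndarray, tol: float = 0.05) -> None:
    dt = np.diff(t)
    med = np.median(dt)
    if np.max(np.abs(dt - med)) > tol * med:
        raise ParameterError(
            "sampling jitter exceeds 5%; resample the trace first")


def reconstruct_path(lin: LinearAccTrace, events: TaskEvents,
                     phase: str = "transport",
                     plane: tuple[int, int] = (0, 2)) -> PathTrace:
    """Double-integrate sagittal-plane linear acceleration into a path.

    The device rests on the table before transport and is momentarily
    still at the mouth, so zero-velocity boundary conditions hold at the
    phase endpoints; the velocity obtained by integration is corrected
    by removing a linear drift between them.  Positions in mm.

    ``phase`` is "transport" (B→C), "return" (C→end) or "full" (B→end,
    drift-corrected piecewise with continuous positions).
    """
    _check_uniform(lin.t)
    if phase == "full":
        p1 = reconstruct_path(lin, events, "transport", plane)
        p2 = reconstruct_path(lin, events, "return", plane)
        xy2 = p2.xy - p2.xy[0] + p1.xy[-1]
        return PathTrace(t=np.concatenate([p1.t, p2.t[1:]]),
                         xy=np.vstack([p1.xy, xy2[1:]]))
    if phase == "transport":
        t0, t1 = events.t_b, events.t_c
    elif phase == "return":
        t0, t1 = events.t_c, events.t_end
    else:
        raise ParameterError(f"unknown phase '{phase}'")
    i0 = int(np.searchsorted(lin.t, t0))
    i1 = int(np.searchsorted(lin.t, t1, side="right"))
    if i1 - i0 < 3:
        raise ParameterError("phase window contains fewer than 3 samples")
    ts = lin.t[i0:i1]
    a = lin.lin_acc[i0:i1][:, list(plane)]
    v = cumulative_trapezoid(a, ts, axis=0, initial=0.0)
    ramp = (ts - ts[0]) / (ts[-1] - ts[0])
    v = v - ramp[:, None] * v[-1]          # zero velocity at both endpoints
    p = cumulative_trapezoid(v, ts, axis=0, initial=0.0) * 1000.0
    return PathTrace(t=ts, xy=p)


def straightness_index(path: PathTrace) -> float:
    """Chord length over arc length of the path, in (0, 1].

    1 for a perfectly straight path; invariant under rigid motion and
    uniform scaling of the path.
    """
    if len(path.t) < 2:
        raise ParameterError("path needs at least 2 points")
    steps = np.linalg.norm(np.diff(path.xy, axis=0), axis=1)
    arc = float(steps.sum())
    if arc <= 0.0:
        raise UndefinedMetricError("zero traveled distance")
    chord = float(np.linalg.norm(path.xy[-1] - path.xy[0]))
    # chord <= arc mathematically; clamp the floating-point ratio
    return min(chord / arc, 1.0)


# ---------------------------------------------------------------------------
# energy expenditure

def energy_expenditure(lin: LinearAccTrace,
                       window: tuple[float, float]) -> float:
    """Accelerometer activity counts over a time window.

    Time integral of the resultant gravity-compensated acceleration
    magnitude (units arbitrary; additive over adjacent windows).
    """
    t0, t1 = window
    mask = (lin.t >= t0) & (lin.t <= t1)
    if mask.sum() < 2:
        raise ParameterError("window contains fewer than 2 samples")
    return float(np.trapezoid(lin.resultant[mask], lin.t[mask]))


# ---------------------------------------------------------------------------
# per-trial assembly and group summaries

def compute_metrics(trace: ImuTrace, events: TaskEvents,
                    speed_channel: str = "rotational",
                    unit_threshold: float | None = None,
                    lin: LinearAccTrace | None = None,
                    lowpass_hz: float = 15.0) -> KinematicMetrics:
    """Assemble the per-trial metric set from a trace and its events.

    Straightness comes from the doubly-integrated path when the
    accelerometer carries translational signal; with a near-quiescent
    resultant (rotation-only recording) it is reported as NaN.
    """
    if lin is None:
        lin = gravity_compensate(lowpass(trace, cutoff_hz=lowpass_hz,
                                         include_angles=True))
    t_end = events.t_end
    if speed_channel == "rotational":
        speed = rotation_speed(trace)
        threshold = (unit_threshold if unit_threshold is not None
                     else UNIT_THRESHOLD_ROTATIONAL)
        tspeed = trace.t
    elif speed_channel == "translational":
        path = reconstruct_path(lin, events, phase="full")
        speed = path_speed(path)
        threshold = (unit_threshold if unit_threshold is not None
                     else UNIT_THRESHOLD_TRANSLATIONAL)
        tspeed = path.t
    else:
        raise ParameterError(f"unknown speed channel '{speed_channel}'")

    sel = (tspeed >= events.t_b) & (tspeed <= events.t_c)
    transport_speed = speed[sel]
    units = count_movement_units(transport_speed, threshold)

    def _straightness(phase):
        try:
            p = reconstruct_path(lin, events, phase=phase)
            steps = np.linalg.norm(np.diff(p.xy, axis=0), axis=1)
            if steps.sum() < 1e-3:   # < 1 µm of travel: no translational signal
                return float("nan")
            return straightness_index(p)
        except (ParameterError, UndefinedMetricError):
            return float("nan")

    return KinematicMetrics(
        total_s=t_end - events.t_a,
        movement_units=units,
        straightness_transport=_straightness("transport"),
        straightness_return=_straightness("return"),
        energy_transport=energy_expenditure(lin, (events.t_b, events.t_c)),
        energy_return=energy_expenditure(lin, (events.t_c, t_end)),
        v_mean=float(np.mean(transport_speed)) if transport_speed.size else 0.0,
        v_peak=float(np.max(transport_speed)) if transport_speed.size else 0.0,
        speed_channel=speed_channel,
    )


def summarize_groups(records: pd.DataFrame, by=("age",),
                     metrics: list[str] | None = None) -> pd.DataFrame:
    """Descriptive mean ± SD table per group.

    ``records`` holds one row per trial with metric columns plus the
    grouping labels.  Returns a frame with rows = metrics and a
    (group, statistic) column MultiIndex; SD of a single-record group
    is reported as 0.  No inferential statistics.
    """
    if records is None or len(records) == 0:
        raise ParameterError("no records to summarize")
    by = list(by)
    for b in by:
        if b not in records.columns:
            raise ParameterError(f"grouping column '{b}' not in records")
    if metrics is None:
        metrics = [c for c in records.columns
                   if c not in by and pd.api.types.is_numeric_dtype(records[c])]
    g = records.groupby(by)[metrics].agg(["mean", "std"])
    g.loc[:, (slice(None), "std")] = g.loc[:, (slice(None), "std")].fillna(0.0)
    table = g.T  # rows = (metric, stat), columns = groups
    table.index.names = ["metric", "stat"]
    return table


def format_summary(table: pd.DataFrame, precision: int = 2) -> pd.DataFrame:
    """Render a summarize_groups table as 'mean ± SD' strings."""
    means = table.xs("mean", level="stat")
    sds = table.xs("std", level="stat")
    fmt = f"{{:.{precision}f}} ± {{:.{precision}f}}"
    out = means.copy().astype(object)
    for col in means.columns:
        out[col] = [fmt.format(m, s) for m, s in zip(means[col], sds[col])]
    return out
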