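"""Inertial trial data model, text I/O and signal conditioning.

One recording of the instrumented glass is a time-aligned multi-channel
inertial log: specific force (3-axis accelerometer), angular velocity
(3-axis gyroscope), optionally magnetometer, and the orientation the IMU
firmware already fused (Euler angles and/or a unit quaternion).  This
module owns the :class:`ImuTrace` container, delimited-text reading and
writing, zero-phase low-pass filtering, and gravity compensation into a
world-frame linear-acceleration trace whose resultant magnitude drives
contact detection downstream.

Conventions
-----------
* time in seconds, strictly increasing; nominal sampling rate 87 Hz
* acceleration in m/s² (specific force in the sensor frame)
* angular velocity in deg/s; Euler angles in degrees, columns X, Y, Z,
  composed as intrinsic Z-Y-X (yaw about Z, then pitch about Y, then roll
  about X); Euler angle Y is the sagittal-plane tilt of the glass
* quaternions scalar-first (w, x, y, z), unit norm
* gravity fixed at standard g = 9.80665 m/s²
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .errors import (
    CapabilityError,
    FormatError,
    ParameterError,
    ValidationError,
)

G_STANDARD = 9.80665  # m/s², standard gravity

#: canonical trial CSV header (mag/quat blocks optional, in this order)
CANONICAL_COLUMNS = {
    "t": "t",
    "ax": "ax", "ay": "ay", "az": "az",
    "gx": "gx", "gy": "gy", "gz": "gz",
    "ex": "eulerX", "ey": "eulerY", "ez": "eulerZ",
    "mx": "mx", "my": "my", "mz": "mz",
    "qw": "qw", "qx": "qx", "qy": "qy", "qz": "qz",
}

_MANDATORY = ("t", "ax", "ay", "az", "gx", "gy", "gz", "ex", "ey", "ez")


@dataclass
class ImuTrace:
    """One trial's inertial recording.

    Invariants (checked at construction): all channels share one length
    >= 2; ``t`` strictly increasing with median step within 20% of
    ``1/rate_hz``; quaternions, if present, unit-norm within 1e-3.
    """

    t: np.ndarray
    acc: np.ndarray                       # (n, 3) specific force, m/s²
    gyro: np.ndarray                      # (n, 3) angular velocity, deg/s
    euler: np.ndarray | None = None       # (n, 3) degrees, columns X, Y, Z
    mag: np.ndarray | None = None         # (n, 3) arbitrary units
    quat: np.ndarray | None = None        # (n, 4) scalar-first unit quaternions
    rate_hz: float = 87.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        for name in ("euler", "mag", "quat"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        self.validate()

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def euler_y(self) -> np.ndarray:
        """Sagittal-plane tilt series in degrees."""
        if self.euler is None:
            raise CapabilityError("trace has no Euler angles")
        return self.euler[:, 1]

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds."""
        return float(np.median(np.diff(self.t)))

    def validate(self) -> None:
        n = self.t.shape[0]
        if n < 2:
            raise ValidationError(f"trace needs at least 2 samples, got {n}")
        for name, width in (("acc", 3), ("gyro", 3), ("euler", 3),
                            ("mag", 3), ("quat", 4)):
            v = getattr(self, name)
            if v is None:
                continue
            if v.shape != (n, width):
                raise ValidationError(
                    f"channel '{name}' has shape {v.shape}, expected ({n}, {width})")
        bad = np.flatnonzero(np.diff(self.t) <= 0)
        if bad.size:
            raise ValidationError(
                f"timestamps not strictly increasing; first offending index {bad[0] + 1}")
        med = np.median(np.diff(self.t))
        nominal = 1.0 / self.rate_hz
        if not (0.8 * nominal <= med <= 1.2 * nominal):
            raise ValidationError(
                f"median sampling step {med:.6g}s deviates more than 20% "
                f"from nominal 1/{self.rate_hz:g}s")
        if self.quat is not None:
            norms = np.linalg.norm(self.quat, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-3):
                i = int(np.argmax(np.abs(norms - 1.0)))
                raise ValidationError(
                    f"quaternion at index {i} has norm {norms[i]:.6f}, not unit")

    def rotations(self) -> Rotation:
        """Sensor→world rotation per sample.

        Prefers the quaternion channel; otherwise composes the Euler
        channels as intrinsic Z-Y-X.
        """
        if self.quat is not None:
            return Rotation.from_quat(self.quat[:, [1, 2, 3, 0]])
        if self.euler is not None:
            return Rotation.from_euler(
                "ZYX", self.euler[:, [2, 1, 0]], degrees=True)
        raise CapabilityError(
            "orientation unavailable: trace has neither quaternion nor Euler angles")

    def replace(self, **kwargs) -> "ImuTrace":
        return dataclasses.replace(self, **kwargs)


@dataclass
class LinearAccTrace:
    """Gravity-compensated world-frame linear acceleration.

    ``resultant`` is recomputed from ``lin_acc`` at construction so the
    magnitude invariant holds by construction.
    """

    t: np.ndarray
    lin_acc: np.ndarray                   # (n, 3) m/s², world frame
    resultant: np.ndarray = field(init=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.lin_acc = np.asarray(self.lin_acc, dtype=float)
        if self.lin_acc.shape != (self.t.shape[0], 3):
            raise ValidationError(
                f"lin_acc shape {self.lin_acc.shape} does not match t ({self.t.shape[0]})")
        self.resultant = np.linalg.norm(self.lin_acc, axis=1)

    def __len__(self) -> int:
        return self.t.shape[0]


@dataclass
class ImuDialect:
    """Column map and conventions of a delimited IMU text log.

    ``columns`` maps the logical channel names (t, ax..az, gx..gz,
    ex..ez, optionally mx..mz, qw..qz) to header labels (``has_header``)
    or 0-based positional indices.  The default matches the canonical
    CSV written by :func:`write_trial`.
    """

    delimiter: str | None = ","           # None means any whitespace
    has_header: bool = True
    angle_unit: str = "deg"               # "deg" or "rad"
    rate_hz: float = 87.0
    columns: dict = field(default_factory=lambda: dict(CANONICAL_COLUMNS))


def read_imu_text(path, dialect: ImuDialect | None = None) -> ImuTrace:
    """Read a delimited IMU trial log into a validated :class:`ImuTrace`.

    Raises :class:`FormatError` naming the first missing mandatory column
    and :class:`ValidationError` (from the trace constructor) for
    non-monotone timestamps.
    """
    dialect = dialect or ImuDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = dialect.delimiter if dialect.delimiter is not None else r"\s+"
    try:
        df = pd.read_csv(path, sep=sep, header=0 if dialect.has_header else None,
                         engine="python", comment="#")
    except Exception as exc:  # malformed text
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc

    def col(name, required):
        key = dialect.columns.get(name)
        if key is None:
            if required:
                raise FormatError(f"dialect does not map mandatory column '{name}'")
            return None
        if isinstance(key, int):
            if key >= df.shape[1]:
                if required:
                    raise FormatError(
                        f"missing mandatory column '{name}' (index {key}) in {path.name}")
                return None
            return df.iloc[:, key].to_numpy(dtype=float)
        if key not in df.columns:
            if required:
                raise FormatError(
                    f"missing mandatory column '{name}' ('{key}') in {path.name}")
            return None
        return df[key].to_numpy(dtype=float)

    data = {name: col(name, name in _MANDATORY) for name in CANONICAL_COLUMNS}
    scale = 1.0 if dialect.angle_unit == "deg" else 180.0 / np.pi
    euler = np.column_stack([data["ex"], data["ey"], data["ez"]]) * scale
    mag = None
    if all(data[k] is not None for k in ("mx", "my", "mz")):
        mag = np.column_stack([data["mx"], data["my"], data["mz"]])
    quat = None
    if all(data[k] is not None for k in ("qw", "qx", "qy", "qz")):
        quat = np.column_stack([data[k] for k in ("qw", "qx", "qy", "qz")])
    return ImuTrace(
        t=data["t"],
        acc=np.column_stack([data["ax"], data["ay"], data["az"]]),
        gyro=np.column_stack([data["gx"], data["gy"], data["gz"]]),
        euler=euler, mag=mag, quat=quat, rate_hz=dialect.rate_hz,
    )


def write_trial(trace: ImuTrace, path) -> Path:
    """Write a trace as the canonical trial CSV (fixed header)."""
    path = Path(path)
    cols = {"t": trace.t,
            "ax": trace.acc[:, 0], "ay": trace.acc[:, 1], "az": trace.acc[:, 2],
            "gx": trace.gyro[:, 0], "gy": trace.gyro[:, 1], "gz": trace.gyro[:, 2]}
    euler = trace.euler if trace.euler is not None else np.zeros((len(trace), 3))
    cols.update({"eulerX": euler[:, 0], "eulerY": euler[:, 1], "eulerZ": euler[:, 2]})
    if trace.mag is not None:
        cols.update({"mx": trace.mag[:, 0], "my": trace.mag[:, 1], "mz": trace.mag[:, 2]})
    if trace.quat is not None:
        cols.update({k: trace.quat[:, i]
                     for i, k in enumerate(("qw", "qx", "qy", "qz"))})
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    return path


def lowpass(trace: ImuTrace, cutoff_hz: float = 15.0, order: int = 4,
            include_angles: bool = False, include_gyro: bool = False) -> ImuTrace:
    """Zero-phase Butterworth low-pass of the acceleration channels.

    Forward–backward filtering (``filtfilt``) gives zero group delay, so
    event times are not shifted.  Euler angles and gyroscope channels are
    passed through unchanged unless the corresponding flag is set.
    """
    fs = 1.0 / trace.dt
    if cutoff_hz <= 0:
        raise ParameterError("cutoff must be positive")
    if cutoff_hz >= fs / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz:g} Hz is at or above Nyquist ({fs / 2:g} Hz)")
    b, a = butter(order, cutoff_hz / (fs / 2))
    if len(trace) < 16:
        raise ParameterError(
            f"trace too short to filter: {len(trace)} samples")
    # the default pad length is too short for low normalized cutoffs;
    # extend it to cover the filter's transient (~3 periods of the cutoff)
    padlen = min(len(trace) - 1,
                 max(3 * max(len(a), len(b)), int(3 * fs / cutoff_hz)))

    def f(x):
        return filtfilt(b, a, x, axis=0, padlen=padlen)

    return trace.replace(
        acc=f(trace.acc),
        euler=f(trace.euler) if (include_angles and trace.euler is not None) else trace.euler,
        gyro=f(trace.gyro) if include_gyro else trace.gyro,
    )


def gravity_compensate(trace: ImuTrace, g: float = G_STANDARD) -> LinearAccTrace:
    """Rotate specific force to the world frame and remove gravity.

    Per sample: ``lin = R @ f - (0, 0, g)`` with R the sensor→world
    rotation from the quaternion (preferred) or Euler channels.  For a
    static device the result is zero regardless of orientation.
    """
    rot = trace.rotations()
    lin = rot.apply(trace.acc) - np.array([0.0, 0.0, g])
    return LinearAccTrace(t=trace.t, lin_acc=lin)


def resample_uniform(trace: ImuTrace, rate_hz: float | None = None) -> ImuTrace:
    """Linear-interpolate every channel onto a uniform time grid.

    Needed before integration-based metrics when the log has timing
    jitter; not applied by default anywhere else.
    """
    rate = rate_hz or trace.rate_hz
    n = int(np.floor((trace.t[-1] - trace.t[0]) * rate)) + 1
    tu = trace.t[0] + np.arange(n) / rate

    def interp(arr):
        if arr is None:
            return None
        return np.column_stack(
            [np.interp(tu, trace.t, arr[:, j]) for j in range(arr.shape[1])])

    quat = interp(trace.quat)
    if quat is not None:
        quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    return ImuTrace(t=tu, acc=interp(trace.acc), gyro=interp(trace.gyro),
                    euler=interp(trace.euler), mag=interp(trace.mag),
                    quat=quat, rate_hz=rate)
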