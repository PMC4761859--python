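"""Event detection and phase decomposition of one drinking-simulation trial.

A trial is partitioned by five key instants:

* **A** — first hand–object contact: first local maximum of the
  gravity-compensated, low-pass-filtered resultant acceleration that
  exceeds a contact threshold (default 0.02 m/s²);
* **B** — movement onset: the Euler-Y (sagittal tilt) first departs its
  pre-contact baseline by more than an onset threshold (default 2°);
* **C** — apex: maximum sagittal-tilt excursion, the inversion of the
  movement at the mouth;
* **D** — table contact: second acceleration peak, after the apex;
* **E** — orientation return: tilt back within the onset threshold of
  baseline.

A–B is the *accommodation* phase (hand settles into a stable grasp),
B–C the *transport* phase (glass to the mouth), C–end the *return*.
The trial end is D (table contact) by default; E is also detected and
either can close the trial via ``end_rule``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import EventNotFoundError, ParameterError, ValidationError
from .imu import ImuTrace, LinearAccTrace, gravity_compensate, lowpass

END_RULES = ("table_contact", "orientation_return", "earliest")


@dataclass
class SegmentationParams:
    """Thresholds and rules of the event detectors.

    contact_threshold : m/s²; resultant-acceleration peaks below it are
        ignored (noise floor for contact detection).
    onset_angle_delta : degrees the sagittal tilt must depart its
        pre-contact baseline to mark movement onset.  The matching
        return threshold defaults to the same value.
    baseline_window_s : window before contact over which the baseline
        tilt is taken as the median (robust to spikes).
    peak_min_separation_s : dead time after the apex before a resultant
        peak may count as table contact.
    debounce_samples : consecutive samples a threshold crossing must
        hold to be accepted (rejects single-sample noise triggers).
    apex_refine_s : >0 refines the raw apex argmax by a local quartic
        polynomial fit over a window of this half-width (seconds), which
        localizes the flat top of a smooth reach profile under sensor
        noise; 0 keeps the earliest exact argmax.
    refine_crossings : sub-sample refinement of onset/return crossings
        by a local quadratic fit.
    """

    contact_threshold: float = 0.02
    onset_angle_delta: float = 2.0
    return_angle_delta: float | None = None
    baseline_window_s: float = 0.5
    peak_min_separation_s: float = 0.3
    end_rule: str = "table_contact"
    debounce_samples: int = 3
    lowpass_hz: float = 15.0
    lowpass_order: int = 4
    apex_refine_s: float = 0.35
    refine_crossings: bool = True

    def __post_init__(self):
        for name in ("contact_threshold", "onset_angle_delta",
                     "baseline_window_s", "peak_min_separation_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.return_angle_delta is not None and self.return_angle_delta <= 0:
            raise ParameterError("return_angle_delta must be positive")
        if self.end_rule not in END_RULES:
            raise ParameterError(f"end_rule must be one of {END_RULES}")

    @property
    def return_delta(self) -> float:
        return (self.return_angle_delta
                if self.return_angle_delta is not None else self.onset_angle_delta)


@dataclass
class TaskEvents:
    """The five event timestamps of one trial (seconds).

    ``t_d``/``t_e`` may be absent when the corresponding criterion was
    never met; ``criterion_end`` names which event closed the trial.
    """

    t_a: float
    t_b: float
    t_c: float
    t_d: float | None = None
    t_e: float | None = None
    criterion_end: str = "table_contact"

    def __post_init__(self):
        if not (self.t_a <= self.t_b < self.t_c):
            raise ValidationError(
                f"event ordering violated: A={self.t_a:.4f} B={self.t_b:.4f} "
                f"C={self.t_c:.4f}")
        if self.t_d is not None and not (self.t_c < self.t_d):
            raise ValidationError(
                f"event ordering violated: C={self.t_c:.4f} D={self.t_d:.4f}")

    @property
    def t_end(self) -> float:
        if self.criterion_end == "table_contact" and self.t_d is not None:
            return self.t_d
        if self.criterion_end == "orientation_return" and self.t_e is not None:
            return self.t_e
        cands = [x for x in (self.t_d, self.t_e) if x is not None]
        if not cands:
            raise ValidationError("no end event present")
        return min(cands)

    def as_dict(self) -> dict:
        return {"A": self.t_a, "B": self.t_b, "C": self.t_c,
                "D": self.t_d, "E": self.t_e,
                "criterion_end": self.criterion_end}


@dataclass
class PhaseDecomposition:
    """Phase durations and percentages induced by the events."""

    total_s: float
    accommodation_s: float
    transport_s: float
    return_s: float
    accommodation_pct: float = field(init=False)
    transport_pct: float = field(init=False)
    return_pct: float = field(init=False)

    def __post_init__(self):
        if self.total_s <= 0:
            raise ValidationError("total duration must be positive")
        self.accommodation_pct = 100.0 * self.accommodation_s / self.total_s
        self.transport_pct = 100.0 * self.transport_s / self.total_s
        self.return_pct = 100.0 * self.return_s / self.total_s

    @classmethod
    def from_events(cls, events: TaskEvents) -> "PhaseDecomposition":
        end = events.t_end
        return cls(total_s=end - events.t_a,
                   accommodation_s=events.t_b - events.t_a,
                   transport_s=events.t_c - events.t_b,
                   return_s=end - events.t_c)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("total_s", "accommodation_s", "transport_s", "return_s",
                 "accommodation_pct", "transport_pct", "return_pct")}


# ---------------------------------------------------------------------------
# helpers

def baseline_angle(trace: ImuTrace, t_ref: float, window_s: float) -> float:
    """Median sagittal tilt over the ``window_s`` preceding ``t_ref``."""
    y = trace.euler_y
    mask = (trace.t >= t_ref - window_s) & (trace.t <= t_ref)
    if not mask.any():
        mask = trace.t <= t_ref
    if not mask.any():
        return float(y[0])
    return float(np.median(y[mask]))


def _refine_crossing(t, y, level, i0, half: int = 7) -> float:
    """Sub-sample crossing time of ``y`` through ``level`` near index i0.

    Fits a local quadratic around the first qualifying sample and takes
    the root nearest that sample; falls back to linear interpolation
    between i0-1 and i0, then to the sample time itself.
    """
    lo, hi = max(i0 - half, 0), min(i0 + half + 1, len(t))
    tb = float(t[i0])
    if hi - lo >= 5:
        ts = t[lo:hi] - tb
        try:
            c = np.polyfit(ts, y[lo:hi] - level, 2)
            roots = np.roots(c)
            real = roots[np.abs(roots.imag) < 1e-9].real
            real = real[(real >= ts[0]) & (real <= ts[-1])]
            if real.size:
                return tb + float(real[np.argmin(np.abs(real))])
        except np.linalg.LinAlgError:
            pass
    if i0 > 0 and y[i0] != y[i0 - 1]:
        frac = (level - y[i0 - 1]) / (y[i0] - y[i0 - 1])
        if 0.0 <= frac <= 1.0:
            return float(t[i0 - 1] + frac * (t[i0] - t[i0 - 1]))
    return tb


def _first_sustained(cond: np.ndarray, nmin: int) -> int | None:
    """First index where ``cond`` holds for ``nmin`` consecutive samples."""
    if cond.size < nmin or nmin < 1:
        return None
    ok = cond.copy()
    for k in range(1, nmin):
        ok[:-k] &= cond[k:]
        ok[-k:] = False
    idx = np.flatnonzero(ok)
    return int(idx[0]) if idx.size else None


# ---------------------------------------------------------------------------
# detectors

def _first_contact_peak(t: np.ndarray, resultant: np.ndarray,
                        threshold: float, merge_s: float) -> float | None:
    """First qualifying resultant peak, sidelobe-merged.

    A band-limited contact transient rings: the magnitude of the
    zero-phase-filtered impulse has small symmetric sidelobes around the
    main peak.  Peaks within ``merge_s`` after the first one exceeding
    the threshold belong to the same contact; the largest of them is the
    event time.  This keeps the detection monotone in the threshold.
    """
    peaks, _ = find_peaks(resultant, height=threshold)
    if peaks.size == 0:
        return None
    t0 = t[peaks[0]]
    cluster = peaks[t[peaks] <= t0 + merge_s]
    return float(t[cluster[np.argmax(resultant[cluster])]])


def detect_contact(lin: LinearAccTrace,
                   params: SegmentationParams | None = None) -> float:
    """Time of first contact (event A).

    First local maximum of the resultant linear acceleration exceeding
    ``contact_threshold`` — the acceleration peak when the hand touches
    the glass (sidelobes of one transient merged, see
    :func:`_first_contact_peak`).
    """
    params = params or SegmentationParams()
    t_a = _first_contact_peak(lin.t, lin.resultant, params.contact_threshold,
                              params.peak_min_separation_s)
    if t_a is None:
        raise EventNotFoundError(
            "contact",
            f"no resultant peak exceeds {params.contact_threshold:g} m/s²")
    return t_a


def detect_onset(trace: ImuTrace, t_a: float,
                 params: SegmentationParams | None = None,
                 baseline: float | None = None) -> float:
    """Movement onset (event B): tilt departs the pre-contact baseline.

    First time at/after A where |eulerY − baseline| exceeds
    ``onset_angle_delta`` and stays above it for ``debounce_samples``.
    """
    params = params or SegmentationParams()
    if baseline is None:
        baseline = baseline_angle(trace, t_a, params.baseline_window_s)
    dev = np.abs(trace.euler_y - baseline)
    start = int(np.searchsorted(trace.t, t_a))
    rel = _first_sustained(dev[start:] > params.onset_angle_delta,
                           params.debounce_samples)
    if rel is None:
        raise EventNotFoundError(
            "onset", "sagittal tilt never departs baseline by the onset threshold")
    i0 = start + rel
    t_b = float(trace.t[i0])
    if params.refine_crossings:
        t_b = _refine_crossing(trace.t, dev, params.onset_angle_delta, i0)
    return max(t_b, t_a)


def _refine_apex(t: np.ndarray, dev: np.ndarray, i_max: int,
                 half_s: float, t_min: float) -> float:
    """Quartic-fit apex localization around the raw argmax.

    A smooth out-and-back tilt profile is cubically flat at its apex, so
    the raw argmax wanders under noise.  Fitting a degree-4 polynomial
    over a window centred on the current estimate captures the (odd)
    flank asymmetry exactly on noise-free data while averaging noise;
    two passes with a shrinking window converge to the stationary point.
    """
    center = float(t[i_max])
    for half in (half_s, 0.7 * half_s):
        sel = (t >= max(center - half, t_min)) & (t <= center + half)
        if sel.sum() < 7:
            break
        ts = t[sel] - center
        coef = np.polyfit(ts, dev[sel], 4)
        crit = np.roots(np.polyder(coef))
        crit = crit[np.abs(crit.imag) < 1e-9].real
        crit = crit[(crit >= ts[0]) & (crit <= ts[-1])]
        if crit.size == 0:                # no interior maximum: keep argmax
            break
        center = center + float(crit[np.argmax(np.polyval(coef, crit))])
    return max(center, t_min)


def detect_apex(trace: ImuTrace, t_b: float,
                baseline: float | None = None,
                refine_s: float = 0.0,
                baseline_window_s: float = 0.5) -> float:
    """Apex (event C): maximum tilt excursion after onset.

    With ``refine_s == 0`` this is the exact global argmax of
    |eulerY − baseline| after B, earliest sample on a flat plateau.
    With ``refine_s > 0`` the argmax is refined by a local quartic fit
    (see :func:`_refine_apex`), robust to sensor noise on the flat top
    of a smooth reach profile.
    """
    if baseline is None:
        baseline = baseline_angle(trace, t_b, baseline_window_s)
    start = int(np.searchsorted(trace.t, t_b))
    if start >= len(trace) - 1:
        raise EventNotFoundError("apex", "onset is at the last sample")
    dev = np.abs(trace.euler_y - baseline)
    seg = dev[start:]
    imax = int(np.argmax(seg))            # earliest index on exact ties
    if refine_s <= 0:
        return float(trace.t[start + imax])
    return _refine_apex(trace.t, dev, start + imax, refine_s, t_min=t_b)


def detect_end(trace: ImuTrace, lin: LinearAccTrace, t_c: float,
               params: SegmentationParams | None = None,
               baseline: float | None = None,
               ) -> tuple[float | None, float | None, str]:
    """Trial end: table contact (D) and/or orientation return (E).

    D is the first resultant-acceleration local maximum exceeding the
    contact threshold after ``t_c + peak_min_separation_s``; E the first
    time after C the tilt is back within ``return_delta`` of baseline.
    Returns ``(t_d, t_e, criterion_end)`` with the closing criterion
    chosen by ``params.end_rule``.
    """
    params = params or SegmentationParams()
    if baseline is None:
        baseline = baseline_angle(trace, t_c, params.baseline_window_s)

    t_d = None
    start_d = int(np.searchsorted(lin.t, t_c + params.peak_min_separation_s))
    if start_d < len(lin) - 1:
        t_d = _first_contact_peak(lin.t[start_d:], lin.resultant[start_d:],
                                  params.contact_threshold,
                                  params.peak_min_separation_s)

    t_e = None
    dev = np.abs(trace.euler_y - baseline)
    start_e = int(np.searchsorted(trace.t, t_c))
    rel = _first_sustained(dev[start_e:] < params.return_delta,
                           params.debounce_samples)
    if rel is not None:
        i0 = start_e + rel
        t_e = float(trace.t[i0])
        if params.refine_crossings:
            t_e = _refine_crossing(trace.t, dev, params.return_delta, i0)
        t_e = max(t_e, t_c)

    if t_d is None and t_e is None:
        raise EventNotFoundError(
            "end", "neither table contact nor orientation return detected")
    if params.end_rule == "table_contact":
        criterion = "table_contact" if t_d is not None else "orientation_return"
    elif params.end_rule == "orientation_return":
        criterion = "orientation_return" if t_e is not None else "table_contact"
    else:  # earliest
        if t_d is None:
            criterion = "orientation_return"
        elif t_e is None:
            criterion = "table_contact"
        else:
            criterion = "table_contact" if t_d <= t_e else "orientation_return"
    return t_d, t_e, criterion


def segment_trial(trace: ImuTrace,
                  params: SegmentationParams | None = None,
                  ) -> tuple[TaskEvents, PhaseDecomposition]:
    """Run the full detection chain on a raw trial.

    low-pass → gravity compensation → A → B → C → D/E, then the phase
    decomposition.  Percentages sum to 100 by construction.
    :class:`EventNotFoundError` from any stage carries the stage name.
    """
    params = params or SegmentationParams()
    filt = lowpass(trace, cutoff_hz=params.lowpass_hz,
                   order=params.lowpass_order, include_angles=True)
    lin = gravity_compensate(filt)
    t_a = detect_contact(lin, params)
    base = baseline_angle(filt, t_a, params.baseline_window_s)
    t_b = detect_onset(filt, t_a, params, baseline=base)
    t_c = detect_apex(filt, t_b, baseline=base,
                      refine_s=params.apex_refine_s)
    t_d, t_e, criterion = detect_end(filt, lin, t_c, params, baseline=base)
    events = TaskEvents(t_a=t_a, t_b=t_b, t_c=t_c, t_d=t_d, t_e=t_e,
                        criterion_end=criterion)
    return events, PhaseDecomposition.from_events(events)
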