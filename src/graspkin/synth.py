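"""Synthetic trials and mirror frames with exact ground truth.

No public recording of the instrumented-glass drinking task exists, so
every pipeline stage is exercised against simulated data whose event
times, movement-unit counts, paths and skin masks are known by
construction.

**Trials.**  The sagittal tilt follows a smooth out-and-back profile
built from minimum-jerk segments — the standard primitive of reach
kinematics — with the transport rise split into ``n_movement_units``
sub-movements (velocity peaks).  The accelerometer carries gravity
rotated into the sensor frame by the (noisy) orientation, plus short
raised-cosine contact impulses at grasp contact and table contact;
orientation noise enters the Euler channel and the specific force
*consistently*, the way a real IMU's fused orientation and accelerometer
agree with each other.  Translational specific force is opt-in
(``translation_in_acc``) because the event detectors assume a
near-quiescent resultant between contacts.

Ground-truth events are *definition-consistent*: the latent movement
start is placed so that the noise-free tilt crosses the onset threshold
exactly at the configured accommodation end, making the configured phase
durations the true (recoverable) ones.

**Frames.**  Skin-colored finger bands are painted on the cylinder
surface in (azimuth, height) coordinates and forward-projected through
the mirror model onto the annulus over glass/background colors, with
Gaussian CIELAB chroma noise; the true skin mask is recorded in
panoramic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage import color as skcolor

from .errors import ParameterError
from .imu import G_STANDARD, ImuTrace, write_trial
from .metrics import PathTrace
from .segmentation import SegmentationParams, TaskEvents
from .vision import MirrorModel

#: CIELAB colors of the three materials in a rendered frame
DEFAULT_COLORS = {
    "background": (35.0, -12.0, 6.0),
    "glass": (75.0, -5.0, -12.0),
    "skin": (65.0, 14.0, 17.0),
}

#: finger-like bands on the cylinder surface: (theta0_deg, width_deg,
#: h0_mm, h1_mm); four fingers wrapping the far side of the glass.
DEFAULT_HAND_BANDS = (
    (80.3, 15.0, 40.2, 95.3),
    (103.3, 15.0, 38.2, 95.3),
    (126.3, 15.0, 40.2, 95.3),
    (149.3, 15.0, 42.2, 95.3),
)


# ---------------------------------------------------------------------------
# minimum-jerk primitives

def minjerk(tau):
    """Normalized minimum-jerk position profile on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minjerk_vel(tau):
    tau = np.clip(tau, 0.0, 1.0)
    return 30 * tau**2 - 60 * tau**3 + 30 * tau**4


def minjerk_acc(tau):
    tau = np.clip(tau, 0.0, 1.0)
    return 60 * tau - 180 * tau**2 + 120 * tau**3


def _quintic(p0, p1, a0, a1):
    """Quintic rest-to-rest segment coefficients on normalized time.

    Boundary conditions: p(0)=p0, p(1)=p1, zero velocity at both ends,
    and (normalized) accelerations a0, a1 at the ends.  Coefficients
    returned lowest order first for :func:`numpy.polynomial.polynomial.polyval`.
    With a0 = a1 = 0 this reduces to the minimum-jerk profile.
    """
    A = np.zeros((6, 6))
    rhs = np.array([p0, 0.0, a0, p1, 0.0, a1], dtype=float)
    powers = np.arange(6)
    A[0, 0] = 1.0                                   # p(0)
    A[1, 1] = 1.0                                   # p'(0)
    A[2, 2] = 2.0                                   # p''(0)
    A[3] = 1.0                                      # p(1)
    A[4] = powers                                   # p'(1)
    A[5] = powers * (powers - 1)                    # p''(1)
    return np.linalg.solve(A, rhs)


@dataclass
class TrialConfig:
    """Parameters of one synthetic drinking-simulation trial.

    Defaults emulate the typical developing-child cycle: total duration
    ≈ 2.55 s split 13.3/43.1/43.5% into accommodation, transport and
    return; apex tilt 45°; contact impulses of 0.5 m/s² lasting 30 ms.
    Noise defaults are typical of a consumer AHRS: 0.3° RMS orientation
    jitter and 0.005 m/s² accelerometer noise per axis.
    """

    phase_s: tuple[float, float, float] = (0.34, 1.10, 1.11)
    apex_angle_deg: float = 45.0
    n_movement_units: int = 2
    contact_impulse: float = 0.5          # m/s² peak
    impulse_width_s: float = 0.030
    noise_acc_sigma: float = 0.005        # m/s² per axis
    noise_angle_sigma: float = 0.3        # degrees
    noise_gyro_sigma: float = 0.1         # deg/s
    rate_hz: float = 87.0
    seed: int = 0
    pre_contact_s: float = 0.7
    post_end_s: float = 0.4
    reach_distance_mm: float = 250.0
    reach_elevation_deg: float = 55.0     # direction of the table→mouth line
    translation_in_acc: bool = False
    min_subsegment_s: float = 0.15        # shortest feasible sub-movement
    #: apex reversal sharpness: the angular acceleration at the apex is
    #: -sharpness * sub_amplitude / sub_duration²; the glass reverses
    #: continuously at the lip rather than pausing (0 = dead stop).
    reversal_sharpness: float = 4.0

    def __post_init__(self):
        if any(p <= 0 for p in self.phase_s):
            raise ParameterError("phase durations must be positive")
        if self.n_movement_units < 1:
            raise ParameterError("n_movement_units must be >= 1")
        for name in ("noise_acc_sigma", "noise_angle_sigma", "noise_gyro_sigma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.apex_angle_deg <= 0:
            raise ParameterError("apex_angle_deg must be positive")


@dataclass
class GroundTruth:
    """Exact event times, path, unit count and skin mask of a synthetic input."""

    events: TaskEvents | None = None
    true_path: PathTrace | None = None
    true_units: int | None = None
    true_skin_mask: np.ndarray | None = None
    config: object | None = None


# ---------------------------------------------------------------------------
# trial generation

def _profile_polys(cfg: TrialConfig, dt_sub: float) -> tuple[list, np.ndarray]:
    """Per-segment tilt polynomials (normalized time, degrees).

    The rise is n equal-amplitude sub-movements; all are minimum jerk
    except the final approach, which ends with the apex reversal
    acceleration -q (q = reversal_sharpness * sub_amp / dt_sub**2), and
    the return segment, which starts with it.  The glass therefore
    reverses continuously at the lip instead of pausing dead.
    """
    n = cfg.n_movement_units
    sub_amp = cfg.apex_angle_deg / n
    a_apex = -cfg.reversal_sharpness * sub_amp      # normalized to dt_sub
    ups = []
    for k in range(n):
        a1 = a_apex if k == n - 1 else 0.0
        ups.append(_quintic(k * sub_amp, (k + 1) * sub_amp, 0.0, a1))
    t_down = cfg.phase_s[2]
    a0_down = a_apex * (t_down / dt_sub) ** 2 if dt_sub > 0 else 0.0
    down = _quintic(cfg.apex_angle_deg, 0.0, a0_down, 0.0)
    return ups, down


def _onset_geometry(cfg: TrialConfig, delta_deg: float):
    """Solve the up-segment timing so the onset crossing is calibrated.

    With sub-amplitude dA = apex/n, the noise-free tilt crosses the
    onset threshold at fraction tau* of the first sub-movement.
    Choosing the total rise duration T_up = transport_s / (1 - tau*/n)
    puts the crossing exactly at the configured accommodation end while
    the apex stays at its end.
    """
    n = cfg.n_movement_units
    sub_amp = cfg.apex_angle_deg / n
    if delta_deg >= sub_amp:
        raise ParameterError(
            f"onset threshold {delta_deg:g} deg exceeds sub-movement amplitude "
            f"{sub_amp:g} deg; reduce n_movement_units or raise the apex angle")
    if n > 1:
        first = np.array([0, 0, 0, 10, -15, 6], float) * sub_amp  # minimum jerk
    else:
        first = _quintic(0.0, sub_amp, 0.0, -cfg.reversal_sharpness * sub_amp)
    tau_star = brentq(
        lambda x: np.polynomial.polynomial.polyval(x, first) - delta_deg,
        0.0, 1.0)
    transport = cfg.phase_s[1]
    t_up = transport / (1.0 - tau_star / n)
    dt_sub = t_up / n
    if dt_sub < cfg.min_subsegment_s:
        raise ParameterError(
            f"{n} movement units in a {transport:g}s transport would give "
            f"{dt_sub:.3f}s sub-movements (< {cfg.min_subsegment_s:g}s); "
            "velocity peaks would overlap")
    delay = tau_star * dt_sub             # crossing delay into the rise
    return t_up, dt_sub, delay


def _tilt_profile(t, cfg: TrialConfig, t_rise_start, t_up, t_c, t_d):
    """Noise-free sagittal tilt over the whole trial (degrees)."""
    n = cfg.n_movement_units
    dt_sub = t_up / n
    ups, down = _profile_polys(cfg, dt_sub)
    pv = np.polynomial.polynomial.polyval
    theta = np.zeros_like(t)
    up = (t >= t_rise_start) & (t < t_c)
    rel = t[up] - t_rise_start
    k = np.minimum((rel / dt_sub).astype(int), n - 1)
    tau = np.clip(rel / dt_sub - k, 0.0, 1.0)
    vals = np.empty(rel.shape)
    for j in range(n):
        sel = k == j
        vals[sel] = pv(tau[sel], ups[j])
    theta[up] = vals
    dmask = (t >= t_c) & (t <= t_d)
    theta[dmask] = pv((t[dmask] - t_c) / cfg.phase_s[2], down)
    return theta


def _raised_cosine(t, center, width, amp):
    x = (t - center) / width
    pulse = np.where(np.abs(x) <= 0.5, 0.5 * (1 + np.cos(2 * np.pi * x)), 0.0)
    return amp * pulse


def synth_trial(cfg: TrialConfig | None = None,
                params: SegmentationParams | None = None,
                ) -> tuple[ImuTrace, GroundTruth]:
    """Generate one trial and its exact ground truth.

    ``params`` supplies the onset/return thresholds the ground-truth
    events are calibrated against (defaults match the default
    detectors).  Identical configs produce bit-identical traces.
    """
    cfg = cfg or TrialConfig()
    params = params or SegmentationParams()
    rng = np.random.default_rng(cfg.seed)

    acc_s, transport_s, return_s = cfg.phase_s
    t_up, dt_sub, delay = _onset_geometry(cfg, params.onset_angle_delta)
    if acc_s <= delay:
        raise ParameterError(
            f"accommodation {acc_s:g}s is shorter than the onset rise delay "
            f"{delay:.3f}s; the tilt would cross the threshold before contact")

    t_a = cfg.pre_contact_s
    t_b = t_a + acc_s
    t_c = t_b + transport_s
    t_d = t_c + return_s
    total = t_d + cfg.post_end_s
    n = int(np.floor(total * cfg.rate_hz)) + 1
    t = np.arange(n) / cfg.rate_hz

    theta = _tilt_profile(t, cfg, t_b - delay, t_up, t_c, t_d)

    # return-threshold crossing (event E), analytic on the noise-free tilt
    _, down_poly = _profile_polys(cfg, dt_sub)
    tau_e = brentq(
        lambda x: np.polynomial.polynomial.polyval(x, down_poly)
        - params.return_delta, 0.0, 1.0)
    t_e = t_c + tau_e * return_s

    a_world = np.zeros((n, 3))
    a_world[:, 2] += _raised_cosine(t, t_a, cfg.impulse_width_s, cfg.contact_impulse)
    a_world[:, 2] += _raised_cosine(t, t_d, cfg.impulse_width_s, cfg.contact_impulse)

    elev = np.deg2rad(cfg.reach_elevation_deg)
    direction = np.array([np.cos(elev), 0.0, np.sin(elev)])
    reach_m = cfg.reach_distance_mm / 1000.0
    if cfg.translation_in_acc:
        for (t0, t1, sign) in ((t_b, t_c, +1.0), (t_c, t_d, -1.0)):
            span = (t >= t0) & (t <= t1)
            tau = (t[span] - t0) / (t1 - t0)
            a_world[span] += (sign * reach_m * minjerk_acc(tau)[:, None]
                              / (t1 - t0) ** 2 * direction)

    theta_noisy = theta + rng.normal(0.0, cfg.noise_angle_sigma, n)
    euler = np.zeros((n, 3))
    euler[:, 1] = theta_noisy
    from scipy.spatial.transform import Rotation
    rot = Rotation.from_euler("ZYX", euler[:, [2, 1, 0]], degrees=True)
    f = rot.inv().apply(a_world + np.array([0.0, 0.0, G_STANDARD]))
    f += rng.normal(0.0, cfg.noise_acc_sigma, (n, 3))

    gyro = rng.normal(0.0, cfg.noise_gyro_sigma, (n, 3))
    gyro[:, 1] += np.gradient(theta, t)

    trace = ImuTrace(t=t, acc=f, gyro=gyro, euler=euler, rate_hz=cfg.rate_hz)

    span = (t >= t_b) & (t <= t_c)
    tau = (t[span] - t_b) / transport_s
    xy = (cfg.reach_distance_mm * minjerk(tau)[:, None]
          * np.array([direction[0], direction[2]]))
    truth = GroundTruth(
        events=TaskEvents(t_a=t_a, t_b=t_b, t_c=t_c, t_d=t_d, t_e=t_e,
                          criterion_end="table_contact"),
        true_path=PathTrace(t=t[span], xy=xy),
        true_units=cfg.n_movement_units,
        config=cfg,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# cohorts

#: per-age movement-unit pools: younger children produce more
#: sub-movements (units decrease with age over 5–10 years)
DEFAULT_UNIT_POOLS = {5: (2, 3), 6: (2, 3), 7: (2, 3),
                      8: (1, 2), 9: (1, 2), 10: (1, 2)}

#: cohort-level phase statistics the generator emulates: mean total
#: cycle 2.55 ± 0.6 s, phase split 13.33 / 43.24 / 43.43 % with SDs
#: 6.05 / 7.41 / 7.73.
DEFAULT_COHORT = {
    "total_mean_s": 2.55, "total_sd_s": 0.6,
    "pct_means": (13.33, 43.24, 43.43),
    "pct_sds": (6.05, 7.41, 7.73),
}


def synth_cohort(n_per_group: int = 8, group_params: dict | None = None,
                 seed: int = 0, ages=(5, 6, 7, 8, 9, 10)) -> list[dict]:
    """Generate a labeled cohort of trials across age groups.

    Returns one record per trial: ``{"trace", "truth", "age", "gender",
    "trial"}``.  Per-trial totals and phase splits are sampled from the
    cohort statistics in ``group_params`` (defaults above), truncated to
    keep each trial feasible, then renormalized to sum to 100%.
    """
    if n_per_group < 1:
        raise ParameterError("n_per_group must be >= 1")
    gp = dict(DEFAULT_COHORT)
    if group_params:
        gp.update(group_params)
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed)
    records = []
    for age in ages:
        pool = DEFAULT_UNIT_POOLS.get(age, (1, 2))
        for j in range(n_per_group):
            total = max(float(rng.normal(gp["total_mean_s"], gp["total_sd_s"])), 1.5)
            pct = rng.normal(gp["pct_means"], gp["pct_sds"])
            pct = np.clip(pct, [8.0, 25.0, 25.0], None)
            pct = 100.0 * pct / pct.sum()
            phases = tuple(total * pct / 100.0)
            n_units = int(rng.choice(pool))
            apex = float(np.clip(rng.normal(45.0, 8.0), 25.0, 70.0))
            child_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31))
            cfg = TrialConfig(phase_s=phases, apex_angle_deg=apex,
                              n_movement_units=n_units, seed=child_seed)
            # a sampled accommodation shorter than the onset rise delay is
            # infeasible; stretch it just past the delay (recorded truth
            # reflects the actual phases)
            _, _, delay = _onset_geometry(cfg, SegmentationParams().onset_angle_delta)
            if phases[0] <= delay + 0.03:
                cfg = TrialConfig(phase_s=(delay + 0.05, phases[1], phases[2]),
                                  apex_angle_deg=apex,
                                  n_movement_units=n_units, seed=child_seed)
            trace, truth = synth_trial(cfg)
            records.append({"trace": trace, "truth": truth, "age": age,
                            "gender": "M" if (j % 2 == 0) else "F",
                            "trial": j})
    return records


def save_cohort(records: list[dict], out_dir) -> Path:
    """Write cohort trials as canonical CSVs plus a label manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        fname = f"trial_{i:03d}.csv"
        write_trial(rec["trace"], out_dir / fname)
        rows.append({"file": fname, "age": rec["age"],
                     "gender": rec["gender"], "trial": rec["trial"]})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


# ---------------------------------------------------------------------------
# omnidirectional frames

def _band_mask(theta_deg, h_mm, bands):
    m = np.zeros(np.broadcast(theta_deg, h_mm).shape, dtype=bool)
    for (t0, width, h0, h1) in bands:
        m |= (((theta_deg - t0) % 360.0) < width) & (h_mm >= h0) & (h_mm <= h1)
    return m


def synth_omni_frame(model: MirrorModel | None = None,
                     hand_bands=DEFAULT_HAND_BANDS,
                     colors: dict | None = None,
                     noise_sigma: float = 3.0,
                     seed: int = 0,
                     shape: tuple[int, int] | None = None,
                     pano_shape: tuple[int, int] = (140, 360),
                     ) -> tuple[np.ndarray, GroundTruth]:
    """Render an omnidirectional frame with a known skin mask.

    Finger bands given in cylinder-surface coordinates are forward
    projected onto the mirror annulus over glass/background colors;
    Gaussian chroma noise of ``noise_sigma`` (CIELAB a*b* units) is
    added before conversion to sRGB.  The ground-truth skin mask is
    evaluated on the ``pano_shape`` panoramic grid of :func:`unwrap`.
    """
    model = model or MirrorModel()
    colors = {**DEFAULT_COLORS, **(colors or {})}
    for (t0, width, h0, h1) in hand_bands:
        if not (0 <= t0 < 360 and 0 < width <= 360):
            raise ParameterError(f"band azimuth ({t0}, {width}) outside [0, 360)")
        if not (model.reject_bottom_mm <= h0 < h1 <= model.cylinder_length_mm):
            raise ParameterError(
                f"band heights ({h0}, {h1}) outside the valid surface "
                f"[{model.reject_bottom_mm}, {model.cylinder_length_mm}] mm")
    rng = np.random.default_rng(seed)
    cy, cx = model.center_px
    if shape is None:
        m = int(np.ceil(2 * (model.r_outer_px + 20)))
        shape = (max(m, int(2 * cy) + 1), max(m, int(2 * cx) + 1))
    yy, xx = np.indices(shape, dtype=float)
    rr = np.hypot(yy - cy, xx - cx)
    theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
    inside = (rr >= model.r_inner_px) & (rr <= model.r_outer_px)
    h = model.height_of_radius(rr)
    skin = inside & _band_mask(theta, h, hand_bands)

    lab = np.empty(shape + (3,), dtype=float)
    lab[...] = colors["background"]
    lab[inside] = colors["glass"]
    lab[skin] = colors["skin"]
    lab[..., 1:] += rng.normal(0.0, noise_sigma, shape + (2,))
    rgb = np.clip(skcolor.lab2rgb(lab), 0.0, 1.0)
    rgb = (rgb * 255).round().astype(np.uint8)

    out_h, out_w = pano_shape
    rows = np.arange(out_h)
    cols = np.arange(out_w)
    h_p = model.reject_bottom_mm + model.band_height_mm * rows / out_h
    th_p = 360.0 * cols / out_w
    mask = _band_mask(th_p[None, :], h_p[:, None], hand_bands)
    return rgb, GroundTruth(true_skin_mask=mask, config=model)
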