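"""Movement units, straightness, path reconstruction, energy, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graspkin import (
    ImuTrace,
    LinearAccTrace,
    ParameterError,
    PathTrace,
    TaskEvents,
    TrialConfig,
    UndefinedMetricError,
    count_movement_units,
    energy_expenditure,
    reconstruct_path,
    rotation_speed,
    straightness_index,
    summarize_groups,
    synth_trial,
)
from graspkin.metrics import compute_metrics
from graspkin.synth import minjerk, minjerk_acc

RATE = 87.0


def units_oracle(speed, threshold):
    """Independent hysteresis state machine over the raw samples.

    Counts one unit per alternating swing: a running maximum followed by
    a drop greater than the threshold, re-armed by a rise greater than
    the threshold.
    """
    speed = np.asarray(speed, dtype=float)
    units = 0
    direction = +1
    ext = speed[0]
    for v in speed[1:]:
        if direction > 0:
            if v > ext:
                ext = v
            elif ext - v > threshold:
                units += 1
                direction = -1
                ext = v
        else:
            if v < ext:
                ext = v
            elif v - ext > threshold:
                direction = +1
                ext = v
    return max(units, 1)


def _profile(points, n=400):
    """Piecewise-linear speed profile through the given value sequence."""
    x = np.linspace(0, 1, len(points))
    return np.interp(np.linspace(0, 1, n), x, points)


class TestMovementUnits:
    def test_single_bell(self):
        assert count_movement_units(_profile([0, 300, 0]), 40.0) == 1

    def test_three_unit_profile(self):
        prof = _profile([0, 300, 120, 200, 60, 250, 0])
        assert count_movement_units(prof, 40.0) == 3

    def test_shallow_dip_merges(self):
        prof = _profile([0, 100, 90, 100, 0])
        assert count_movement_units(prof, 40.0) == 1

    def test_empty_profile_rejected(self):
        with pytest.raises(ParameterError):
            count_movement_units(np.array([]), 40.0)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_oracle_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        from scipy.signal import butter, filtfilt
        b, a = butter(2, 0.1)
        y = np.abs(filtfilt(b, a, np.cumsum(rng.normal(0, 30, 500))))
        thr = float(rng.uniform(5, 80))
        assert count_movement_units(y, thr) == units_oracle(y, thr)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        from scipy.signal import butter, filtfilt
        b, a = butter(2, 0.1)
        y = np.abs(filtfilt(b, a, np.cumsum(rng.normal(0, 30, 500))))
        counts = [count_movement_units(y, thr)
                  for thr in (5, 10, 20, 40, 80, 160)]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_generator_unit_count_recovered(self):
        for n_units in (1, 2, 3):
            trace, truth = synth_trial(TrialConfig(n_movement_units=n_units,
                                                   seed=11))
            te = truth.events
            speed = rotation_speed(trace)
            sel = (trace.t >= te.t_b) & (trace.t <= te.t_c)
            assert count_movement_units(speed[sel]) == n_units


class TestRotationSpeed:
    def _trace(self, angle):
        n = angle.shape[0]
        z = np.zeros((n, 3))
        euler = np.zeros((n, 3))
        euler[:, 1] = angle
        return ImuTrace(t=np.arange(n) / RATE, acc=z, gyro=z, euler=euler)

    def test_linear_ramp(self):
        t = np.arange(300) / RATE
        speed = rotation_speed(self._trace(50.0 * t))
        assert np.all(np.abs(speed - 50.0) < 0.5)

    def test_sinusoid_peak_speed(self):
        t = np.arange(500) / RATE
        f, amp = 1.0, 30.0
        speed = rotation_speed(self._trace(amp * np.sin(2 * np.pi * f * t)))
        assert speed.max() == pytest.approx(2 * np.pi * f * amp, rel=0.02)

    def test_constant_angle_zero_speed(self):
        speed = rotation_speed(self._trace(np.full(300, 12.0)))
        assert np.allclose(speed, 0.0, atol=1e-9)

    def test_too_short(self):
        with pytest.raises(ParameterError):
            rotation_speed(self._trace(np.zeros(2)))


class TestStraightness:
    def test_collinear_path_exact_one(self):
        xy = np.column_stack([np.linspace(0, 300, 50),
                              np.linspace(0, 150, 50)])
        assert straightness_index(PathTrace(t=np.arange(50.0), xy=xy)) == 1.0

    def test_semicircle(self):
        phi = np.linspace(0, np.pi, 100)
        xy = np.column_stack([np.cos(phi), np.sin(phi)]) * 100.0
        s = straightness_index(PathTrace(t=np.arange(100.0), xy=xy))
        assert s == pytest.approx(2 / np.pi, abs=1e-3)

    def test_right_angle_path(self):
        xy = np.array([[0.0, 0.0], [300.0, 0.0], [300.0, 400.0]])
        s = straightness_index(PathTrace(t=np.arange(3.0), xy=xy))
        assert s == pytest.approx(5.0 / 7.0, abs=1e-9)

    def test_zero_travel_undefined(self):
        xy = np.zeros((10, 2))
        with pytest.raises(UndefinedMetricError):
            straightness_index(PathTrace(t=np.arange(10.0), xy=xy))

    @settings(max_examples=30, derandomize=True)
    @given(angle=st.floats(-np.pi, np.pi),
           dx=st.floats(-500, 500), dy=st.floats(-500, 500),
           scale=st.floats(0.1, 10.0))
    def test_rigid_motion_and_scale_invariance(self, angle, dx, dy, scale):
        rng = np.random.default_rng(5)
        xy = np.cumsum(rng.normal(0, 10, (40, 2)), axis=0)
        s0 = straightness_index(PathTrace(t=np.arange(40.0), xy=xy))
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        xy2 = scale * (xy @ rot.T) + [dx, dy]
        s1 = straightness_index(PathTrace(t=np.arange(40.0), xy=xy2))
        assert s1 == pytest.approx(s0, rel=1e-9)


class TestPathReconstruction:
    def _events(self, t0, t1):
        return TaskEvents(t_a=t0, t_b=t0, t_c=t1, t_d=None, t_e=t1,
                          criterion_end="orientation_return")

    def test_zero_acceleration_stays_at_origin(self):
        n = 200
        lin = LinearAccTrace(t=np.arange(n) / RATE, lin_acc=np.zeros((n, 3)))
        path = reconstruct_path(lin, self._events(0.0, 2.0))
        assert np.max(np.abs(path.xy)) < 1e-9

    def test_minimum_jerk_reach_endpoint(self):
        n = 175
        t = np.arange(n) / RATE
        T = t[-1]
        d = 0.250  # 250 mm reach along x
        acc = np.zeros((n, 3))
        acc[:, 0] = d * minjerk_acc(t / T) / T**2
        lin = LinearAccTrace(t=t, lin_acc=acc)
        path = reconstruct_path(lin, self._events(0.0, T))
        endpoint = np.linalg.norm(path.xy[-1] - path.xy[0])
        assert endpoint == pytest.approx(250.0, rel=0.02)

    def test_synthetic_trial_endpoint(self):
        cfg = TrialConfig(seed=3, translation_in_acc=True,
                          noise_acc_sigma=0.0, noise_angle_sigma=0.0,
                          noise_gyro_sigma=0.0)
        from graspkin import gravity_compensate, lowpass
        trace, truth = synth_trial(cfg)
        lin = gravity_compensate(lowpass(trace, include_angles=True))
        path = reconstruct_path(lin, truth.events, phase="transport")
        endpoint = np.linalg.norm(path.xy[-1] - path.xy[0])
        assert endpoint == pytest.approx(cfg.reach_distance_mm, rel=0.05)

    def test_jittered_sampling_rejected(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.uniform(0.5, 1.5, 200)) / RATE
        lin = LinearAccTrace(t=t, lin_acc=np.zeros((200, 3)))
        with pytest.raises(ParameterError, match="resample"):
            reconstruct_path(lin, self._events(t[3], t[-3]))


class TestEnergy:
    def _lin(self, resultant, rate=RATE):
        n = resultant.shape[0]
        acc = np.column_stack([resultant, np.zeros(n), np.zeros(n)])
        return LinearAccTrace(t=np.arange(n) / rate, lin_acc=acc)

    def test_zero_acceleration(self):
        lin = self._lin(np.zeros(200))
        assert energy_expenditure(lin, (0.0, 2.0)) == 0.0

    def test_constant_resultant_closed_form(self):
        lin = LinearAccTrace(t=np.linspace(0, 2, 175),
                             lin_acc=np.column_stack(
                                 [np.ones(175), np.zeros(175), np.zeros(175)]))
        assert energy_expenditure(lin, (0.0, 2.0)) == pytest.approx(2.0,
                                                                    rel=1e-9)

    def test_additive_over_adjacent_windows(self):
        rng = np.random.default_rng(4)
        lin = self._lin(np.abs(rng.normal(0, 1, 400)))
        t_mid = lin.t[200]
        total = energy_expenditure(lin, (lin.t[0], lin.t[-1]))
        parts = (energy_expenditure(lin, (lin.t[0], t_mid))
                 + energy_expenditure(lin, (t_mid, lin.t[-1])))
        assert parts == pytest.approx(total, rel=1e-9)

    def test_amplitude_monotonicity(self):
        """Doubling the trial's impulse amplitude increases the counts."""
        from graspkin import gravity_compensate, lowpass
        values = []
        for amp in (0.5, 1.0, 2.0):
            trace, truth = synth_trial(TrialConfig(seed=8,
                                                   contact_impulse=amp))
            lin = gravity_compensate(lowpass(trace, include_angles=True))
            te = truth.events
            values.append(energy_expenditure(lin, (te.t_c, te.t_d)))
        assert values[0] < values[1] < values[2]

    def test_empty_window_rejected(self):
        lin = self._lin(np.ones(100))
        with pytest.raises(ParameterError):
            energy_expenditure(lin, (5.0, 6.0))


class TestSummaries:
    def test_single_record_zero_sd(self):
        df = pd.DataFrame({"total_s": [2.0], "age": [5]})
        table = summarize_groups(df, by=("age",))
        assert table.loc[("total_s", "mean"), 5] == 2.0
        assert table.loc[("total_s", "std"), 5] == 0.0

    def test_two_records_closed_form(self):
        df = pd.DataFrame({"total_s": [2.0, 3.0], "age": [5, 5]})
        table = summarize_groups(df, by=("age",))
        assert table.loc[("total_s", "mean"), 5] == pytest.approx(2.5)
        assert table.loc[("total_s", "std"), 5] == pytest.approx(0.7071,
                                                                 abs=1e-3)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            summarize_groups(pd.DataFrame())


class TestComputeMetrics:
    def test_full_metric_set(self, noisy_trial):
        trace, truth = noisy_trial
        km = compute_metrics(trace, truth.events)
        te = truth.events
        assert km.total_s == pytest.approx(te.t_d - te.t_a)
        assert km.movement_units == truth.true_units
        assert km.energy_transport >= 0 and km.energy_return >= 0
        assert km.v_peak >= km.v_mean > 0
        assert km.speed_channel == "rotational"
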