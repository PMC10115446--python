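"""Saccade detection, performance index, epochs, tracking bouts,
inter-saccadic gain, pre-saccadic error, and rigid-tether steering metrics."""

import numpy as np
import pytest
from scipy.special import expit

from barsaccade import kinematics, synthgen
from barsaccade.errors import InvalidArgumentError, UndefinedPIError
from barsaccade.synthgen import SynthHeadingConfig, gen_bar_trajectory, gen_heading_trace
from barsaccade.types import HeadingTrace, Saccade, SteeringTrace, TrackingBout, wrap_180

# fraction of a logistic step captured between the 25%-of-peak-velocity
# points: tanh(arccosh(2)) = sqrt(3)/2
LOGISTIC_CAPTURE = np.sqrt(3.0) / 2.0


def make_manual_trace(bar, heading_unwrapped, meta=None):
    return HeadingTrace(
        time_s=bar.time_s,
        heading_deg=np.asarray(heading_unwrapped) % 360.0,
        bar_deg=bar.angle_deg,
        meta=meta or {},
    )


def inject_saccades(t, centres, amp, peak_vel):
    k = 4.0 * peak_vel / amp
    heading = np.zeros_like(t)
    for tc in centres:
        heading = heading + amp * expit(k * (t - tc))
    dur = 2.0 * np.log(19.0) / k
    return heading, dur


class TestAngularKinematics:
    def test_constant_heading_zero_velocity(self, bar_112):
        trace = make_manual_trace(bar_112, np.full(bar_112.time_s.size, 123.0))
        kin = kinematics.angular_kinematics(trace)
        assert np.max(np.abs(kin.velocity_deg_s)) < 1e-6

    def test_ramp_recovers_rotation_speed(self, bar_112):
        trace = make_manual_trace(bar_112, 112.5 * bar_112.time_s)
        kin = kinematics.angular_kinematics(trace)
        interior = slice(100, -100)
        assert np.allclose(kin.velocity_deg_s[interior], 112.5, atol=0.1)

    def test_wrapped_sawtooth_unwraps_to_affine(self, bar_112):
        # several full rotations; bypass the low-pass filter to isolate unwrapping
        truth = 300.0 * bar_112.time_s + 17.0
        trace = make_manual_trace(bar_112, truth)
        kin = kinematics.angular_kinematics(trace, cutoff_hz=1e9)
        recovered = kin.heading_unwrapped_deg
        assert np.max(np.abs((recovered - recovered[0]) - (truth - truth[0]))) < 1e-9

    def test_too_short_trace_rejected(self):
        bar = gen_bar_trajectory(112.5, 0.3, sample_rate_hz=200.0)
        trace = make_manual_trace(bar, np.zeros(bar.time_s.size))
        with pytest.raises(InvalidArgumentError):
            kinematics.angular_kinematics(trace)


class TestDetectSaccades:
    def test_smooth_tracking_yields_no_saccades(self, bar_112):
        cfg = SynthHeadingConfig(saccade_rate_hz=0.0, smooth_gain=1.0)
        trace, _ = gen_heading_trace(bar_112, cfg, seed=0)
        assert kinematics.detect_saccades(trace) == []

    def test_injected_saccades_all_recovered(self, bar_112):
        centres = np.linspace(2.0, 23.0, 10)
        heading, dur = inject_saccades(bar_112.time_s, centres, amp=30.0, peak_vel=1000.0)
        trace = make_manual_trace(bar_112, heading)
        detected = kinematics.detect_saccades(trace)
        assert len(detected) == 10
        for s, tc in zip(detected, centres):
            # the 25%-of-peak-velocity window captures sqrt(3)/2 of a
            # logistic step; the filter smears a further few percent
            assert s.amplitude_deg == pytest.approx(30.0 * LOGISTIC_CAPTURE, rel=0.05)
            assert abs(s.onset_s - (tc - dur / 2.0)) < 0.010
            assert s.direction == "syn"

    def test_control_like_rate_recovered(self, bar_112):
        cfg = SynthHeadingConfig(saccade_rate_hz=1.0, smooth_gain=0.3)
        rates = []
        for seed in range(50):
            trace, _ = gen_heading_trace(bar_112, cfg, seed=seed)
            rates.append(len(kinematics.detect_saccades(trace)) / 25.0)
        assert np.mean(rates) == pytest.approx(1.0, abs=0.1)

    def test_precision_and_recall_at_high_snr(self, bar_112):
        # SNR = amplitude / noise SD = 30 / 3 = 10
        cfg = SynthHeadingConfig(saccade_rate_hz=1.0, smooth_gain=0.3, heading_noise_sd=3.0)
        tp = fp = fn = 0
        for seed in range(100):
            trace, truth = gen_heading_trace(bar_112, cfg, seed=seed)
            detected = kinematics.detect_saccades(trace)
            d_onsets = [s.onset_s for s in detected]
            used = set()
            for s in truth:
                hits = [
                    i
                    for i, d in enumerate(d_onsets)
                    if abs(d - s.onset_s) < 0.1 and i not in used
                ]
                if hits:
                    used.add(hits[0])
                    tp += 1
                else:
                    fn += 1
            fp += len(d_onsets) - len(used)
        assert tp / (tp + fp) >= 0.95
        assert tp / (tp + fn) >= 0.95

    def test_counter_directional_saccade_labelled(self, bar_112):
        heading, _ = inject_saccades(bar_112.time_s, [10.0], amp=-30.0, peak_vel=-1000.0)
        trace = make_manual_trace(bar_112, heading)
        (s,) = kinematics.detect_saccades(trace)
        assert s.direction == "counter"
        assert s.amplitude_deg < 0


class TestPerformanceIndex:
    def test_perfect_tracking(self, bar_112):
        trace = make_manual_trace(bar_112, bar_112.unwrapped_deg)
        assert kinematics.performance_index(trace) == pytest.approx(1.0)

    def test_stationary_fly(self, bar_112):
        trace = make_manual_trace(bar_112, np.zeros(bar_112.time_s.size))
        assert kinematics.performance_index(trace) == pytest.approx(0.0)

    def test_counter_directional_half_gain(self, bar_112):
        trace = make_manual_trace(bar_112, -0.5 * bar_112.unwrapped_deg)
        assert kinematics.performance_index(trace) == pytest.approx(-0.5)

    def test_invariant_to_full_wraps(self, bar_112):
        heading = 0.4 * bar_112.unwrapped_deg
        a = make_manual_trace(bar_112, heading)
        b = make_manual_trace(bar_112, heading + 720.0)  # extra wraps change nothing
        assert kinematics.performance_index(a) == pytest.approx(
            kinematics.performance_index(b)
        )

    def test_zero_bar_displacement_rejected(self):
        bar = gen_bar_trajectory(0.0, 5.0, 90.0)
        trace = make_manual_trace(bar, np.linspace(0, 100, bar.time_s.size))
        with pytest.raises(UndefinedPIError):
            kinematics.performance_index(trace)


class TestEpochMetrics:
    def test_25s_trial_has_five_epochs(self, bar_112):
        trace = make_manual_trace(bar_112, bar_112.unwrapped_deg)
        out = kinematics.epoch_metrics(trace, saccades=[])
        assert len(out.table) == 5

    def test_perfect_tracking_all_positive_pi(self, bar_112):
        trace = make_manual_trace(bar_112, bar_112.unwrapped_deg)
        out = kinematics.epoch_metrics(trace, saccades=[])
        assert out.positive_pi_fraction == 1.0
        assert np.allclose(out.table["pi"], 1.0)

    def test_alternating_gain_epochs_recovered(self, bar_112):
        # LED ON epochs forced to zero gain, OFF to gain 1
        t = bar_112.time_s
        gain = np.where((t // 5.0).astype(int) % 2 == 0, 1.0, 0.0)
        dt_disp = np.concatenate([[0.0], np.diff(bar_112.unwrapped_deg)])
        heading = np.cumsum(gain * dt_disp)
        trace = make_manual_trace(
            bar_112, heading, meta={"epoch_labels": ["OFF", "ON", "OFF", "ON", "OFF"]}
        )
        out = kinematics.epoch_metrics(trace, saccades=[])
        table = out.table
        assert np.allclose(table.loc[table.label == "OFF", "pi"], 1.0, atol=0.01)
        assert np.allclose(table.loc[table.label == "ON", "pi"], 0.0, atol=0.01)

    def test_ccw_trial_reflected_to_positive_displacement(self):
        bar = gen_bar_trajectory(112.5, 25.0, direction=-1)
        trace = make_manual_trace(bar, bar.unwrapped_deg, meta={"direction": -1})
        out = kinematics.epoch_metrics(trace, saccades=[])
        assert np.all(out.table["displacement_deg"] > 0)


class TestTrackingBouts:
    def test_standard_trial_tiles_into_15_windows(self, bar_112):
        # 2812.5 deg / 180 deg = 15.625 -> 15 whole windows of 1.6 s
        trace = make_manual_trace(bar_112, bar_112.unwrapped_deg)
        bouts = kinematics.tracking_bouts(trace)
        assert len(bouts) == 1
        assert bouts[0].n_windows == 15
        assert bouts[0].duration_s == pytest.approx(15 * 1.6, abs=0.02)

    def test_perfect_tracking_with_noise_merges_to_one_bout(self, bar_112, rng):
        heading = bar_112.unwrapped_deg + rng.normal(0.0, 0.5, bar_112.time_s.size)
        trace = make_manual_trace(bar_112, heading)
        bouts = kinematics.tracking_bouts(trace)
        assert len(bouts) == 1
        assert bouts[0].n_windows == 15

    def test_independent_wobble_rarely_qualifies(self, bar_112):
        cfg = SynthHeadingConfig(saccade_rate_hz=0.0, smooth_gain=0.0, heading_noise_sd=20.0)
        with_bouts = 0
        for seed in range(100):
            trace, _ = gen_heading_trace(bar_112, cfg, seed=seed)
            with_bouts += bool(kinematics.tracking_bouts(trace))
        assert with_bouts <= 5

    def test_short_trial_warns_and_returns_empty(self):
        bar = gen_bar_trajectory(112.5, 1.0)
        trace = make_manual_trace(bar, bar.unwrapped_deg)
        with pytest.warns(UserWarning):
            assert kinematics.tracking_bouts(trace) == []


class TestIntersaccadicGain:
    def test_perfect_smooth_tracking_gain_one(self, bar_112):
        trace = make_manual_trace(bar_112, bar_112.unwrapped_deg)
        bout = [TrackingBout(start_s=0.0, end_s=25.0, r_squared=1.0)]
        out = kinematics.intersaccadic_gain(trace, [], bout)
        assert out.mean == pytest.approx(1.0)
        assert out.pooled == pytest.approx(1.0)

    def test_stationary_fly_gain_zero(self, bar_112):
        trace = make_manual_trace(bar_112, np.zeros(bar_112.time_s.size))
        bout = [TrackingBout(start_s=0.0, end_s=25.0, r_squared=1.0)]
        saccades = [
            Saccade(onset_s=8.0, offset_s=8.1, amplitude_deg=0.0, peak_velocity_deg_s=0.0)
        ]
        out = kinematics.intersaccadic_gain(trace, saccades, bout)
        assert out.mean == pytest.approx(0.0)

    def test_generator_smooth_gain_recovered(self, bar_112):
        cfg = SynthHeadingConfig(saccade_rate_hz=1.0, smooth_gain=0.3)
        pooled = []
        for seed in range(10):
            trace, _ = gen_heading_trace(bar_112, cfg, seed=seed)
            saccades = kinematics.detect_saccades(trace)
            bout = [TrackingBout(start_s=0.0, end_s=25.0, r_squared=1.0)]
            pooled.append(kinematics.intersaccadic_gain(trace, saccades, bout).pooled)
        assert np.mean(pooled) == pytest.approx(0.3, abs=0.05)


class TestPreSaccadicError:
    def test_bar_at_heading_zero_error(self, bar_112):
        trace = make_manual_trace(bar_112, bar_112.unwrapped_deg)
        s = [Saccade(onset_s=5.0, offset_s=5.1, amplitude_deg=10.0, peak_velocity_deg_s=500.0)]
        err = kinematics.pre_saccadic_error(trace, s)
        assert err[0] == pytest.approx(0.0, abs=1e-9)

    def test_large_lead_wraps_to_negative(self, bar_112):
        # bar 190 deg ahead of the fly wraps to -170 deg
        trace = make_manual_trace(bar_112, bar_112.unwrapped_deg - 190.0)
        s = [Saccade(onset_s=5.0, offset_s=5.1, amplitude_deg=10.0, peak_velocity_deg_s=500.0)]
        err = kinematics.pre_saccadic_error(trace, s)
        assert err[0] == pytest.approx(-170.0, abs=1e-6)

    def test_sign_follows_bar_direction(self):
        bar = gen_bar_trajectory(112.5, 25.0, direction=-1)
        # bar leads the fly by 30 deg in its (CCW) direction of motion
        trace = make_manual_trace(bar, bar.unwrapped_deg + 30.0, meta={"direction": -1})
        s = [Saccade(onset_s=5.0, offset_s=5.1, amplitude_deg=-10.0, peak_velocity_deg_s=-500.0)]
        err = kinematics.pre_saccadic_error(trace, s)
        assert err[0] == pytest.approx(30.0, abs=1e-6)


class TestConservation:
    def test_saccadic_plus_intersaccadic_displacement_is_total(self, bar_112):
        cfg = SynthHeadingConfig(saccade_rate_hz=1.0, smooth_gain=0.3)
        trace, _ = gen_heading_trace(bar_112, cfg, seed=6)
        kin = kinematics.angular_kinematics(trace)
        saccades = kinematics.detect_saccades(trace)
        assert saccades
        h = kin.heading_unwrapped_deg
        t = kin.time_s

        def at(ts):
            return h[int(np.searchsorted(t, ts, side="left"))]

        bounds = [t[0]] + [x for s in saccades for x in (s.onset_s, s.offset_s)] + [t[-1]]
        inter = sum(at(b1) - at(b0) for b0, b1 in zip(bounds[0::2], bounds[1::2]))
        sacc = sum(s.amplitude_deg for s in saccades)
        total = h[-1] - h[0]
        assert inter + sacc == pytest.approx(total, abs=1e-6)


class TestReflectionSymmetry:
    def test_mirrored_trial_negates_signed_outputs(self, bar_112):
        cfg = SynthHeadingConfig(saccade_rate_hz=1.0, smooth_gain=0.3)
        trace, _ = gen_heading_trace(bar_112, cfg, seed=8)
        mirrored = HeadingTrace(
            time_s=trace.time_s,
            heading_deg=(-trace.heading_deg) % 360.0,
            bar_deg=(-trace.bar_deg) % 360.0,
            meta={**trace.meta, "direction": -1},
        )
        fwd = kinematics.detect_saccades(trace)
        rev = kinematics.detect_saccades(mirrored)
        assert len(fwd) == len(rev)
        for a, b in zip(fwd, rev):
            assert b.amplitude_deg == pytest.approx(-a.amplitude_deg, abs=1e-6)
            assert b.peak_velocity_deg_s == pytest.approx(-a.peak_velocity_deg_s, abs=1e-6)
            assert b.direction == a.direction
            assert b.pre_error_deg == pytest.approx(a.pre_error_deg, abs=1e-6)
        assert kinematics.performance_index(mirrored) == pytest.approx(
            kinematics.performance_index(trace)
        )


class TestRigidTetherMetrics:
    @staticmethod
    def sweep_trace(dwba):
        # bar sweeps from -90 to +90 deg over 2 s at 1 kHz, crossing the
        # midline at t = 1 s
        t = np.arange(0.0, 2.0, 0.001)
        bar = -90.0 + 90.0 * t
        return SteeringTrace(time_s=t, dwba=dwba, bar_deg=bar % 360.0)

    def test_zero_signal_zero_metrics(self):
        trace = self.sweep_trace(np.zeros(2000))
        out = kinematics.rigid_tether_metrics(trace)
        assert out.midline_mean_dwba == 0.0
        assert np.all(out.windup == 0.0)

    def test_constant_signal_mean_and_linear_windup(self):
        trace = self.sweep_trace(np.full(2000, 0.7))
        out = kinematics.rigid_tether_metrics(trace)
        assert out.midline_mean_dwba == pytest.approx(0.7)
        assert out.midline_crossing_s == pytest.approx(1.0, abs=0.002)
        # normalized wind-up of a constant signal is a linear ramp 0 -> 1
        assert out.windup[-1] == pytest.approx(1.0)
        assert np.allclose(out.windup, trace.time_s / trace.time_s[-1], atol=1e-6)
        assert out.windup_raw[-1] == pytest.approx(0.7 * 1.999, rel=1e-6)

    def test_window_mean_matches_brute_force(self, rng):
        dwba = rng.normal(0.0, 1.0, 2000)
        trace = self.sweep_trace(dwba)
        out = kinematics.rigid_tether_metrics(trace, midline_window_s=0.2)
        in_window = (trace.time_s >= out.midline_crossing_s - 0.2) & (
            trace.time_s < out.midline_crossing_s
        )
        assert int(in_window.sum()) == 200  # 200 ms at 1 kHz
        assert out.midline_mean_dwba == pytest.approx(float(dwba[in_window].mean()))

    def test_no_crossing_rejected(self):
        t = np.arange(0.0, 2.0, 0.001)
        trace = SteeringTrace(time_s=t, dwba=np.zeros(2000), bar_deg=np.full(2000, 120.0))
        with pytest.raises(InvalidArgumentError):
            kinematics.rigid_tether_metrics(trace)
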