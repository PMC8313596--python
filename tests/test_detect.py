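"""Drift correction, velocity filtering, saccade detection and trial
classification, scored against the renderer's ground truth."""

import warnings

import numpy as np
import pytest
from scipy import signal

from sacstep import (
    ClassificationConfig,
    DetectionConfig,
    NoiseModel,
    StaircaseState,
    TrialOutcome,
    build_experiment_plan,
    classify_trial_online,
    compute_velocity,
    detect_saccades,
    drift_correct,
    extract_rt,
    render_trial_trace,
    simulate_subject,
)
from sacstep.detect import DetectionError, classify_rendered_trial
from sacstep.gaze import GazeTrace, _ground_truth_dict, inject_drift, noise_free
from sacstep.task import TrialSpec

NO_STEP_OUT = TrialOutcome(
    trial=TrialSpec("no_step", 0, None, 1200.0, 0, 0),
    outcome="no_step_saccade", rt_ms=300.0)
REDIRECT_TRIAL = TrialSpec("redirect", 0, 4, 1200.0, 0, 1)
NONCOMP_OUT = TrialOutcome(trial=REDIRECT_TRIAL, outcome="noncompensated",
                           rt_ms=280.0, tsd_ms=150.0, corrective_rt_ms=520.0)
COMP_OUT = TrialOutcome(trial=REDIRECT_TRIAL, outcome="compensated",
                        rt_ms=260.0, tsd_ms=150.0)


def fixation_trace(n=240, rate=60.0, onset=1200.0):
    t = np.arange(n) * (1000.0 / rate)
    return GazeTrace(t_ms=t, x_deg=np.zeros(n), y_deg=np.zeros(n),
                     valid=np.ones(n, bool), array_onset_ms=onset)


class TestDriftCorrect:
    def test_centered_trace_unchanged(self):
        trace = fixation_trace()
        out = drift_correct(trace)
        np.testing.assert_allclose(out.x_deg, trace.x_deg, atol=1e-12)

    def test_constant_offset_removed_exactly(self, geometry, rng):
        trace = render_trial_trace(NO_STEP_OUT, geometry, noise_free(), rng)
        shifted = inject_drift(trace, (1.5, -0.5))
        corrected = drift_correct(shifted)
        np.testing.assert_allclose(corrected.x_deg, trace.x_deg, atol=1e-9)
        np.testing.assert_allclose(corrected.y_deg, trace.y_deg, atol=1e-9)

    def test_idempotent_on_offset_traces(self, geometry, rng):
        trace = inject_drift(
            render_trial_trace(NO_STEP_OUT, geometry, noise_free(), rng),
            (2.0, 1.0))
        once = drift_correct(trace)
        twice = drift_correct(once)
        np.testing.assert_allclose(twice.x_deg, once.x_deg, atol=1e-9)

    def test_noisy_offset_residual_small(self, geometry):
        residuals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = NoiseModel(fixation_sd_deg=0.15, drift_offset_deg=(1.5, -0.5),
                               blink_rate_per_trial=0.0)
            trace = render_trial_trace(NO_STEP_OUT, geometry, noise, rng)
            corrected = drift_correct(trace)
            pre = corrected.t_ms < corrected.array_onset_ms - 50
            residuals.append(np.hypot(corrected.x_deg[pre].mean(),
                                      corrected.y_deg[pre].mean()))
        assert np.mean(residuals) < 0.1

    def test_no_valid_window_returns_uncorrected(self):
        trace = fixation_trace()
        trace = GazeTrace(t_ms=trace.t_ms, x_deg=trace.x_deg + 3.0,
                          y_deg=trace.y_deg, valid=np.zeros(240, bool),
                          array_onset_ms=1200.0)
        with pytest.warns(UserWarning, match="uncorrected"):
            out = drift_correct(trace)
        np.testing.assert_array_equal(out.x_deg, trace.x_deg)


class TestComputeVelocity:
    def test_constant_position_zero_velocity(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = compute_velocity(fixation_trace())
        assert np.all(np.abs(v) < 1e-9)

    def test_linear_ramp_recovered(self):
        t = np.arange(240) * (1000.0 / 60.0)
        trace = GazeTrace(t_ms=t, x_deg=10.0 * t / 1000.0, y_deg=np.zeros(240),
                          valid=np.ones(240, bool), array_onset_ms=1000.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = compute_velocity(trace)
        interior = v[20:-20]
        assert np.all(np.abs(interior - 10.0) < 0.5)   # within 5%

    def test_cutoff_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="Nyquist"):
            compute_velocity(fixation_trace(), DetectionConfig(cutoff_hz=40.0))

    def test_matches_independent_filter_route(self, geometry, rng):
        # oracle: transfer-function (b, a) forward-backward filtering of the
        # same derivative, vs the implementation's second-order sections
        trace = render_trial_trace(NO_STEP_OUT, geometry, noise_free(), rng)
        config = DetectionConfig()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = compute_velocity(trace, config)
        t_s = trace.t_ms / 1000.0
        vx = np.gradient(trace.x_deg, t_s)
        vy = np.gradient(trace.y_deg, t_s)
        b, a = signal.butter(config.filter_order, 0.9 * 30.0, btype="low",
                             fs=60.0, output="ba")
        ref = np.hypot(signal.filtfilt(b, a, vx), signal.filtfilt(b, a, vy))
        assert v.max() == pytest.approx(ref.max(), rel=0.10)

    def test_too_short_trace_rejected(self):
        with pytest.raises(DetectionError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                compute_velocity(fixation_trace(n=10, onset=50.0))


class TestDetectSaccades:
    def _events(self, outcome, geometry, rng, noise=None):
        noise = noise or noise_free()
        trace = render_trial_trace(outcome, geometry, noise, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = compute_velocity(trace)
        return detect_saccades(v, trace), trace

    def test_fixation_trace_has_no_events(self):
        trace = fixation_trace()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = compute_velocity(trace)
        assert detect_saccades(v, trace) == []

    def test_single_saccade_onset_within_one_sample(self, geometry, rng):
        events, trace = self._events(NO_STEP_OUT, geometry, rng)
        assert len(events) == 1
        true_onset = 1200.0 + 300.0
        assert abs(events[0].onset_ms - true_onset) <= 1000.0 / 60.0

    def test_noncompensated_trial_has_two_directed_saccades(self, geometry, rng):
        events, _ = self._events(NONCOMP_OUT, geometry, rng)
        assert len(events) == 2
        # T1 at 0 deg, T2 at 180 deg on the 8-position array
        assert min(events[0].direction_deg, 360 - events[0].direction_deg) < 45
        assert abs(events[1].direction_deg - 180.0) < 45

    def test_subthreshold_noise_preserves_event_count(self, geometry):
        rng = np.random.default_rng(0)
        base_events, trace = self._events(NO_STEP_OUT, geometry, rng)
        # sd chosen so the per-sample velocity contribution stays < threshold/3
        sd = (30.0 / 3) / (2 * 60.0) * 0.5
        noisy = GazeTrace(
            t_ms=trace.t_ms,
            x_deg=trace.x_deg + rng.normal(0, sd, trace.n_samples),
            y_deg=trace.y_deg + rng.normal(0, sd, trace.n_samples),
            valid=trace.valid, array_onset_ms=trace.array_onset_ms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = compute_velocity(noisy)
        assert len(detect_saccades(v, noisy)) == len(base_events)

    def test_event_overlapping_long_dropout_is_dropped(self, geometry, rng):
        trace = render_trial_trace(NO_STEP_OUT, geometry, noise_free(), rng)
        valid = trace.valid.copy()
        onset_idx = int((1200.0 + 300.0) / (1000.0 / 60.0))
        valid[onset_idx - 5:onset_idx + 10] = False    # 250 ms dropout
        broken = GazeTrace(t_ms=trace.t_ms, x_deg=trace.x_deg,
                           y_deg=trace.y_deg, valid=valid,
                           array_onset_ms=trace.array_onset_ms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = compute_velocity(broken)
        assert detect_saccades(v, broken) == []


class TestClassifyOnline:
    def test_trace_inside_window_is_indeterminate(self, geometry):
        assert classify_trial_online(fixation_trace(), REDIRECT_TRIAL,
                                     geometry) == "indeterminate"

    def test_round_trip_labels(self, geometry, rng):
        for outcome, expected in ((COMP_OUT, "compensated"),
                                  (NONCOMP_OUT, "noncompensated")):
            trace = render_trial_trace(outcome, geometry, noise_free(), rng)
            assert classify_trial_online(trace, REDIRECT_TRIAL,
                                         geometry) == expected

    def test_excursion_before_latency_floor_ignored(self, geometry):
        trace = fixation_trace()
        x = trace.x_deg.copy()
        # 3-sample excursion ending 60 ms after array onset, back inside after
        i0 = int((1200.0 + 30.0) / (1000.0 / 60.0))
        x[i0:i0 + 2] = 5.0
        early = GazeTrace(t_ms=trace.t_ms, x_deg=x, y_deg=trace.y_deg,
                          valid=trace.valid, array_onset_ms=1200.0)
        assert classify_trial_online(early, REDIRECT_TRIAL,
                                     geometry) == "indeterminate"

    def test_non_redirect_trial_rejected(self, geometry):
        with pytest.raises(DetectionError):
            classify_trial_online(fixation_trace(), NO_STEP_OUT.trial, geometry)

    def test_off_axis_excursion_is_indeterminate(self, geometry):
        trace = fixation_trace()
        y = trace.y_deg.copy()
        i0 = int(1600.0 / (1000.0 / 60.0))
        y[i0:] = -6.0   # 270 deg: neither T1 (0) nor T2 (180)
        odd = GazeTrace(t_ms=trace.t_ms, x_deg=trace.x_deg, y_deg=y,
                        valid=trace.valid, array_onset_ms=1200.0)
        assert classify_trial_online(odd, REDIRECT_TRIAL,
                                     geometry) == "indeterminate"


class TestExtractRt:
    def _event(self, onset):
        from sacstep.detect import SaccadeEvent
        return SaccadeEvent(onset_ms=onset, offset_ms=onset + 40.0,
                            amplitude_deg=9.0, direction_deg=0.0,
                            peak_velocity_deg_s=300.0)

    def test_no_step_rt_from_array_onset(self):
        rt, excluded = extract_rt([self._event(1500.0)], NO_STEP_OUT.trial,
                                  None, "no_step_saccade", 1200.0)
        assert rt == 300.0 and not excluded

    def test_compensated_rt_from_t2_onset(self):
        rt, excluded = extract_rt([self._event(1600.0)], REDIRECT_TRIAL,
                                  150.0, "compensated", 1200.0)
        assert rt == 250.0 and not excluded

    def test_anticipation_excluded(self):
        rt, excluded = extract_rt([self._event(1280.0)], NO_STEP_OUT.trial,
                                  None, "no_step_saccade", 1200.0)
        assert rt == 80.0 and excluded

    def test_missing_events_error(self):
        with pytest.raises(DetectionError):
            extract_rt([], NO_STEP_OUT.trial, None, "no_step_saccade", 1200.0)


class TestRoundTrip:
    def _agreement(self, noise, seed, n_sessions=2):
        from sacstep import ArrayGeometry, default_race_parameters

        rng = np.random.default_rng(seed)
        geometry = ArrayGeometry()
        plan = build_experiment_plan(n_sessions, 60, (0.30, 0.40, 0.30),
                                     geometry, rng)
        params = default_race_parameters()
        ds = simulate_subject(params, plan, StaircaseState.from_ms(100.0), rng)
        n_agree = n_total = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for outcome in ds.outcomes:
                if outcome.trial.trial_type != "redirect":
                    continue
                trace = render_trial_trace(outcome, geometry, noise, rng)
                row = classify_rendered_trial(trace, _ground_truth_dict(outcome),
                                              geometry)
                n_total += 1
                n_agree += row["outcome"] == outcome.outcome
        return n_agree / n_total

    def test_noise_free_classification_is_exact(self):
        assert self._agreement(noise_free(), seed=21) == 1.0

    def test_default_noise_agreement_at_least_95_percent(self):
        assert self._agreement(NoiseModel(), seed=22) >= 0.95

    def test_rts_invariant_to_time_translation(self, geometry, rng):
        trace = render_trial_trace(NO_STEP_OUT, geometry, noise_free(), rng)
        shifted = GazeTrace(t_ms=trace.t_ms + 500.0, x_deg=trace.x_deg,
                            y_deg=trace.y_deg, valid=trace.valid,
                            array_onset_ms=trace.array_onset_ms + 500.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e0 = detect_saccades(compute_velocity(trace), trace)
            e1 = detect_saccades(compute_velocity(shifted), shifted)
        rt0, _ = extract_rt(e0, NO_STEP_OUT.trial, None, "no_step_saccade",
                            trace.array_onset_ms)
        rt1, _ = extract_rt(e1, NO_STEP_OUT.trial, None, "no_step_saccade",
                            shifted.array_onset_ms)
        assert rt0 == pytest.approx(rt1, abs=1e-9)
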