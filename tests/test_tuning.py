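"""Responsiveness, direction tuning, onset, PD regression, stability, heterogeneity."""

import numpy as np
import pandas as pd
import pytest

from obci.synth import GroundTruthROI, HandTrajectory, simulate_roi_trace
from obci.tuning import (
    circular_diff_deg,
    direction_anova,
    event_responsiveness,
    fit_velocity_regression,
    heterogeneity_test,
    stability_shuffle_test,
    tuning_onset,
)


def _point_roi(pd_deg, gain=0.02, cis=0.0):
    return GroundTruthROI(rows=[0], cols=[0], weights=[1.0],
                          shape_class="dendritic", pd_deg=pd_deg, gain=gain,
                          baseline_f0=100.0, cis_gain=cis)


from hypothesis import given, settings, strategies as st


class TestCircularDiff:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        a=st.floats(-1e4, 1e4, allow_nan=False),
        b=st.floats(-1e4, 1e4, allow_nan=False),
        phi=st.floats(-720, 720, allow_nan=False),
    )
    def test_properties_hold_for_arbitrary_angles(self, a, b, phi):
        d = float(circular_diff_deg(a, b))
        assert 0.0 <= d <= 180.0
        assert d == pytest.approx(float(circular_diff_deg(b, a)))
        assert float(circular_diff_deg(a, a)) == pytest.approx(0.0, abs=1e-9)
        # rotating both angles together leaves the difference unchanged
        assert float(circular_diff_deg(a + phi, b + phi)) == pytest.approx(d, abs=1e-6)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 360, (2, 500))
        d1, d2 = circular_diff_deg(a, b), circular_diff_deg(b, a)
        assert np.allclose(d1, d2)
        assert np.all((d1 >= 0) & (d1 <= 180))

    def test_wraparound(self):
        assert circular_diff_deg(10.0, 350.0) == pytest.approx(20.0)
        assert circular_diff_deg(0.0, 180.0) == pytest.approx(180.0)


class TestEventResponsiveness:
    def test_step_response_is_detected(self, default_behavior):
        _, trials, hand, ft = default_behavior
        rng = np.random.default_rng(0)
        trace = rng.normal(0, 0.02, ft.size)
        # add a constant offset after every movement onset
        for on in trials["movement_onset_ms"]:
            trace[(ft >= on) & (ft < on + 350)] += 1.0
        p = event_responsiveness(trace, ft, trials)
        assert p["p_move"] < 1e-10

    def test_movement_gain_roi_is_move_but_not_cue_responsive(self, default_behavior):
        _, trials, hand, ft = default_behavior
        roi = _point_roi(45.0, gain=0.02, cis=0.0)
        trace = simulate_roi_trace(roi, hand, trials, ft, noise_sd=0.02,
                                   rng=np.random.default_rng(1))
        p = event_responsiveness(trace, ft, trials)
        assert p["p_move"] < 0.01
        assert p["p_target"] > 0.01


class TestDirectionAnova:
    def test_large_effect_detected(self, default_behavior):
        _, trials, hand, ft = default_behavior
        rng = np.random.default_rng(2)
        trace = rng.normal(0, 0.001, ft.size)
        for tr in trials.itertuples():
            if tr.target_index in (1, 3):
                trace[(ft >= tr.movement_onset_ms) & (ft < tr.movement_onset_ms + 350)] += 10.0
        assert direction_anova(trace, ft, trials) < 1e-20

    def test_generator_tuned_roi_detected(self, default_behavior):
        _, trials, hand, ft = default_behavior
        detected = 0
        rng = np.random.default_rng(3)
        n_runs = 20
        for i in range(n_runs):
            roi = _point_roi(float(rng.uniform(0, 360)))
            trace = simulate_roi_trace(roi, hand, trials, ft, noise_sd=0.02, rng=rng)
            detected += direction_anova(trace, ft, trials) < 0.01
        assert detected >= 0.9 * n_runs


class TestTuningOnset:
    def test_step_tuning_onset_localized(self, default_behavior):
        _, trials, hand, ft = default_behavior
        rng = np.random.default_rng(4)
        trace = rng.normal(0, 0.05, ft.size)
        t0 = 100.0  # tuning switches on 100 ms after movement onset
        for tr in trials.itertuples():
            if tr.target_index % 2 == 0:
                m = (ft >= tr.movement_onset_ms + t0) & (ft < tr.movement_onset_ms + 500)
                trace[m] += 2.0
        onset = tuning_onset(trace, ft, trials)
        assert onset is not None
        assert t0 - 40 <= onset <= t0 + 100

    def test_identical_traces_have_no_onset(self, default_behavior):
        _, trials, hand, ft = default_behavior
        assert tuning_onset(np.ones(ft.size), ft, trials) is None


class TestVelocityRegression:
    def test_exact_vx_model_recovered(self, default_behavior):
        _, trials, hand, ft = default_behavior
        vx = np.interp(ft - 50.0, hand.timestamps_ms, hand.velocity_cmps[:, 0])
        fit = fit_velocity_regression(0.5 * vx, hand, ft, lag_ms=50.0)
        assert fit.beta_x == pytest.approx(0.5, abs=1e-10)
        assert fit.beta_y == pytest.approx(0.0, abs=1e-10)
        assert fit.pd_deg in (pytest.approx(0.0, abs=1e-6), pytest.approx(360.0, abs=1e-6))

    def test_pure_vy_model_gives_90_degrees(self, default_behavior):
        _, trials, hand, ft = default_behavior
        vy = np.interp(ft - 50.0, hand.timestamps_ms, hand.velocity_cmps[:, 1])
        fit = fit_velocity_regression(vy, hand, ft, lag_ms=50.0)
        assert fit.pd_deg == pytest.approx(90.0, abs=1e-6)

    def test_pd_estimator_rotation_equivariant(self, default_behavior):
        _, trials, hand, ft = default_behavior
        roi = _point_roi(30.0)
        trace = simulate_roi_trace(roi, hand, trials, ft, noise_sd=0.0)
        fit0 = fit_velocity_regression(trace, hand, ft)
        phi = 40.0
        R = np.array([
            [np.cos(np.deg2rad(phi)), -np.sin(np.deg2rad(phi))],
            [np.sin(np.deg2rad(phi)), np.cos(np.deg2rad(phi))],
        ])
        rot = HandTrajectory(
            timestamps_ms=hand.timestamps_ms,
            position_cm=hand.position_cm @ R.T,
            velocity_cmps=hand.velocity_cmps @ R.T,
        )
        fit1 = fit_velocity_regression(trace, rot, ft)
        assert circular_diff_deg(fit1.pd_deg, fit0.pd_deg + phi) < 1e-6

    def test_generator_pd_recovery_median_error(self, default_behavior):
        _, trials, hand, ft = default_behavior
        rng = np.random.default_rng(5)
        errs = []
        for _ in range(40):
            pd_true = float(rng.uniform(0, 360))
            roi = _point_roi(pd_true, cis=0.2)
            trace = simulate_roi_trace(roi, hand, trials, ft, noise_sd=0.02, rng=rng)
            fit = fit_velocity_regression(trace, hand, ft)
            errs.append(float(circular_diff_deg(fit.pd_deg, pd_true)))
        assert np.median(errs) < 10.0


class TestStability:
    def test_identical_halves_not_significant(self, default_behavior):
        _, trials, hand, ft = default_behavior
        roi = _point_roi(120.0)
        trace = simulate_roi_trace(roi, hand, trials, ft, noise_sd=0.02,
                                   rng=np.random.default_rng(6))
        p, dpd = stability_shuffle_test(trace, ft, trials, hand, n_shuffles=300,
                                        rng=np.random.default_rng(7))
        assert p > 0.01
        assert dpd < 30.0

    def test_pd_flip_between_halves_detected(self, default_behavior):
        # strong drift: PD flips 180 degrees and tuning deepens between halves.
        # (an exactly amplitude-matched 180-degree flip is the one degenerate
        # direction of the shuffle null: mixed-label subsets cancel and the
        # null itself concentrates near 180, so no test can resolve it)
        _, trials, hand, ft = default_behavior
        n = len(trials)
        half_t = trials.iloc[n // 2]["target_onset_ms"]
        early = simulate_roi_trace(_point_roi(0.0, gain=0.03), hand, trials, ft,
                                   noise_sd=0.005, rng=np.random.default_rng(8))
        late = simulate_roi_trace(_point_roi(180.0, gain=0.06), hand, trials, ft,
                                  noise_sd=0.005, rng=np.random.default_rng(9))
        trace = np.where(ft < half_t, early, late)
        p, dpd = stability_shuffle_test(trace, ft, trials, hand, n_shuffles=500,
                                        rng=np.random.default_rng(10))
        assert p < 0.01
        assert dpd > 150.0


class TestHeterogeneity:
    def _pixel_traces(self, hand, trials, ft, pds, noise, rng):
        return np.vstack([
            simulate_roi_trace(_point_roi(pd), hand, trials, ft,
                               noise_sd=noise, rng=rng)
            for pd in pds
        ])

    def test_homogeneous_roi_not_flagged(self, default_behavior):
        _, trials, hand, ft = default_behavior
        rng = np.random.default_rng(11)
        P = self._pixel_traces(hand, trials, ft, [75.0] * 20, 0.05, rng)
        het, k, _ = heterogeneity_test(P, hand, ft)
        assert not het

    def test_two_population_roi_flagged(self, default_behavior):
        _, trials, hand, ft = default_behavior
        rng = np.random.default_rng(12)
        P = self._pixel_traces(hand, trials, ft, [0.0] * 10 + [90.0] * 10, 0.005, rng)
        het, k, labels = heterogeneity_test(P, hand, ft)
        assert het and k >= 2

    def test_minority_split_fails_30pct_rule(self, default_behavior):
        _, trials, hand, ft = default_behavior
        rng = np.random.default_rng(13)
        P = self._pixel_traces(hand, trials, ft, [0.0] * 19 + [180.0], 0.005, rng)
        het, _, _ = heterogeneity_test(P, hand, ft)
        assert not het
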