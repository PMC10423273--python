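"""Kinematic analyses: segments, velocities, deviation detection, errors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from doublestep.kinematics import (VelocityTrace, detect_deviation_time,
                                   endpoint_error, lateral_velocity,
                                   movement_segment, movement_summary,
                                   peak_velocity_variability, reaction_time)
from doublestep.simulate import SimParams, Trial, simulate_session, simulate_trial


def _make_trial(x, onset=0.0, cue=None, dt=0.01, **kw):
    """Trial with a prescribed index x-series; y, z flat."""
    n = len(x)
    t = np.arange(n) * dt
    xyz = np.column_stack([np.asarray(x, float), np.zeros(n), np.zeros(n)])
    defaults = dict(trial_id=0, participant_id="p", experiment=1,
                    dimension="horizontal", condition="static",
                    initial_endpoint_id="right", final_endpoint_id="right",
                    t=t, index_xyz=xyz, wrist_xyz=xyz.copy(),
                    cue_on_s=cue if cue is not None else onset - 0.35,
                    movement_onset_s=onset, shift_s=None, touch_s=t[-1],
                    endpoint_touch_xy=np.array([8.0, 0.0]))
    defaults.update(kw)
    return Trial(**defaults)


class TestMovementSegment:
    def test_inclusive_bounds_sample_count(self):
        tr = _make_trial(np.zeros(101), onset=0.35, touch_s=0.98)
        assert len(movement_segment(tr)) == 64  # 10 ms steps in [0.35, 0.98]

    def test_onset_at_first_stamp(self):
        tr = _make_trial(np.zeros(20), onset=0.0)
        assert len(movement_segment(tr)) == 20

    def test_malformed_trial_raises(self):
        tr = _make_trial(np.zeros(20), onset=0.0)
        tr.touch_s = -0.1
        with pytest.raises(ValueError):
            movement_segment(tr)


class TestLateralVelocity:
    def test_linear_motion_constant_velocity(self):
        t = np.arange(100) * 0.01
        tr = _make_trial(2.0 * t, onset=0.0)
        v = lateral_velocity(tr).v_lat
        assert np.allclose(v[1:-1], 2.0)

    def test_constant_position_zero_velocity(self):
        tr = _make_trial(np.full(50, 3.0), onset=0.0)
        assert np.allclose(lateral_velocity(tr).v_lat, 0.0)

    def test_sinusoid_matches_analytic_derivative(self):
        t = np.arange(100) * 0.01
        tr = _make_trial(np.sin(2 * np.pi * t), onset=0.0)
        v = lateral_velocity(tr).v_lat
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        assert np.max(np.abs(v[1:-1] - expected[1:-1])) < 0.05

    def test_too_short_raises(self):
        tr = _make_trial(np.zeros(4), onset=0.0, touch_s=0.01)
        with pytest.raises(ValueError):
            lateral_velocity(tr)


def _traces(mat, dt_ms=10.0):
    t = np.arange(mat.shape[1]) * dt_ms
    return [VelocityTrace(t, row) for row in mat]


class TestDeviationDetection:
    def test_identical_groups_no_deviation(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(10, 60))
        res = detect_deviation_time(_traces(mat), _traces(mat.copy()))
        assert res.deviation_time_ms is None

    def test_step_difference_located(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.01, size=(20, 60))
        b = rng.normal(0, 0.01, size=(20, 60))
        b[:, 20:] += 5.0
        res = detect_deviation_time(_traces(a), _traces(b), run_length=5)
        assert res.deviation_time_ms == pytest.approx(200.0, abs=10.0)

    def test_symmetric_in_group_exchange(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(8, 40))
        b = rng.normal(0.5, 1, size=(8, 40))
        r1 = detect_deviation_time(_traces(a), _traces(b), run_length=3)
        r2 = detect_deviation_time(_traces(b), _traces(a), run_length=3)
        assert r1.deviation_time_ms == r2.deviation_time_ms
        assert np.allclose(r1.p_values, r2.p_values)

    def test_uncorrected_sagittal_shifts_show_no_deviation(self, layout):
        # late depth perturbations go uncorrected, so near/far trajectories
        # never statistically separate
        params = SimParams.for_experiment(2)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = [simulate_trial(layout, params, "sagittal", "shifted", "near", "near-",
                                rng, experiment=2) for _ in range(30)]
            b = [simulate_trial(layout, params, "sagittal", "shifted", "near", "near+",
                                rng, experiment=2) for _ in range(30)]
            res = detect_deviation_time([lateral_velocity(t, axis="y") for t in a],
                                        [lateral_velocity(t, axis="y") for t in b])
            hits += res.deviation_time_ms is not None
        assert hits <= 1


class TestEndpointError:
    def test_three_four_five(self):
        assert endpoint_error([3, 4], [0, 0]) == pytest.approx(5.0)

    def test_identity(self):
        assert endpoint_error([1.2, -0.7], [1.2, -0.7]) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=6))
    def test_triangle_inequality(self, vals):
        a, b, m = vals[0:2], vals[2:4], vals[4:6]
        assert endpoint_error(a, b) <= endpoint_error(a, m) + endpoint_error(m, b) + 1e-9

    def test_uncorrected_error_exceeds_corrected(self, layout):
        params = SimParams.for_experiment(2, rng_seed=7)
        rng = np.random.default_rng(7)
        uncorr = [simulate_trial(layout, params, "sagittal", "shifted", "near", "near+",
                                 rng, experiment=2) for _ in range(20)]
        corr = [simulate_trial(layout, params, "horizontal", "shifted", "left", "left+",
                               rng, experiment=2) for _ in range(20)]
        err_u = np.mean([endpoint_error(t.endpoint_touch_xy, layout.position("near+"))
                         for t in uncorr])
        err_c = np.mean([endpoint_error(t.endpoint_touch_xy, layout.position("left+"))
                         for t in corr])
        assert err_u > err_c


class TestReactionTime:
    def test_subtraction(self):
        tr = _make_trial(np.zeros(250), onset=1.85, cue=1.5)
        assert reaction_time(tr) == pytest.approx(350.0)

    def test_onset_before_cue_raises(self):
        tr = _make_trial(np.zeros(50), onset=0.1, cue=0.2)
        with pytest.raises(ValueError):
            reaction_time(tr)

    def test_session_mean_matches_params(self, session_exp1):
        rts = [reaction_time(t) for t in session_exp1.trials]
        sem = np.std(rts, ddof=1) / np.sqrt(len(rts))
        assert abs(np.mean(rts) - 350.0) < 3 * sem + 5.0  # +5 ms grid snap


class TestVariabilityAndSummary:
    def test_identical_trials_zero_sd(self):
        t = np.arange(80) * 0.01
        tr = _make_trial(np.sin(t) * 5, onset=0.0)
        assert peak_velocity_variability([tr, tr], "x") == 0.0

    def test_two_point_sample_sd(self):
        from doublestep.simulate import minimum_jerk
        a = _make_trial(minimum_jerk([0.0], [2.0], 0.8, 81)[:, 0], onset=0.0)
        b = _make_trial(minimum_jerk([0.0], [6.0], 0.8, 81)[:, 0], onset=0.0)
        # peak speed at midpoint, where x is 1 and 3: sample sd sqrt(2)
        assert peak_velocity_variability([a, b], "x") == pytest.approx(np.sqrt(2), rel=0.01)

    def test_static_variability_bounded_by_endpoint_sd(self):
        params = SimParams.for_experiment(1, rng_seed=13, position_noise_sd_cm=0.0)
        sess = simulate_session(params, n_static=40, n_shifted=4)
        trials = sess.select(condition="static", final_endpoint_id="right")
        assert peak_velocity_variability(trials, "x") < params.endpoint_sd_cm

    def test_movement_summary_conditions(self, session_exp1):
        out = movement_summary(session_exp1)
        assert set(out) == {"static", "shifted"}
        assert len(out["static"]["durations_s"]) == 60
        assert out["static"]["mean_speeds_cm_s"].min() > 0


class TestLatencyRecoveryHelper:
    def test_recovers_injected_latency(self):
        from doublestep.kinematics import latency_recovery
        dev = latency_recovery(200.0, n_per_group=120, seed=3)
        assert dev is not None
        assert abs(dev - 200.0) <= 45.0  # loose unit-level bound; tight one in acceptance
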