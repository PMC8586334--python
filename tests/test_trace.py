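import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_min_cost, make_piecewise_trace
from unwindkit.errors import EmptyResultError, InputError, OverfitWarning
from unwindkit.trace import (
    AnalysisConfig,
    BeadTrajectory,
    UnwindingTrace,
    analyze_condition,
    calibrate_force_variance,
    default_penalty,
    detect_events,
    fragment_velocity_fit,
    segment_constant_velocity,
    summarize_velocity,
    survival_probability,
)


def make_trace(y, dt=1.0):
    y = np.asarray(y, dtype=float)
    return UnwindingTrace(time_s=np.arange(y.size) * dt, unwound_bp=y)


class TestBeadTrajectory:
    def test_nonuniform_time_rejected(self):
        t = np.array([0.0, 1.0, 2.5, 3.0])
        with pytest.raises(InputError):
            BeadTrajectory(time_s=t, extension_nm=np.zeros(4))

    def test_decreasing_time_rejected(self):
        t = np.array([0.0, 2.0, 1.0])
        with pytest.raises(InputError):
            BeadTrajectory(time_s=t, extension_nm=np.zeros(3))

    def test_nonfinite_extension_rejected(self):
        with pytest.raises(InputError):
            BeadTrajectory(time_s=np.arange(3.0),
                           extension_nm=np.array([0.0, np.nan, 1.0]))


class TestFragmentFit:
    def test_unit_slope(self):
        t = make_trace([0.0, 1.0, 2.0])
        v, b, rss = fragment_velocity_fit(t, 0, 3)
        assert v == pytest.approx(1.0)
        assert rss == pytest.approx(0.0, abs=1e-12)

    def test_slope_two(self):
        t = make_trace([0.0, 2.0, 4.0])
        v, _, _ = fragment_velocity_fit(t, 0, 3)
        assert v == pytest.approx(2.0)

    def test_hand_computed_ols(self):
        # points (0,0),(1,1),(2,0): slope 0, intercept 1/3, rss 2/3
        t = make_trace([0.0, 1.0, 0.0])
        v, b, rss = fragment_velocity_fit(t, 0, 3)
        assert v == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(1.0 / 3.0)
        assert rss == pytest.approx(2.0 / 3.0)

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            fragment_velocity_fit(make_trace([0.0, 1.0, 2.0]), 0, 1)


class TestSegmentation:
    def test_single_line(self):
        t = np.arange(100) * 1.0
        trace = UnwindingTrace(time_s=t, unwound_bp=2.0 * t)
        frags = segment_constant_velocity(trace, penalty=1.0)
        assert len(frags) == 1
        assert frags[0].velocity_bp_per_s == pytest.approx(2.0)
        assert (frags[0].i_start, frags[0].i_end) == (0, 100)

    def test_constant_trace(self):
        frags = segment_constant_velocity(make_trace(np.ones(50)), penalty=1.0)
        assert len(frags) == 1
        assert frags[0].velocity_bp_per_s == pytest.approx(0.0, abs=1e-12)

    def test_two_slopes_noiseless(self):
        # v = 0 until t = 5 s, then v = 10
        t = np.arange(0, 15, 0.1)
        y = np.where(t < 5, 0.0, 10.0 * (t - 5))
        trace = UnwindingTrace(time_s=t, unwound_bp=y)
        frags = segment_constant_velocity(trace, penalty=0.5)
        assert len(frags) == 2
        assert frags[0].velocity_bp_per_s == pytest.approx(0.0, abs=1e-9)
        assert frags[1].velocity_bp_per_s == pytest.approx(10.0, rel=1e-6)
        # breakpoint lands at the slope change (t=5 -> index 50, +-1)
        assert abs(frags[1].i_start - 50) <= 1

    def test_matches_brute_force_small(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            trace, _ = make_piecewise_trace(rng, n=int(rng.integers(20, 60)))
            penalty = 40.0
            frags = segment_constant_velocity(trace, penalty)
            dp_cost = sum(f.rss for f in frags) + penalty * (len(frags) - 1)
            bf = brute_force_min_cost(trace, penalty)
            assert dp_cost == pytest.approx(bf, rel=0, abs=1e-9 * max(1, bf))

    def test_partition_covers_input(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            trace, _ = make_piecewise_trace(rng)
            frags = segment_constant_velocity(trace, penalty=10.0)
            bounds = [(f.i_start, f.i_end) for f in frags]
            assert bounds[0][0] == 0
            assert bounds[-1][1] == len(trace)
            for (a0, a1), (b0, b1) in zip(bounds[:-1], bounds[1:]):
                assert a1 == b0
            assert all(b - a >= 3 for a, b in bounds)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            segment_constant_velocity(make_trace([0.0, 1.0, 2.0]), penalty=1.0)

    def test_zero_penalty_warns(self):
        trace = make_trace(np.arange(12.0))
        with pytest.warns(OverfitWarning):
            segment_constant_velocity(trace, penalty=0.0)

    def test_negative_penalty_rejected(self):
        with pytest.raises(InputError):
            segment_constant_velocity(make_trace(np.arange(12.0)), penalty=-1.0)

    def test_default_penalty_positive(self):
        rng = np.random.default_rng(0)
        trace = make_trace(rng.normal(0, 1, 100))
        assert default_penalty(trace) > 0


class TestSummarizeVelocity:
    def _frags(self, velocities, length=10):
        from unwindkit.trace import VelocityFragment

        return [
            VelocityFragment(i * length, (i + 1) * length, v, 0.0, 0.0)
            for i, v in enumerate(velocities)
        ]

    def test_equal_velocities(self):
        mean, sem, n = summarize_velocity(self._frags([10.0, 10.0, 10.0]))
        assert (mean, sem, n) == (10.0, 0.0, 3)

    def test_hand_computed_sem(self):
        mean, sem, n = summarize_velocity(self._frags([30.0, 40.0, 50.0]))
        assert mean == pytest.approx(40.0)
        assert sem == pytest.approx(10.0 / np.sqrt(3.0))

    def test_pause_excluded_single_survivor(self):
        mean, sem, n = summarize_velocity(
            self._frags([0.0, 40.0]), pause_threshold_bp_per_s=5.0
        )
        assert mean == pytest.approx(40.0)
        assert n == 1
        assert sem is None

    def test_all_paused_raises(self):
        with pytest.raises(EmptyResultError):
            summarize_velocity(self._frags([1.0, -2.0]),
                               pause_threshold_bp_per_s=5.0)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            summarize_velocity([])

    def test_duration_weighting(self):
        from unwindkit.trace import VelocityFragment

        frags = [
            VelocityFragment(0, 10, 10.0, 0.0, 0.0),   # weight 10
            VelocityFragment(10, 40, 40.0, 0.0, 0.0),  # weight 30
        ]
        mean, _, _ = summarize_velocity(frags, weight_by_duration=True)
        assert mean == pytest.approx((10 * 10 + 40 * 30) / 40)


class TestDetectEvents:
    def test_monotone_rise(self):
        y = np.linspace(0, 2300, 300)
        events = detect_events(make_trace(y, dt=0.1), min_processivity_bp=100)
        assert len(events) == 1
        assert events[0].processivity_bp == pytest.approx(2300, rel=0.02)

    def test_two_separated_rises(self):
        # 500 bp rise, drop, 1000 bp rise
        y = np.concatenate([
            np.linspace(0, 500, 100),
            np.linspace(500, 100, 60),
            np.linspace(100, 1100, 200),
        ])
        events = detect_events(make_trace(y, dt=0.1), min_processivity_bp=100)
        assert len(events) == 2
        assert events[0].processivity_bp == pytest.approx(500, rel=0.05)
        assert events[1].processivity_bp == pytest.approx(1000, rel=0.05)
        assert events[0].t_end_s <= events[1].t_start_s

    def test_flat_trace_no_events(self):
        assert detect_events(make_trace(np.zeros(100))) == []

    def test_small_wiggles_merged(self):
        # a long rise broken by sub-threshold dips is one event
        rng = np.random.default_rng(3)
        t = np.arange(0, 60, 1 / 30)
        y = 40.0 * t + rng.normal(0, 30, t.size)
        events = detect_events(
            UnwindingTrace(time_s=t, unwound_bp=y), min_processivity_bp=100
        )
        assert len(events) == 1
        assert events[0].processivity_bp == pytest.approx(2400, rel=0.1)

    def test_invalid_threshold(self):
        with pytest.raises(InputError):
            detect_events(make_trace(np.zeros(10)), min_processivity_bp=0)

    def test_empty_trace(self):
        with pytest.raises(InputError):
            detect_events(make_trace([]))


class TestSurvival:
    def test_single_value(self):
        x, s = survival_probability([5.0])
        assert np.interp(4.9, x, s, left=1.0) == 1.0  # S below min is 1
        assert s[-1] == 0.0

    def test_exceedance_counting(self):
        x, s = survival_probability([1.0, 2.0, 3.0, 4.0])
        # S(2.5) = 0.5: two of four values exceed 2.5
        idx = np.searchsorted(x, 2.5, side="right") - 1
        assert s[idx] == 0.5

    def test_non_increasing_right_continuous(self):
        rng = np.random.default_rng(0)
        vals = rng.exponential(100, 50)
        x, s = survival_probability(vals)
        assert np.all(np.diff(s) < 0)
        assert s[0] == pytest.approx(1 - 1 / 50)
        assert s[-1] == 0.0

    def test_integral_equals_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.exponential(500, 200)
        x, s = survival_probability(vals)
        # integral of the right-continuous step function over [0, max]
        x_full = np.concatenate([[0.0], x])
        s_full = np.concatenate([[1.0], s])
        integral = float(np.sum(s_full[:-1] * np.diff(x_full)))
        assert integral == pytest.approx(vals.mean(), rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            survival_probability([])

    @given(st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=1,
                    max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_survival_bounds_property(self, values):
        x, s = survival_probability(values)
        assert np.all((s >= 0) & (s <= 1))
        assert np.all(np.diff(s) <= 0)
        assert s[-1] == 0.0


class TestForceCalibration:
    def test_closed_form(self):
        x = np.zeros(200)
        x[::2] = np.sqrt(1645.6)  # constructed to a known sample variance
        var_target = 1645.6
        x = np.random.default_rng(0).normal(0, 1, 200)
        x = (x - x.mean()) / x.std(ddof=1) * np.sqrt(var_target)
        force = calibrate_force_variance(x, tether_length_nm=2000.0,
                                         kBT_pN_nm=4.114)
        assert force == pytest.approx(4.114 * 2000 / 1645.6, rel=1e-9)
        assert force == pytest.approx(5.0, abs=0.01)

    def test_doubling_variance_halves_force(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 10, 500)
        f1 = calibrate_force_variance(x, 1000.0)
        f2 = calibrate_force_variance(x * np.sqrt(2), 1000.0)
        assert f2 == pytest.approx(f1 / 2, rel=1e-9)

    def test_monte_carlo_recovery(self):
        from unwindkit.simulate import simulate_transverse_fluctuations

        kBT, L, F = 4.114, 2000.0, 5.0
        x = simulate_transverse_fluctuations(F, L, kBT, n=10_000, seed=11)
        est = calibrate_force_variance(x, L, kBT)
        assert abs(est - F) / F < 0.05

    def test_errors(self):
        with pytest.raises(InputError):
            calibrate_force_variance(np.zeros(50), 1000.0)  # too short
        with pytest.raises(InputError):
            calibrate_force_variance(np.zeros(200), 1000.0)  # zero variance
        with pytest.raises(InputError):
            calibrate_force_variance(np.random.default_rng(0).normal(size=200),
                                     -5.0)


class TestAnalyzeCondition:
    def test_single_linear_trace(self):
        t = np.arange(0, 30, 1 / 30.0)
        trace = UnwindingTrace(time_s=t, unwound_bp=44.0 * t)
        cfg = AnalysisConfig(penalty=1e6, censored_event_margin_s=0.0)
        s = analyze_condition([trace], cfg)
        assert s.n_fragments == 1
        assert s.sem_velocity is None
        assert s.mean_velocity_bp_per_s == pytest.approx(44.0, rel=1e-6)
        assert s.n_events == 1

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            analyze_condition([], AnalysisConfig())

    def test_parameter_recovery_small(self):
        # 8 traces for speed; the full 25-trace version is in acceptance
        from unwindkit.simulate import SimConfig, simulate_condition
        from unwindkit.tether import extension_to_unwound_bp

        cfg = SimConfig(seed=2, n_traces=8, duration_s=160,
                        pause_entry_per_s=0.0, reinitiation_per_s=0.0)
        pairs = simulate_condition(cfg)
        traces = [
            extension_to_unwound_bp(traj, cfg.polymer, truth.baseline_nm)
            for traj, truth in pairs
        ]
        s = analyze_condition(traces, AnalysisConfig())
        assert abs(s.mean_velocity_bp_per_s - 44.0) < 3 * s.sem_velocity
        truth_mean = np.mean(
            [p for _, tr in pairs for p in tr.event_processivities_bp]
        )
        assert abs(s.mean_processivity_bp - truth_mean) < 3 * s.sem_processivity
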