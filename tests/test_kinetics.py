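import numpy as np
import pytest
from scipy import stats as sstats

from stip.kinetics import (KineticsConfig, compute_profile, delta_vs_control,
                           divergence_onset, group_mean_curve, intra_cv,
                           logphase_slope, normalize_to_t0, plateau_window,
                           pointwise_tests, smooth_ma3, sustained_duration,
                           trapezoid_auc)
from stip.plate_io import ConfluenceTrace
from stip.reference import COHORT

HOURS = np.arange(0.0, 49.0)


def trace(values, times=None, well="A1"):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values), dtype=float) if times is None else times
    return ConfluenceTrace(well, t, values)


class TestNormalizeAndSmooth:
    @pytest.mark.parametrize("values,expected", [
        ([30, 30, 30], [0, 0, 0]),
        ([10, 15, 40], [0, 5, 30]),
        ([10, 8, 40], [0, 0, 30]),        # clipped at 0 from below
    ])
    def test_baseline_subtraction(self, values, expected):
        assert np.allclose(normalize_to_t0(trace(values)).values, expected)

    @pytest.mark.parametrize("values,expected", [
        ([5, 5, 5, 5], [5, 5, 5, 5]),
        ([0, 3, 6, 9], [1.5, 3, 6, 7.5]),
    ])
    def test_moving_average_window_rule(self, values, expected):
        assert np.allclose(smooth_ma3(trace(values)).values, expected)

    def test_smoothing_needs_three_points(self):
        with pytest.raises(ValueError):
            smooth_ma3(trace([1, 2]))

    def test_smoothing_contracts_white_noise_variance(self, rng):
        reduced = 0
        for _ in range(1000):
            v = np.clip(50 + rng.normal(0, 3, size=30), 0, 100)
            out = smooth_ma3(trace(v)).values
            reduced += out.var() < v.var()
        assert reduced >= 990


class TestGroupMean:
    def test_constant_replicates(self):
        t, mean, sd = group_mean_curve([trace([50, 50]), trace([50, 50]),
                                        trace([50, 50])])
        assert np.allclose(mean, 50) and np.allclose(sd, 0)

    def test_sample_sd_uses_n_minus_1(self):
        _, mean, sd = group_mean_curve([trace([48, 48]), trace([50, 50]),
                                        trace([52, 52])])
        assert np.allclose(mean, 50) and np.allclose(sd, 2.0)

    def test_matches_bruteforce_loop(self, rng):
        reps = [trace(np.clip(rng.normal(40, 5, 20), 0, 100)) for _ in range(3)]
        _, mean, sd = group_mean_curve(reps)
        for j in range(20):
            col = [r.values[j] for r in reps]
            m = sum(col) / 3
            s = (sum((x - m) ** 2 for x in col) / 2) ** 0.5
            assert mean[j] == pytest.approx(m)
            assert sd[j] == pytest.approx(s)

    def test_mismatched_grids_rejected(self):
        a = trace([1, 2, 3])
        b = ConfluenceTrace("A2", [0, 2, 4], [1, 2, 3])
        with pytest.raises(Exception, match="grid"):
            group_mean_curve([a, b])


class TestDeltaVsControl:
    @pytest.mark.parametrize("treated,control,dp,dr", [
        (63.2, 29.1, 34.1, 1.172),      # strongest stimulated line
        (52.6, 35.9, 16.7, 0.465),
        (40.0, 40.0, 0.0, 0.0),
    ])
    def test_examples(self, treated, control, dp, dr):
        got_dp, got_dr = delta_vs_control(treated, control)
        assert got_dp == pytest.approx(dp, abs=1e-9)
        assert got_dr == pytest.approx(dr, abs=5e-4)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            delta_vs_control(50.0, 0.0)

    def test_reference_cohort_reconstruction(self):
        """Reconstructed controls are positive; relative deltas separate the
        active lines (|Δrel| >= 0.20) from the neutral ones (< 0.10)."""
        for line, (cat, final, delta, *_rest) in COHORT.items():
            control = final - delta
            assert control > 0
            _, dr = delta_vs_control(final, control)
            if cat == "neutral":
                assert abs(dr) < 0.10
            else:
                assert abs(dr) >= 0.20


class TestPointwiseTests:
    def test_identical_replicates_give_p_one(self):
        a = np.array([[50.0, 60.0]] * 3)
        ps = pointwise_tests(a, a.copy(), np.array([0.0, 1.0]))
        assert np.allclose(ps.p_values, 1.0)
        assert ps.n_significant == 0

    def test_welch_closed_form(self):
        """Three vs three replicates with unit spacing: t = 30/sqrt(2/3),
        df = 4 by Welch-Satterthwaite with equal variances."""
        a = np.array([[60.0], [61.0], [62.0]])
        b = np.array([[30.0], [31.0], [32.0]])
        ps = pointwise_tests(a, b, np.array([0.0]))
        t_expected = 30.0 / np.sqrt(2.0 / 3.0)
        p_expected = 2 * sstats.t.sf(t_expected, df=4)
        assert ps.p_values[0] == pytest.approx(p_expected, rel=1e-6)
        assert ps.p_values[0] < 1e-3

    def test_fewer_than_two_reps_rejected(self):
        with pytest.raises(Exception):
            pointwise_tests(np.array([[1.0]]), np.array([[1.0], [2.0]]),
                            np.array([0.0]))


class TestDivergence:
    cfg = KineticsConfig()

    def test_identical_curves_no_onset_zero_duration(self):
        t = HOURS
        c = 40 * np.ones_like(t)
        ps = _ps(np.ones_like(t))
        assert divergence_onset(t, c, c, ps, self.cfg) is None
        assert sustained_duration(t, c, c, ps, self.cfg) == 0.0

    def test_step_divergence_detected_at_step(self):
        t = HOURS
        c = 20 * np.ones_like(t)
        tr = c.copy()
        tr[10:] = 30.0                      # +50% from t=10
        p = np.ones_like(t)
        p[10:] = 0.001
        ps = _ps(p)
        assert divergence_onset(t, tr, c, ps, self.cfg) == 10.0

    def test_onset_matches_bruteforce_rule_on_logistic_boost(self, rng):
        """Growth-rate boost from t=10: the detected onset agrees with a
        literal scan of the onset rule and falls in [10, 14]."""
        t = HOURS
        K, r, tm = 50.0, 0.3, 12.0
        control = K / (1 + np.exp(-r * (t - tm)))
        boosted = K / (1 + np.exp(-2 * r * (t - tm)))
        treatedc = np.where(t < 10, control, boosted)
        # tiny replicate noise for the tests
        reps_t = np.vstack([treatedc + rng.normal(0, .05, t.size) for _ in range(3)])
        reps_c = np.vstack([control + rng.normal(0, .05, t.size) for _ in range(3)])
        ps = pointwise_tests(reps_t, reps_c, t)
        got = divergence_onset(t, treatedc, control, ps, self.cfg)
        # brute-force re-scan of the rule
        rel = (treatedc - control) / np.maximum(np.abs(control), self.cfg.rel_floor)
        ok = (np.abs(rel) >= self.cfg.onset_rel) & (ps.p_values < self.cfg.alpha)
        expected = None
        for i in range(len(t)):
            if all(ok[i:i + self.cfg.onset_run]) and i + self.cfg.onset_run <= len(t):
                expected = t[i]
                break
        assert got == expected
        assert 10.0 <= got <= 14.0

    def test_duration_counts_longest_qualifying_run(self):
        t = HOURS
        c = 30 * np.ones_like(t)
        tr = c.copy()
        tr[15:43] = 40.0                    # 28 qualifying hourly points
        p = np.where((t >= 15) & (t < 43), 0.001, 1.0)
        assert sustained_duration(t, tr, c, _ps(p), self.cfg) == 28.0

    def test_alternating_points_give_single_hour(self):
        t = HOURS
        c = 30 * np.ones_like(t)
        tr = c.copy()
        tr[1::2] = 40.0
        p = np.where(t % 2 == 1, 0.001, 1.0)
        assert sustained_duration(t, tr, c, _ps(p), self.cfg) == 1.0


class TestSlopeAucPlateau:
    cfg = KineticsConfig()

    @pytest.mark.parametrize("slope", [1.0, -2.5])
    def test_exact_line_recovers_slope(self, slope):
        t = HOURS
        v = 50 + slope * (t - 24)
        assert logphase_slope(t, v, self.cfg) == pytest.approx(slope)

    def test_logistic_peak_slope_near_kr_over_4(self):
        K, r = 60.0, 0.2
        t = HOURS
        v = K / (1 + np.exp(-r * (t - 24)))
        got = logphase_slope(t, v, self.cfg)
        assert got == pytest.approx(K * r / 4, rel=0.10)

    def test_window_longer_than_curve_rejected(self):
        with pytest.raises(ValueError):
            logphase_slope(np.arange(3.0), np.arange(3.0), self.cfg)

    @pytest.mark.parametrize("values,times,expected", [
        (50 * np.ones(49), HOURS, 2400.0),
        (np.linspace(0, 48, 49), HOURS, 1152.0),
    ])
    def test_trapezoid_basics(self, values, times, expected):
        assert trapezoid_auc(times, values) == pytest.approx(expected)

    def test_trapezoid_matches_fine_grid_for_logistic(self):
        K, r, tm = 55.0, 0.25, 20.0

        def f(t):
            return K / (1 + np.exp(-r * (t - tm)))

        hourly = trapezoid_auc(HOURS, f(HOURS))
        fine_t = np.arange(0, 48.0001, 0.01)
        fine = np.trapezoid(f(fine_t), fine_t)
        assert abs(hourly - fine) / fine < 0.005

    def test_plateau_flat_tail_from_38(self):
        t = HOURS
        v = np.clip(40.0 + 2.0 * (t - 38.0), 0.0, 40.0)   # ramp, flat from 38
        assert plateau_window(t, v, self.cfg) == (38.0, 48.0)

    def test_plateau_absent_on_strict_ramp(self):
        assert plateau_window(HOURS, 1.0 * HOURS, self.cfg) is None

    def test_constant_curve_is_full_span_plateau(self):
        assert plateau_window(HOURS, 30 * np.ones(49), self.cfg) == (0.0, 48.0)


class TestIntraCv:
    @pytest.mark.parametrize("finals,expected", [
        ([50, 50, 50], 0.0),
        ([48, 50, 52], 4.0),
    ])
    def test_examples(self, finals, expected):
        assert intra_cv(finals) == pytest.approx(expected)

    def test_recovers_generative_cv(self, rng):
        target = 5.0
        draws = 50 * np.exp(rng.normal(0, target / 100, size=1000))
        assert intra_cv(draws) == pytest.approx(target, rel=0.15)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            intra_cv([0.0, 0.0])


class TestComputeProfile:
    def test_metrics_invariant_to_replicate_order(self, rng):
        t = HOURS
        base = 40 / (1 + np.exp(-0.25 * (t - 18)))
        treated = [trace(np.clip(base * 1.5 + rng.normal(0, 1, t.size), 0, 100),
                         t, f"A{i}") for i in (1, 2, 3)]
        control = [trace(np.clip(base + rng.normal(0, 1, t.size), 0, 100),
                         t, f"A{i}") for i in (4, 5, 6)]
        p1, _ = compute_profile(treated, control, cell_line="X")
        p2, _ = compute_profile(treated[::-1], control[::-1], cell_line="X")
        import dataclasses
        for k, v in dataclasses.asdict(p1).items():
            w = getattr(p2, k)
            if isinstance(v, float):
                assert w == pytest.approx(v, abs=1e-9), k
            else:
                assert w == v, k


def _ps(p_values):
    t = np.arange(len(p_values), dtype=float)
    from stip.kinetics import PointwiseStats
    return PointwiseStats(times=t, p_values=np.asarray(p_values, float))
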