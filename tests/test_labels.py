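"""Score normalization, LTLF/ITI label builders and test sensitivity."""

import numpy as np
import pytest

import fieldfatigue as ff
from fieldfatigue.config import ProtocolConfig
from fieldfatigue.labels import TestSeries as ScoreSeries
from fieldfatigue.labels import (
    build_iti,
    build_ltlf,
    normalize_scores,
    sensitivity_r2,
)
from fieldfatigue.synth import (
    DEFAULT_TEST_DEFS,
    FatigueTrajectory,
    default_test_schedule,
    synth_test_scores,
)


def ols_line(t, y):
    """Closed-form simple least squares."""
    slope = np.cov(t, y, ddof=1)[0, 1] / np.var(t, ddof=1)
    return slope, y.mean() - slope * t.mean()


class TestNormalize:
    def test_endpoints_and_midpoint(self):
        assert np.allclose(normalize_scores([40.0, 35.0, 30.0]), [1.0, 0.5, 0.0])

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            normalize_scores([5.0, 5.0, 5.0])

    def test_output_spans_unit_interval(self):
        rng = np.random.default_rng(0)
        y = normalize_scores(rng.normal(size=20))
        assert y.min() == 0.0 and y.max() == 1.0


class TestLabelBuilders:
    def _series(self, t, s):
        return ScoreSeries("ftt_dominant", np.asarray(t, float), np.asarray(s, float))

    def test_ltlf_noiseless_line_recovered_exactly(self):
        t = np.array([0.0, 100.0, 200.0, 300.0])
        s = 60.0 - 0.05 * t
        label = build_ltlf(self._series(t, s), 300.0, rate_hz=10.0)
        grid = np.arange(label.values.size) / 10.0
        assert np.allclose(label.values, 1.0 - grid / 300.0, atol=1e-9)

    def test_ltlf_matches_closed_form_ols(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 1000, 12))
        s = 50 - 0.01 * t + rng.normal(0, 1, 12)
        label = build_ltlf(self._series(t, s), 1000.0, rate_hz=1.0)
        y = normalize_scores(s)
        slope, intercept = ols_line(t, y)
        grid = np.arange(label.values.size)
        assert np.allclose(label.values, np.clip(intercept + slope * grid, 0, 1), atol=1e-9)

    def test_iti_passes_through_every_observation(self):
        t = np.array([10.0, 20.0, 40.0, 50.0])
        s = np.array([40.0, 38.0, 31.0, 30.0])
        label = build_iti(self._series(t, s), 60.0, rate_hz=10.0)
        norm = normalize_scores(s)
        for ti, ni in zip(t, norm):
            assert label.values[int(ti * 10)] == pytest.approx(ni, abs=1e-12)

    def test_iti_midpoint_interpolation(self):
        t = np.array([0.0, 10.0, 20.0])
        s = np.array([1.0, 0.8, 0.6])  # normalized: 1, 0.5, 0
        label = build_iti(self._series(t, s), 20.0, rate_hz=1.0)
        assert label.values[5] == pytest.approx(0.75)
        assert label.values[15] == pytest.approx(0.25)

    def test_iti_equals_ltlf_for_collinear_observations(self):
        t = np.array([0.0, 25.0, 50.0, 75.0, 100.0])
        s = 10.0 - 0.04 * t
        iti = build_iti(self._series(t, s), 100.0, rate_hz=5.0)
        ltlf = build_ltlf(self._series(t, s), 100.0, rate_hz=5.0)
        assert np.allclose(iti.values, ltlf.values, atol=1e-9)

    def test_builders_return_bounded_full_length_series(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 500, 8))
        s = rng.normal(size=8)
        for build in (build_ltlf, build_iti):
            label = build(self._series(t, s), 500.0, rate_hz=250.0)
            assert label.values.size == 500 * 250
            assert label.values.min() >= 0.0 and label.values.max() <= 1.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            ScoreSeries("x", [1.0], [2.0])


class TestSensitivity:
    def test_noiseless_linear_gives_unity(self):
        t = np.arange(10.0)
        series = ScoreSeries("jump_height", t, 40 - 2 * t)
        assert sensitivity_r2(series) == pytest.approx(1.0)

    def test_time_independent_scores_near_zero(self):
        rng = np.random.default_rng(2)
        t = np.arange(400.0)
        series = ScoreSeries("pvsat", t, rng.normal(size=400))
        assert sensitivity_r2(series) < 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        t = np.arange(15.0)
        s = 5 - 0.3 * t + rng.normal(0, 0.5, 15)
        base = sensitivity_r2(ScoreSeries("a", t, s))
        scaled = sensitivity_r2(ScoreSeries("a", 7 + 3 * t, -2 * s + 11))
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_phase_subsets(self):
        t = np.arange(8.0)
        phases = np.array(["post_physical", "post_cognitive"] * 4, dtype=object)
        series = ScoreSeries("a", t, 10 - t, phases=phases)
        assert sensitivity_r2(series, "post_physical") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            sensitivity_r2(ScoreSeries("a", t[:4], t[:4], phases=phases[:4]),
                           "post_physical")

    def test_outlier_removal_restores_correlation(self):
        t = np.arange(12.0)
        s = 30 - t
        s[5] += 40.0  # one gross outlier
        series = ScoreSeries("stroop", t, s)
        with_out = sensitivity_r2(series)
        without = sensitivity_r2(series, remove_outliers=True)
        assert without > with_out
        assert without > 0.95

    def test_battery_ranking_matches_field_pattern(self):
        """Jump and dominant-hand FTT rank above PVSAT in >=95% of replicates."""
        cfg = ProtocolConfig(n_laps=11, seed=0)
        schedule = default_test_schedule(cfg)
        traj = FatigueTrajectory.linear(schedule[-1][0] + 1.0, 0.0, 0.6)
        wins = 0
        for rep in range(200):
            table = synth_test_scores(traj, schedule, rng=rep)
            r2 = {
                name: sensitivity_r2(ScoreSeries.from_table(table, name))
                for name in ("jump_height", "ftt_dominant", "pvsat")
            }
            wins += r2["jump_height"] > r2["pvsat"] and r2["ftt_dominant"] > r2["pvsat"]
        assert wins >= 190

    def test_ftt_sensitivity_recovers_analytic_target(self):
        """Mean recovered R2 over replicates sits near its analytic value."""
        cfg = ProtocolConfig(n_laps=11, seed=0)
        schedule = default_test_schedule(cfg)
        traj = FatigueTrajectory.linear(schedule[-1][0] + 1.0, 0.0, 0.6)
        d = DEFAULT_TEST_DEFS["ftt_dominant"]
        f = traj(np.array([t for t, _ in schedule]))
        var_sig = d.slope_per_f**2 * np.var(f)
        target = var_sig / (var_sig + d.noise_sd**2)
        vals = []
        for rep in range(100):
            table = synth_test_scores(traj, schedule, rng=1000 + rep)
            vals.append(sensitivity_r2(ScoreSeries.from_table(table, "ftt_dominant")))
        assert abs(np.mean(vals) - target) <= 0.15
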