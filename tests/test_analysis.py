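"""Classifier, cobweb, bifurcation and sweep tests."""

import numpy as np
import pytest

from neuroca.activation import ActivationParams
from neuroca.analysis import (
    REPRESENTATIVE_PARAMS,
    InsufficientDataError,
    bifurcation_scan,
    classify_run,
    cobweb,
    correlation_length,
    critical_fraction,
    linear_grid,
    nonlinear_grid,
    phase_sweep,
    steady_onset,
)
from neuroca.lattice import LatticeConfig, RunResult, run


def _synthetic_result(series, snapshot=None, t_snap=10):
    series = np.asarray(series, dtype=float)
    snaps = {} if snapshot is None else {t_snap: snapshot}
    return RunResult(
        mean_activity=series,
        snapshots=snaps,
        steady_state=float(series[-10:].mean()),
        cfg=LatticeConfig(timesteps=len(series) - 1),
        params=ActivationParams.linear(0.2, 0.6, 0.8),
    )


class TestClassifier:
    def test_all_zero_series_is_fast_quiescent(self):
        assert classify_run(_synthetic_result(np.zeros(101))) == "0a"

    def test_slow_decay_is_0b(self):
        series = 0.5 * 0.8 ** np.arange(101)  # drops below 1e-4 at t ~ 38
        assert classify_run(_synthetic_result(series)) == "0b"

    def test_alternating_tail_is_oscillatory(self):
        series = np.full(101, 0.3)
        series[-10:] = [0.2, 0.4] * 5
        assert classify_run(_synthetic_result(series)) == "2"

    def test_random_snapshot_is_1a_coherent_is_1b(self):
        rng = np.random.default_rng(0)
        series = np.full(101, 0.4)
        noise = rng.uniform(0, 0.8, (64, 64))
        assert classify_run(_synthetic_result(series, noise)) == "1a"
        x = np.linspace(0, 2 * np.pi, 64)
        wave = 0.4 + 0.4 * np.sin(x)[:, None] * np.ones(64)[None, :]
        assert classify_run(_synthetic_result(series, wave)) == "1b"

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            classify_run(_synthetic_result(np.zeros(15)))

    def test_oscillatory_lattice_run(self):
        """The canonical negatively-sloped rule yields a period-2 lattice
        mean (the oscillatory class) on a toroidal patch."""
        cfg = LatticeConfig(rows=64, cols=64, seed=1)
        res = run(cfg, ActivationParams.linear(0.6, 0.0, 0.6))
        assert classify_run(res) == "2"

    def test_correlation_length_orders(self):
        rng = np.random.default_rng(1)
        short = correlation_length(rng.uniform(0, 1, (64, 64)))
        x = np.linspace(0, 2 * np.pi, 64)
        long = correlation_length(np.sin(x)[:, None] * np.cos(x)[None, :])
        assert short < 3 < long


class TestCobweb:
    def test_quiescent_map_reaches_zero_from_anywhere(self):
        p = ActivationParams.linear(0.8, 0.9, 0.3)
        for start in (0.1, 0.5, 0.85):
            assert cobweb(p, start).terminal[0] == "zero"

    def test_neutral_two_cycle(self):
        """f(a) = 0.6 - a: every non-fixed start lies on a neutral 2-cycle."""
        p = ActivationParams.linear(0.6, 0.0, 0.6)
        kind, values = cobweb(p, 0.2).terminal
        assert kind == "cycle"
        assert sorted(np.round(values, 9)) == [0.2, 0.4]

    def test_fixed_point_of_negative_slope_map(self):
        p = ActivationParams.linear(0.6, 0.0, 0.6)
        kind, values = cobweb(p, 0.3).terminal
        assert kind == "fixed_point"
        assert values[0] == pytest.approx(0.3)

    def test_start_on_identity_crossing_stays(self):
        # f(a) = a2*(a-a0)/(a1-a0) crosses a_out=a_in at 0.25 for these values
        p = ActivationParams.linear(0.1, 0.7, 1.0)
        x = 0.1 / (1.0 - 0.6 / 1.0) / 1.0  # solve 1.0*(x-0.1)/0.6 = x
        kind, values = cobweb(p, x).terminal
        assert kind == "fixed_point"
        assert values[0] == pytest.approx(x)

    def test_trace_equals_plain_iteration(self):
        """The cobweb geometry is presentation only: its iterates are the
        orbit x_{k+1} = f(x_k)."""
        from neuroca.activation import evaluate

        p = ActivationParams.linear(0.1, 0.5, 0.9)
        t = cobweb(p, 0.37, n_iter=50)
        x = 0.37
        for k in range(50):
            x = evaluate(x, p)
            assert t.iterates[k + 1] == pytest.approx(x, abs=1e-15)
        # alternating vertical/horizontal segments: 2 points per iteration
        assert t.points.shape == (2 * 50 + 1, 2)


class TestBifurcation:
    CFG = LatticeConfig(rows=48, cols=48)

    def test_zero_saturation_gives_zero_branch(self):
        res = bifurcation_scan(0.6, 0.0, [0.0], self.CFG)
        assert np.all(np.concatenate(res.steady_values) == 0.0)

    def test_period_doubling_on_negative_slope_sweep(self):
        res = bifurcation_scan(0.6, 0.0, np.linspace(0.1, 0.9, 9), self.CFG)
        branches = [res.n_branches(i, decimals=2) for i in range(9)]
        assert max(branches) >= 2

    def test_no_doubling_without_thresholds(self):
        res = bifurcation_scan(0.0, 0.0, np.linspace(0.1, 0.9, 9), self.CFG)
        assert all(res.n_branches(i, decimals=2) == 1 for i in range(9))


class TestSweeps:
    def test_phase_sweep_totality(self):
        """Every grid point receives exactly one of the five labels."""
        cfg = LatticeConfig(rows=32, cols=32)
        grid = linear_grid(0.25)
        table = phase_sweep(grid, cfg, seeds=(0, 1))
        assert len(table) == 125
        assert set(table["class"]) <= {"0a", "0b", "1a", "1b", "2"}

    def test_nonlinear_low_b_quiescent(self):
        cfg = LatticeConfig(rows=32, cols=32)
        table = phase_sweep(
            nonlinear_grid([0.2, 0.5], [0.3, 0.9], [0.5]), cfg, seeds=(0,)
        )
        assert set(table["class"]) <= {"0a", "0b"}

    def test_nonlinear_extreme_cases_quiescent(self):
        cfg = LatticeConfig(rows=32, cols=32)
        table = phase_sweep(
            nonlinear_grid([1.0], [0.5], [2.0]) + nonlinear_grid([0.3], [0.0], [2.0]),
            cfg, seeds=(0,),
        )
        assert set(table["class"]) <= {"0a", "0b"}


class TestCriticalFraction:
    CFG = LatticeConfig(rows=48, cols=48)

    def test_fully_active_start_survives_for_all_pass_rule(self):
        # full drive only survives when the rule passes a_in = 1; band-pass
        # rules (a1 < 1) zero out a saturated lattice in one step
        p = ActivationParams.linear(0.0, 1.0, 1.0)
        assert critical_fraction(p, self.CFG, [1.0], seeds=(0,)) == 1.0

    def test_fully_active_start_dies_for_band_pass_rule(self):
        p = REPRESENTATIVE_PARAMS["1a"]  # active window [0.1, 0.4]
        assert critical_fraction(p, self.CFG, [1.0], seeds=(0,)) is None

    def test_empty_start_dies_with_threshold(self):
        p = ActivationParams.linear(0.2, 0.6, 0.8)
        assert critical_fraction(p, self.CFG, [0.0], seeds=(0,)) is None


class TestSteadyOnset:
    def test_constant_series_settles_immediately(self):
        assert steady_onset(np.full(50, 0.3)) == 0

    def test_late_transient_detected(self):
        s = np.concatenate([np.linspace(1.0, 0.3, 30), np.full(30, 0.3)])
        assert 25 <= steady_onset(s) <= 30

    def test_period_two_envelope(self):
        s = np.tile([0.2, 0.4], 30)
        assert steady_onset(s, period=2) == 0
        assert steady_onset(s, period=1) is None
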