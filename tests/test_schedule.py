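"""Unpaired-probability curves and LR schedules: closed forms, solver, limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abcurriculum.schedule import (
    ScheduleSpec, LRScheduleSpec, unpaired_probability, mean_unpaired_fraction,
    solve_shift, learning_rate, InfeasibleTargetError, curve_table,
)


def quadrature_mean(A, B, k, shift, n=1_000_000):
    """Midpoint-rule Riemann sum of P(t) over [0, 1] — the independent oracle."""
    t = (np.arange(n) + 0.5) / n
    return float(np.mean(B - A / (1.0 + np.exp(-k * (t - shift)))))


class TestCurveValues:
    def test_sigmoid_midpoint(self):
        spec = ScheduleSpec(kind="curriculum", A=0.4, B=0.7, k=15.0,
                            shift=0.5, total_steps=1000)
        assert unpaired_probability(spec, 500) == pytest.approx(0.7 - 0.2)

    def test_constant_curve(self):
        spec = ScheduleSpec(kind="constant", target_mean=0.625, total_steps=10)
        assert all(unpaired_probability(spec, s) == 0.625 for s in range(11))

    def test_solved_curriculum_initial_value(self):
        # with the default 62.5% mixture the curve starts just under B=0.7
        spec = ScheduleSpec(kind="curriculum", A=0.4, B=0.7, k=15.0,
                            total_steps=1000, target_mean=0.625)
        p0 = unpaired_probability(spec, 0)
        assert 0.69 < p0 <= 0.7
        direct = 0.7 - 0.4 / (1 + math.exp(-15 * (0 - spec.shift)))
        assert p0 == pytest.approx(direct)

    def test_finetune_step_function(self):
        spec = ScheduleSpec(kind="finetune", target_mean=0.625, total_steps=1000)
        assert unpaired_probability(spec, 0) == 1.0
        assert unpaired_probability(spec, 624) == 1.0
        assert unpaired_probability(spec, 625) == 0.0

    def test_step_out_of_range(self):
        spec = ScheduleSpec(kind="constant", target_mean=0.5, total_steps=10)
        with pytest.raises(ValueError):
            unpaired_probability(spec, 11)
        with pytest.raises(ValueError):
            unpaired_probability(spec, -1)

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            ScheduleSpec(kind="curriculum", A=float("nan"), B=0.7, shift=0.5)


class TestMean:
    def test_degenerate_curriculum_mean_is_B(self):
        spec = ScheduleSpec(kind="curriculum", A=0.0, B=0.7, k=15.0, shift=0.5)
        assert mean_unpaired_fraction(spec) == pytest.approx(0.7)

    def test_finetune_mean_is_switch_fraction(self):
        spec = ScheduleSpec(kind="finetune", target_mean=0.625)
        assert mean_unpaired_fraction(spec) == pytest.approx(0.625)

    def test_closed_form_matches_quadrature(self):
        spec = ScheduleSpec(kind="curriculum", A=0.4, B=0.7, k=15.0, shift=0.5)
        assert mean_unpaired_fraction(spec) == pytest.approx(
            quadrature_mean(0.4, 0.7, 15.0, 0.5), abs=1e-8)

    def test_closed_form_vs_quadrature_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            A = rng.uniform(0.05, 1.0)
            B = rng.uniform(A, 1.0)
            k = rng.uniform(1.0, 50.0)
            shift = rng.uniform(0.0, 1.0)
            spec = ScheduleSpec(kind="curriculum", A=A, B=B, k=k, shift=shift)
            assert abs(mean_unpaired_fraction(spec)
                       - quadrature_mean(A, B, k, shift, n=100_000)) <= 1e-8


class TestSolveShift:
    def test_round_trip_at_half(self):
        target = quadrature_mean(0.4, 0.7, 15.0, 0.5)
        assert solve_shift(0.4, 0.7, 15.0, target) == pytest.approx(0.5, abs=1e-6)

    def test_unattainable_mean_raises(self):
        with pytest.raises(InfeasibleTargetError):
            solve_shift(0.4, 0.7, 15.0, 0.7)

    def test_full_range_curve(self):
        shift = solve_shift(1.0, 1.0, 15.0, 0.625)
        assert quadrature_mean(1.0, 1.0, 15.0, shift) == pytest.approx(
            0.625, abs=1e-6)

    @given(st.floats(0.1, 0.9), st.floats(2.0, 40.0), st.floats(0.1, 0.9))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_round_trip_property(self, A, k, frac):
        B = min(1.0, A + 0.2)
        lo = mean_unpaired_fraction(
            ScheduleSpec(kind="curriculum", A=A, B=B, k=k, shift=-4.0))
        hi = mean_unpaired_fraction(
            ScheduleSpec(kind="curriculum", A=A, B=B, k=k, shift=5.0))
        target = lo + frac * (hi - lo)
        shift = solve_shift(A, B, k, target)
        spec = ScheduleSpec(kind="curriculum", A=A, B=B, k=k, shift=shift)
        assert abs(mean_unpaired_fraction(spec) - target) <= 1e-9


class TestMonotonicity:
    def test_p_non_increasing_every_kind(self):
        specs = [
            ScheduleSpec(kind="curriculum", A=0.4, B=0.7, k=15.0, total_steps=200),
            ScheduleSpec(kind="constant", target_mean=0.625, total_steps=200),
            ScheduleSpec(kind="finetune", target_mean=0.625, total_steps=200),
        ]
        for spec in specs:
            vals = [unpaired_probability(spec, s) for s in range(201)]
            assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_mean_increasing_in_shift(self):
        shifts = np.linspace(-1, 2, 40)
        means = [mean_unpaired_fraction(
            ScheduleSpec(kind="curriculum", A=0.4, B=0.7, k=15.0, shift=s))
            for s in shifts]
        assert all(b > a for a, b in zip(means, means[1:]))


class TestFamilyLimits:
    def test_constant_is_A_zero_limit(self):
        curric = ScheduleSpec(kind="curriculum", A=0.0, B=0.625, k=15.0,
                              shift=0.5, total_steps=100)
        const = ScheduleSpec(kind="constant", target_mean=0.625, total_steps=100)
        for s in range(0, 101, 10):
            assert unpaired_probability(curric, s) == pytest.approx(
                unpaired_probability(const, s))

    def test_finetune_is_steep_curriculum_limit(self):
        ft = ScheduleSpec(kind="finetune", target_mean=0.625, total_steps=1000)
        steep = ScheduleSpec(kind="curriculum", A=1.0, B=1.0, k=1e4,
                             shift=0.625, total_steps=1000)
        for s in [0, 100, 200, 300, 400, 500, 600, 700, 800, 1000]:
            assert abs(unpaired_probability(ft, s)
                       - unpaired_probability(steep, s)) <= 1e-3


class TestLearningRate:
    def test_warmup_reaches_peak(self):
        spec = LRScheduleSpec(kind="linear", peak_lr=4e-4,
                              warmup_steps=6000, total_steps=100_000)
        assert learning_rate(spec, 0) == 0.0
        assert learning_rate(spec, 6000) == pytest.approx(4e-4)

    def test_linear_decays_to_zero(self):
        spec = LRScheduleSpec(kind="linear", peak_lr=4e-4,
                              warmup_steps=6000, total_steps=100_000)
        assert learning_rate(spec, 100_000) == 0.0
        assert learning_rate(spec, 53_000) == pytest.approx(
            4e-4 * (100_000 - 53_000) / 94_000)

    def test_wsd_stable_phase(self):
        spec = LRScheduleSpec(kind="wsd", peak_lr=1e-3, warmup_steps=100,
                              total_steps=1000, stable_fraction=0.8)
        for s in (100, 400, 820):    # stable through warmup + 80% of the rest
            assert learning_rate(spec, s) == pytest.approx(1e-3)
        assert learning_rate(spec, 1000) == pytest.approx(0.0)

    def test_sgdr_restarts_to_peak(self):
        spec = LRScheduleSpec(kind="sgdr", peak_lr=1e-3, warmup_steps=0,
                              total_steps=1000, n_restarts=2)
        assert learning_rate(spec, 0) == pytest.approx(1e-3)
        # decays within a period, then jumps back to the peak at the restart
        assert learning_rate(spec, 499) < 1e-4
        assert learning_rate(spec, 500) == pytest.approx(1e-3)
        assert learning_rate(spec, 499) == pytest.approx(
            1e-3 * 0.5 * (1 + np.cos(np.pi * 499 / 500)), abs=1e-9)


def test_curve_table_columns():
    spec = ScheduleSpec(kind="constant", target_mean=0.625, total_steps=100)
    lr = LRScheduleSpec(kind="linear", peak_lr=1e-3, warmup_steps=10,
                        total_steps=100)
    table = curve_table(spec, lr, n_points=11)
    assert table.shape == (11, 4)
    assert np.all(table[:, 2] == 0.625)
    assert table[0, 3] == 0.0 and table[-1, 3] == 0.0
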