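"""Forward-model machinery: schedules, corrections, compartments, averaging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ammoflow as af
from ammoflow.kinetics import (
    ContinuousCurve,
    FrameSchedule,
    KineticParams,
    delayed_exp_metabolite_factor,
    frame_average_matrix,
    linear_metabolite_factor,
)


class TestFrameSchedule:
    def test_clinical_schedule_shape(self, schedule):
        assert schedule.n_frames == 21
        assert schedule.end_time == pytest.approx(180.0)
        # after 15 frames of 5 s the 15-s frames begin
        assert schedule.starts[15] == pytest.approx(75.0)
        assert schedule.durations[15] == pytest.approx(15.0)
        assert schedule.durations[-1] == pytest.approx(30.0)

    def test_rejects_gap_and_nonpositive_duration(self):
        with pytest.raises(ValueError, match="contiguous"):
            FrameSchedule(starts=[0.0, 6.0], durations=[5.0, 5.0])
        with pytest.raises(ValueError, match="positive"):
            FrameSchedule(starts=[0.0, 5.0], durations=[5.0, 0.0])


class TestMetaboliteCorrections:
    def test_linear_factor_examples(self):
        assert linear_metabolite_factor(2.0, 0.0) == pytest.approx(1.0)
        assert linear_metabolite_factor(2.0, 0.1) == pytest.approx(0.8)
        # clamped at zero beyond t = 1/m_corr, never negative
        assert linear_metabolite_factor(3.0, 0.5) == 0.0

    def test_linear_rejects_negative_slope(self, grid):
        curve = ContinuousCurve(grid, np.ones_like(grid))
        with pytest.raises(ValueError):
            af.metabolite_correct_linear(curve, -0.1)

    def test_delayed_exp_factor_examples(self):
        assert delayed_exp_metabolite_factor(0.2, 0.48, 6.69) == pytest.approx(1.0)
        assert delayed_exp_metabolite_factor(0.48, 0.48, 6.69) == pytest.approx(1.0)
        # one half-life past the onset the factor is exactly 1/2
        assert delayed_exp_metabolite_factor(0.48 + 6.69, 0.48, 6.69) == pytest.approx(0.5)

    def test_delayed_exp_continuous_at_onset(self):
        eps = 1e-9
        below = delayed_exp_metabolite_factor(0.48 - eps, 0.48, 6.69)
        above = delayed_exp_metabolite_factor(0.48 + eps, 0.48, 6.69)
        assert below == pytest.approx(above, abs=1e-8)

    def test_delayed_exp_rejects_bad_half_life(self, grid):
        curve = ContinuousCurve(grid, np.ones_like(grid))
        with pytest.raises(ValueError):
            af.metabolite_correct_delayed_exp(curve, half_life=0.0)

    @given(
        m=st.floats(0.0, 5.0),
        t0=st.floats(0.0, 2.0),
        hl=st.floats(0.1, 20.0),
        t=st.floats(0.0, 10.0),
    )
    def test_factors_lie_in_unit_interval(self, m, t0, hl, t):
        assert 0.0 <= linear_metabolite_factor(t, m) <= 1.0
        assert 0.0 <= delayed_exp_metabolite_factor(t, t0, hl) <= 1.0


class TestUclaConstraints:
    def test_k2_is_k1_over_vnd(self):
        k2, _ = af.ucla_rate_constraints(1.0, 0.8)
        assert k2 == pytest.approx(1.25)

    def test_k3_direct_evaluation(self):
        # independent numeric evaluation of the adopted expression
        expected = 1.0 / (1.65 * np.exp(1.25) - 1.0)
        _, k3 = af.ucla_rate_constraints(1.0)
        assert k3 == pytest.approx(expected, rel=1e-12)
        assert k3 == pytest.approx(0.2102, abs=5e-4)

    def test_k3_limit_and_monotonicity(self):
        assert af.ucla_rate_constraints(0.0)[1] == 0.0
        grid = np.linspace(1e-4, 10.0, 4000)
        k3 = np.array([af.ucla_rate_constraints(k)[1] for k in grid])
        assert np.all(np.diff(k3) > 0)
        assert k3[0] < 1e-3  # continuous approach to the K1 -> 0 limit

    def test_rejects_negative_k1(self):
        with pytest.raises(ValueError):
            af.ucla_rate_constraints(-0.5)


def _constant_cp(value=10.0, t_end=3.0):
    t = af.uniform_grid(t_end)
    return ContinuousCurve(t, np.full_like(t, value))


class TestSolveTissue:
    def test_zero_uptake_gives_zero_curves(self, input_curves):
        clv, _ = input_curves
        sol = af.solve_tissue("hutchins", KineticParams(k1=0.0, k2=1.0, k3=0.2), clv)
        assert np.all(sol.c1.values == 0)
        assert np.all(sol.c2.values == 0)

    def test_one_tissue_constant_input_closed_form(self):
        cp = _constant_cp(10.0)
        k1, k2 = 1.7, 0.9
        sol = af.solve_tissue("1tcm", KineticParams(k1=k1, k2=k2), cp)
        expected = (k1 * 10.0 / k2) * (1.0 - np.exp(-k2 * cp.times))
        assert np.allclose(sol.c1.values, expected, rtol=1e-6)

    def test_two_tissue_with_zero_k3_reduces_to_one_tissue(self, input_curves):
        clv, _ = input_curves
        p2 = KineticParams(k1=1.4, k2=0.7, k3=0.0)
        p1 = KineticParams(k1=1.4, k2=0.7)
        two = af.solve_tissue("hutchins", p2, clv)
        one = af.solve_tissue("1tcm", p1, clv)
        assert np.allclose(two.c1.values, one.c1.values, atol=1e-12)
        assert np.all(two.c2.values == 0)

    def test_trapped_compartment_is_nondecreasing(self, input_curves):
        clv, _ = input_curves
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = KineticParams(
                k1=rng.uniform(0.1, 5),
                k2=rng.uniform(0.0, 5),
                k3=rng.uniform(0.01, 3),
            )
            sol = af.solve_tissue("hutchins", p, clv)
            assert np.all(np.diff(sol.c2.values) >= -1e-12)

    def test_forward_curves_scale_linearly_with_input(self, input_curves):
        clv, crv = input_curves
        p = KineticParams(k1=2.0, k2=1.0, k3=0.1, v_lv=0.3, v_rv=0.1)
        def model(clv_c, crv_c):
            tissue = af.solve_tissue("hutchins", p, clv_c).total
            return af.compose_model_tac(tissue, clv_c, crv_c, p.v_lv, p.v_rv).values
        base = model(clv, crv)
        doubled = model(clv.with_values(2 * clv.values), crv.with_values(2 * crv.values))
        assert np.allclose(doubled, 2 * base, rtol=1e-12)

    def test_agrees_with_independent_ode_integrator(self, input_curves):
        from scipy.integrate import solve_ivp

        clv, _ = input_curves
        rng = np.random.default_rng(42)
        for _ in range(10):
            k1 = rng.uniform(0.1, 5)
            k2 = rng.uniform(0.05, 5)
            k3 = rng.uniform(0.0, 2)
            sol = af.solve_tissue("hutchins", KineticParams(k1=k1, k2=k2, k3=k3), clv)

            def rhs(t, y):
                c = np.interp(t, clv.times, clv.values)
                return [k1 * c - (k2 + k3) * y[0], k3 * y[0]]

            ode = solve_ivp(rhs, (0, clv.times[-1]), [0, 0], t_eval=clv.times,
                            method="LSODA", rtol=1e-10, atol=1e-12, max_step=1 / 240)
            scale = max(np.max(np.abs(ode.y)), 1e-12)
            err = np.max(np.abs(np.vstack([sol.c1.values, sol.c2.values]) - ode.y))
            assert err / scale < 1e-4


class TestCompose:
    def test_no_spillover_returns_tissue(self, input_curves):
        clv, crv = input_curves
        tissue = clv.with_values(np.linspace(0, 5, clv.times.size))
        out = af.compose_model_tac(tissue, clv, crv, 0.0, 0.0)
        assert np.array_equal(out.values, tissue.values)

    def test_constant_curve_arithmetic(self, grid):
        mk = lambda c: ContinuousCurve(grid, np.full_like(grid, c))
        out = af.compose_model_tac(mk(1.0), mk(2.0), mk(4.0), 0.3, 0.2)
        assert np.allclose(out.values, 1.9)

    def test_rejects_excessive_spillover(self, grid):
        c = ContinuousCurve(grid, np.ones_like(grid))
        with pytest.raises(ValueError):
            af.compose_model_tac(c, c, c, 0.6, 0.5)

    @given(v_lv=st.floats(0.0, 0.45), v_rv=st.floats(0.0, 0.45), seed=st.integers(0, 100))
    def test_output_within_pointwise_envelope(self, v_lv, v_rv, seed):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 50)
        curves = [ContinuousCurve(t, rng.uniform(0, 10, t.size)) for _ in range(3)]
        out = af.compose_model_tac(curves[0], curves[1], curves[2], v_lv, v_rv)
        stacked = np.vstack([c.values for c in curves])
        assert np.all(out.values >= stacked.min(axis=0) - 1e-12)
        assert np.all(out.values <= stacked.max(axis=0) + 1e-12)


class TestFrameAverage:
    def test_constant_curve(self, grid, schedule):
        curve = ContinuousCurve(grid, np.full_like(grid, 7.3))
        tac = af.frame_average(curve, schedule)
        assert np.allclose(tac.values, 7.3)

    def test_linear_curve_exact_midpoint(self, grid, schedule):
        a = 2.5
        tac = af.frame_average(ContinuousCurve(grid, a * grid), schedule)
        mids = schedule.mid_minutes
        assert np.allclose(tac.values, a * mids, rtol=1e-12)

    def test_conservation_of_integral(self, input_curves, schedule):
        clv, _ = input_curves
        tac = af.frame_average(clv, schedule)
        per_frame = np.sum(tac.values * schedule.duration_minutes)
        total = np.trapezoid(clv.values, clv.times)
        assert per_frame == pytest.approx(total, rel=1e-6)

    def test_rejects_schedule_beyond_support(self, schedule):
        short = ContinuousCurve(np.linspace(0, 1.0, 100), np.ones(100))
        with pytest.raises(ValueError):
            af.frame_average(short, schedule)

    def test_matrix_exact_with_unaligned_boundaries(self):
        # frame boundaries falling strictly between grid nodes
        t = np.linspace(0.0, 1.0, 11)
        sched = FrameSchedule(starts=[0.0, 19.0], durations=[19.0, 41.0])
        W = frame_average_matrix(t, sched)
        vals = 3.0 * t + 1.0
        mids = (sched.starts + 0.5 * sched.durations) / 60.0
        assert np.allclose(W @ vals, 3.0 * mids + 1.0, rtol=1e-12)
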