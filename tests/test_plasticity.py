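"""Tests for the two-trace dopaminergic learning rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from flexsim import (
    TraceParams,
    TracePair,
    apply_weight_update,
    dopamine_hebbian_update,
    dopamine_reinforcement,
    fixed_point_residual,
    hebbian_activity,
    step_traces,
)


class TestDopamineReinforcement:
    def test_neutral_band(self):
        assert dopamine_reinforcement(5.0, 5.0, 1.0) == 0.0
        assert dopamine_reinforcement(5.9, 5.0, 1.0) == 0.0
        assert dopamine_reinforcement(4.1, 5.0, 1.0) == 0.0

    def test_piecewise_linear_branches(self):
        r0, theta = 5.0, 1.0
        assert dopamine_reinforcement(r0 + theta, r0, theta) == 0.0
        assert dopamine_reinforcement(r0 + theta + 2.0, r0, theta) == pytest.approx(2.0)
        assert dopamine_reinforcement(r0 - theta - 3.0, r0, theta) == pytest.approx(-3.0)

    def test_continuity_at_band_edges(self):
        r0, theta = 5.0, 1.5
        for edge in (r0 - theta, r0 + theta):
            lo = dopamine_reinforcement(edge - 1e-9, r0, theta)
            hi = dopamine_reinforcement(edge + 1e-9, r0, theta)
            assert abs(hi - lo) < 1e-6

    def test_vectorized(self):
        out = dopamine_reinforcement(np.array([2.0, 5.0, 9.0]), 5.0, 1.0)
        assert np.allclose(out, [-2.0, 0.0, 3.0])

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            dopamine_reinforcement(5.0, 5.0, -0.1)


class TestHebbianActivity:
    def test_zero_rate_gives_zero(self):
        assert hebbian_activity(0.0, 7.0) == 0.0
        assert hebbian_activity(np.zeros(3), np.ones(4)).sum() == 0.0

    def test_vta_is_plain_product(self):
        assert hebbian_activity(10.0, 5.0, D=100.0, region="vta") == pytest.approx(50.0)

    def test_pfc_gating_suppresses_positive_reinforcement(self):
        # alpha * D = 9 gives a 10-fold suppression of the product 50
        h = hebbian_activity(10.0, 5.0, D=9.0, region="pfc", alpha=1.0)
        assert h == pytest.approx(5.0)

    def test_pfc_gate_inactive_for_negative_reinforcement(self):
        h = hebbian_activity(10.0, 5.0, D=-9.0, region="pfc", alpha=1.0)
        assert h == pytest.approx(50.0)

    def test_outer_product_orientation(self):
        H = hebbian_activity(np.array([1.0, 2.0]), np.array([3.0, 4.0, 5.0]))
        assert H.shape == (3, 2)
        assert H[2, 1] == pytest.approx(10.0)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            hebbian_activity(-1.0, 5.0)


class TestTraces:
    def test_decay_without_activity(self):
        tr = TracePair(1, TraceParams())
        tr.Tp[:] = 0.8
        tr.Td[:] = 0.4
        dt, T = 0.1, 500.0
        for _ in range(int(T / dt)):
            step_traces(tr, np.zeros(1), dt)
        p = tr.params
        assert tr.Tp[0] == pytest.approx(0.8 * np.exp(-T / p.tau_p), rel=1e-3)
        assert tr.Td[0] == pytest.approx(0.4 * np.exp(-T / p.tau_d), rel=1e-2)

    def test_constant_drive_fixed_point(self):
        """Steady state Tp* = tau eta H Tmax / (1 + tau eta H) ... the ODE
        fixed point of the saturating trace equation."""
        p = TraceParams(eta_p=0.01, eta_d=0.05, tau_p=500.0, tau_d=100.0)
        tr = TracePair(1, p)
        H = np.array([30.0])
        for _ in range(80000):
            step_traces(tr, H, 0.1)
        for trace, eta, tmax in ((tr.Tp, p.eta_p, p.tmax_p), (tr.Td, p.eta_d, p.tmax_d)):
            expect = eta * H[0] * tmax / (1 + eta * H[0])
            assert trace[0] == pytest.approx(expect, rel=1e-3)

    def test_saturation_never_exceeded(self):
        p = TraceParams()
        tr = TracePair(1, p)
        tr.Tp[:] = p.tmax_p
        step_traces(tr, np.array([1e6]), 0.1)
        assert tr.Tp[0] <= p.tmax_p + 1e-12

    def test_matches_high_resolution_ode_oracle(self, rng):
        """Euler traces track an independent adaptive ODE integration within
        1% on a random piecewise-constant H(t) profile."""
        p = TraceParams(eta_p=2e-3, eta_d=1e-2, tau_p=1500.0, tau_d=250.0)
        segs = rng.uniform(0.0, 400.0, size=8)   # H values, 100 ms segments
        T = 800.0

        def H_of_t(t):
            return segs[min(int(t // 100.0), 7)]

        def rhs(t, y):
            H = H_of_t(t)
            return [(-y[0] + p.eta_p * H * (p.tmax_p - y[0])) / p.tau_p,
                    (-y[1] + p.eta_d * H * (p.tmax_d - y[1])) / p.tau_d]

        sol = solve_ivp(rhs, (0, T), [0.0, 0.0], rtol=1e-9, atol=1e-12,
                        max_step=5.0)
        tr = TracePair(1, p)
        dt = 0.05
        for i in range(int(T / dt)):
            step_traces(tr, np.array([H_of_t(i * dt)]), dt)
        assert tr.Tp[0] == pytest.approx(sol.y[0, -1], rel=0.01)
        assert tr.Td[0] == pytest.approx(sol.y[1, -1], rel=0.01)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=15, deadline=None)
    def test_traces_bounded_for_any_drive(self, seed):
        r = np.random.default_rng(seed)
        p = TraceParams(eta_p=r.uniform(1e-4, 1e-1), eta_d=r.uniform(1e-4, 1e-1),
                        tau_p=r.uniform(100, 3000), tau_d=r.uniform(50, 500))
        tr = TracePair(3, p)
        for _ in range(300):
            step_traces(tr, r.uniform(0, 1000, 3), 0.5, D=r.uniform(-5, 20))
            assert (tr.Tp >= 0).all() and (tr.Tp <= p.tmax_p).all()
            assert (tr.Td >= 0).all() and (tr.Td <= p.tmax_d).all()


class TestWeightUpdates:
    def _traces(self, tp, td):
        tr = TracePair(1, TraceParams())
        tr.Tp[:] = tp
        tr.Td[:] = td
        return tr

    def test_no_change_when_reinforcement_zero(self):
        W = np.array([0.5])
        apply_weight_update(W, self._traces(0.9, 0.1), 0.0, 1.0, 1.0)
        assert W[0] == 0.5

    def test_no_change_at_trace_crossing(self):
        W = np.array([0.5])
        apply_weight_update(W, self._traces(0.4, 0.4), 10.0, 1.0, 1.0)
        assert W[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("D,tp,td,sign", [
        (1.0, 0.6, 0.2, +1),
        (-1.0, 0.6, 0.2, -1),
        (1.0, 0.2, 0.6, -1),
        (-1.0, 0.2, 0.6, +1),
    ])
    def test_sign_table(self, D, tp, td, sign):
        W = np.array([0.5])
        apply_weight_update(W, self._traces(tp, td), D, 0.1, 1.0)
        assert np.sign(W[0] - 0.5) == sign

    def test_clipping_to_bounds(self):
        W = np.array([0.01])
        apply_weight_update(W, self._traces(0.0, 1.0), 10.0, 1.0, 1.0, w_max=1.0)
        assert W[0] == 0.0
        W = np.array([0.99])
        apply_weight_update(W, self._traces(1.0, 0.0), 10.0, 1.0, 1.0, w_max=1.0)
        assert W[0] == 1.0

    def test_dopamine_hebbian_rule(self):
        W = np.zeros((1, 1))
        dopamine_hebbian_update(W, [10.0], [5.0], 2.0, 0.001, 1.0)
        assert W[0, 0] == pytest.approx(0.1)
        dopamine_hebbian_update(W, [10.0], [5.0], -2.0, 0.001, 1.0)
        assert W[0, 0] == pytest.approx(0.0)
        dopamine_hebbian_update(W, [0.0], [5.0], 5.0, 1.0, 1.0)
        assert W[0, 0] == 0.0


class TestFixedPointResidual:
    def test_zero_reinforcement_gives_zero(self, rng):
        t = np.linspace(0, 1000, 200)
        res = fixed_point_residual(t, np.zeros(200), rng.random(200), rng.random(200))
        assert res == pytest.approx(0.0)

    def test_impulse_reduces_to_trace_difference(self):
        """A unit-area reinforcement impulse at tR leaves Tp(tR) - Td(tR)."""
        t = np.linspace(0, 1000, 2001)
        dt = t[1] - t[0]
        D = np.zeros_like(t)
        k = 1200
        D[k] = 1.0 / dt  # discrete unit impulse
        Tp = np.exp(-t / 700.0)
        Td = np.exp(-t / 150.0)
        res = fixed_point_residual(t, D, Tp, Td)
        assert res == pytest.approx(Tp[k] - Td[k], rel=1e-6)

    def test_two_bump_quadrature(self):
        """Residual equals the sum of the two bump integrals computed directly."""
        t = np.linspace(0, 1500, 3001)
        D = np.where((t >= 100) & (t < 250), 8.0, 0.0) \
            + np.where((t >= 1100) & (t < 1250), 20.0, 0.0)
        Tp = 0.5 * np.exp(-t / 2000.0)
        Td = 0.9 * np.exp(-t / 200.0)
        total = fixed_point_residual(t, D, Tp, Td)
        parts = 0.0
        for lo, hi in ((100, 250), (1100, 1250)):
            sel = (t >= lo - 1) & (t <= hi + 1)
            parts += np.trapezoid((D * (Tp - Td))[sel], t[sel])
        assert total == pytest.approx(parts, rel=1e-6)

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            fixed_point_residual(np.arange(5.0), np.zeros(4), np.zeros(5), np.zeros(5))
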