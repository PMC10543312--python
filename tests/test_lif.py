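"""Unit tests for the LIF core: membrane, synaptic activation, rate filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flexsim import (
    NeuronGroup,
    NeuronParams,
    PoissonInput,
    compute_conductances,
    step_membrane,
    step_rate_estimate,
    step_synaptic_activation,
)


def run_free(group, T, dt, rng=None):
    n = int(T / dt)
    z = np.zeros(group.n)
    for _ in range(n):
        step_membrane(group, z, z, dt, rng)
    return group.v


class TestMembrane:
    def test_leak_equilibrium(self, group):
        """With no input and no noise, v stays exactly at EL."""
        run_free(group, 50.0, 0.1)
        assert np.allclose(group.v, group.params.EL)

    def test_closed_form_decay_and_euler_order(self, quiet_params):
        """Subthreshold decay matches EL + (v0-EL) exp(-gL t / C); halving dt
        roughly halves the max deviation (first-order convergence)."""
        v0, T = -55.0, 40.0
        p = quiet_params
        errs = []
        for dt in (0.2, 0.1):
            g = NeuronGroup(1, p, "n")
            g.v[:] = v0
            n = int(T / dt)
            z = np.zeros(1)
            worst = 0.0
            for i in range(n):
                step_membrane(g, z, z, dt)
                t = (i + 1) * dt
                exact = p.EL + (v0 - p.EL) * np.exp(-p.gL * t / p.C)
                worst = max(worst, abs(g.v[0] - exact))
            errs.append(worst)
        assert errs[1] < errs[0]
        assert 0.3 < errs[1] / errs[0] < 0.7

    def test_constant_excitation_steady_state(self, quiet_params):
        """Subthreshold steady state is the conductance-weighted mean of EL, EE."""
        p = quiet_params
        g = NeuronGroup(1, p, "n")
        gE = np.array([0.2])   # steady state -58.3 mV, below vth = -50
        for _ in range(4000):
            step_membrane(g, gE, np.zeros(1), 0.1)
        expect = (p.gL * p.EL + gE[0] * p.EE) / (p.gL + gE[0])
        assert g.v[0] == pytest.approx(expect, abs=1e-3)

    def test_spike_reset_and_refractory(self, quiet_params):
        p = quiet_params
        g = NeuronGroup(1, p, "n")
        gE = np.array([2.0])  # strongly suprathreshold
        spikes = []
        for i in range(200):
            spikes.append(step_membrane(g, gE, np.zeros(1), 0.1)[0])
            if spikes[-1]:
                assert g.v[0] == p.vreset
        isis = np.diff(np.flatnonzero(spikes)) * 0.1
        assert (isis >= p.tref).all()

    def test_bad_inputs_rejected(self, group):
        with pytest.raises(ValueError, match="dt"):
            step_membrane(group, np.zeros(10), np.zeros(10), 0.0)
        with pytest.raises(ValueError, match="conductances"):
            step_membrane(group, np.full(10, -1.0), np.zeros(10), 0.1)

    def test_nonfinite_state_names_neuron(self, group):
        group.v[3] = np.nan
        with pytest.raises(FloatingPointError, match="neuron 3"):
            step_membrane(group, np.zeros(10), np.zeros(10), 0.1)


class TestSynapticActivation:
    def test_single_spike_then_decay(self, group):
        spikes = np.zeros(10, dtype=bool)
        spikes[0] = True
        step_synaptic_activation(group, spikes, 0.1)
        assert group.s_fast[0] == pytest.approx(group.params.rho)
        # decay follows tau_s_fast approximately (Euler)
        for _ in range(50):
            step_synaptic_activation(group, np.zeros(10, dtype=bool), 0.1)
        expect = group.params.rho * (1 - 0.1 / group.params.tau_s_fast) ** 50
        assert group.s_fast[0] == pytest.approx(expect, rel=1e-9)

    def test_saturation_at_one(self, group):
        group.s_fast[:] = 1.0
        step_synaptic_activation(group, np.ones(10, dtype=bool), 1e-9)
        assert group.s_fast.max() <= 1.0

    def test_poisson_mean_field_steady_state(self, quiet_params, rng):
        """Sustained Poisson input at f drives mean s to rho f tau / (1 + rho f tau)
        (continuum limit, rho reduced so individual jumps are small)."""
        p = NeuronParams(rho=0.05, tau_s_fast=5.0)
        g = NeuronGroup(500, p, "n")
        f = 0.1  # spikes per ms = 100 Hz
        dt = 0.05
        for _ in range(int(400 / dt)):
            spikes = rng.random(500) < f * dt
            step_synaptic_activation(g, spikes, dt)
        expect = p.rho * f * p.tau_s_fast / (1 + p.rho * f * p.tau_s_fast)
        assert g.s_fast.mean() == pytest.approx(expect, rel=0.05)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=20, deadline=None)
    def test_activation_bounded_for_any_spike_train(self, seed):
        rng = np.random.default_rng(seed)
        g = NeuronGroup(5, NeuronParams(rho=rng.uniform(0.05, 1.0)), "n")
        for _ in range(200):
            step_synaptic_activation(g, rng.random(5) < 0.3, 0.5)
            assert (g.s_fast >= 0).all() and (g.s_fast <= 1).all()
            assert (g.s_slow >= 0).all() and (g.s_slow <= 1).all()


class TestRateEstimate:
    def test_single_spike_peak_and_decay(self, group):
        spikes = np.zeros(10, dtype=bool)
        spikes[0] = True
        step_rate_estimate(group, spikes, 0.1)
        assert group.r[0] == pytest.approx(1.0 / group.params.tau_r)
        r0 = group.r[0]
        for _ in range(100):
            step_rate_estimate(group, np.zeros(10, dtype=bool), 0.1)
        assert group.r[0] < r0
        assert group.r[0] > 0

    def test_poisson_long_run_mean_equals_rate(self, quiet_params, rng):
        """Unit-area filter: mean of r equals the Poisson rate (1/ms units)."""
        g = NeuronGroup(400, quiet_params, "n")
        f = 0.02  # 20 Hz
        dt = 0.5
        vals = []
        for i in range(int(4000 / dt)):
            step_rate_estimate(g, rng.random(400) < f * dt, dt)
            if i * dt > 500:
                vals.append(g.r.mean())
        assert np.mean(vals) == pytest.approx(f, rel=0.05)
        assert np.allclose(g.rate_hz, g.r * 1000.0)


class TestConductances:
    def test_zero_activation_and_single_synapse(self):
        W = np.array([[0.7]])
        gE, gI = compute_conductances(W, None, np.array([0.0]), None)
        assert gE[0] == 0.0 and gI[0] == 0.0
        gE, _ = compute_conductances(W, None, np.array([0.4]), None)
        assert gE[0] == pytest.approx(0.28)

    def test_linearity_in_weights(self, rng):
        W = rng.random((4, 6))
        s = rng.random(6)
        g1, _ = compute_conductances(W, None, s, None)
        g2, _ = compute_conductances(2 * W, None, s, None)
        assert np.allclose(g2, 2 * g1)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="incompatible"):
            compute_conductances(rng.random((4, 6)), None, rng.random(5), None)


class TestPoissonInput:
    def test_silent_when_rate_zero(self, rng):
        inp = PoissonInput(50, name="cs")
        for _ in range(100):
            spikes = inp.step(0.0, 0.5, rng)
            assert not spikes.any()
        assert inp.r.max() == 0.0

    def test_rate_tracks_drive(self, rng):
        inp = PoissonInput(200, name="cs")
        count = 0
        for _ in range(int(2000 / 0.5)):
            count += inp.step(50.0, 0.5, rng).sum()
        assert count / (200 * 2.0) == pytest.approx(50.0, rel=0.1)


class TestParamValidation:
    @pytest.mark.parametrize("bad", [
        {"EI": -60.0},         # violates EI <= EL
        {"vth": -75.0},        # violates EL < vth
        {"tau_s_fast": 0.0},
        {"rho": 0.0},
        {"sigma": -1.0},
        {"b_adapt": -0.1},
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            NeuronParams(**bad).validate()
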