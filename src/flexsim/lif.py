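"""Conductance-based leaky integrate-and-fire populations.

Every population in the model (cortical Timer/Inhibitory/Messenger columns
and the VTA dopamine/GABA pools) is a homogeneous group of LIF neurons with

* membrane dynamics  ``C dv/dt = gL(EL - v) + gE(EE - v) + gI(EI - v) + noise``
* synaptic activation ``ds/dt = -s/tau_s + rho (1 - s) * spikes``
* conductances       ``g_i = sum_j W_ij s_j``
* online rate estimate ``tau_r dr/dt = -r + spikes`` (unit-area exponential
  filter, so a stationary Poisson train at f Hz averages to r = f).

Each neuron carries two synaptic-activation variables with identical update
rules but different decay constants: a fast AMPA/GABA-like channel and a slow
NMDA-like channel. Projections choose which channel they read; the slow
channel is what lets recurrent Timer excitation outlast the membrane time
constant by an order of magnitude.

Integration is forward Euler (default dt = 0.1 ms, configurable); noise is
Euler-Maruyama with per-step standard deviation ``sigma * sqrt(dt) / C``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronGroup",
    "PoissonInput",
    "step_membrane",
    "step_synaptic_activation",
    "step_rate_estimate",
    "compute_conductances",
]


@dataclass
class NeuronParams:
    """Parameters of a homogeneous LIF population.

    Units: potentials mV, times ms, conductances relative to the leak
    conductance ``gL`` (so ``tau_m = C / gL`` with C in gL-normalized units),
    ``sigma`` is the standard deviation of the white current noise in
    gL*mV per sqrt(ms).
    """

    C: float = 20.0          # membrane capacitance; tau_m = C/gL = 20 ms
    gL: float = 1.0          # leak conductance (normalization)
    EL: float = -70.0        # leak reversal (mV)
    EE: float = 0.0          # excitatory reversal (mV)
    EI: float = -80.0        # inhibitory reversal (mV)
    vth: float = -50.0       # spike threshold (mV)
    vreset: float = -70.0    # post-spike reset (mV)
    tref: float = 2.0        # absolute refractory period (ms)
    tau_s_fast: float = 5.0  # fast (AMPA/GABA-like) activation decay (ms)
    tau_s_slow: float = 100.0  # slow (NMDA-like) activation decay (ms)
    rho: float = 1.0         # per-spike activation increment factor
    sigma: float = 0.0       # current noise amplitude
    tau_r: float = 50.0      # rate-estimate filter time constant (ms)
    # slow afterhyperpolarization (spike-frequency adaptation) conductance;
    # off by default, enabled for Timer populations where it converts
    # near-critical recurrent excitation into a graded, weight-controlled
    # persistence duration instead of a bistable switch
    b_adapt: float = 0.0     # adaptation conductance increment per spike
    tau_adapt: float = 600.0  # adaptation decay (ms)
    E_adapt: float = -90.0   # adaptation reversal (K-like, mV)

    def validate(self) -> None:
        if not (self.EI <= self.EL < self.vth <= self.EE):
            raise ValueError(
                f"reversal/threshold ordering violated: need EI <= EL < vth <= EE, "
                f"got EI={self.EI}, EL={self.EL}, vth={self.vth}, EE={self.EE}"
            )
        for name in ("C", "gL", "tau_s_fast", "tau_s_slow", "tau_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"NeuronParams.{name} must be > 0")
        if self.tref < 0:
            raise ValueError("NeuronParams.tref must be >= 0")
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("NeuronParams.rho must lie in (0, 1]")
        if self.sigma < 0:
            raise ValueError("NeuronParams.sigma must be >= 0")
        if self.b_adapt < 0:
            raise ValueError("NeuronParams.b_adapt must be >= 0")
        if self.tau_adapt <= 0:
            raise ValueError("NeuronParams.tau_adapt must be > 0")


@dataclass
class NeuronGroup:
    """State of one LIF population.

    ``s_fast``/``s_slow`` are the two synaptic-activation channels (both
    kept in [0, 1] by the saturating ``rho (1 - s)`` increment); ``r`` is the
    exponentially filtered rate estimate in kHz-per-ms units scaled so that
    its long-run mean equals the firing rate in spikes/ms * 1000 -> Hz.
    """

    n: int
    params: NeuronParams
    name: str = "group"

    v: np.ndarray = field(init=False)
    s_fast: np.ndarray = field(init=False)
    s_slow: np.ndarray = field(init=False)
    r: np.ndarray = field(init=False)
    g_adapt: np.ndarray = field(init=False)
    refractory_until: np.ndarray = field(init=False)
    t: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"group '{self.name}': n must be positive, got {self.n}")
        self.params.validate()
        self.reset_state()

    def reset_state(self) -> None:
        p = self.params
        self.v = np.full(self.n, p.EL, dtype=float)
        self.s_fast = np.zeros(self.n)
        self.s_slow = np.zeros(self.n)
        self.r = np.zeros(self.n)
        self.g_adapt = np.zeros(self.n)
        self.refractory_until = np.full(self.n, -np.inf)
        self.t = 0.0

    @property
    def rate_hz(self) -> np.ndarray:
        """Rate estimate in Hz (r carries 1/ms units internally)."""
        return self.r * 1000.0

    def step(self, gE: np.ndarray, gI: np.ndarray, dt: float,
             rng: np.random.Generator) -> np.ndarray:
        """One full update: membrane -> spikes -> activations -> rate."""
        spikes = step_membrane(self, gE, gI, dt, rng)
        step_synaptic_activation(self, spikes, dt)
        step_rate_estimate(self, spikes, dt)
        return spikes


def step_membrane(group: NeuronGroup, gE, gI, dt: float,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Forward-Euler membrane update; returns boolean spike indicators.

    Refractory neurons are clamped at ``vreset`` and do not integrate.
    Spikes are registered at threshold crossing; crossing neurons are reset
    and enter a refractory period of ``tref``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    p = group.params
    v = group.v
    gE = np.asarray(gE, dtype=float)
    gI = np.asarray(gI, dtype=float)
    if gE.min(initial=0.0) < 0 or gI.min(initial=0.0) < 0:
        raise ValueError(f"group '{group.name}': conductances must be >= 0")

    dv = (p.gL * (p.EL - v) + gE * (p.EE - v) + gI * (p.EI - v)
          + group.g_adapt * (p.E_adapt - v)) * (dt / p.C)
    if p.sigma > 0:
        if rng is None:
            raise ValueError("rng required when sigma > 0")
        dv = dv + (p.sigma * np.sqrt(dt) / p.C) * rng.standard_normal(group.n)
    refractory = group.t < group.refractory_until
    v = v + np.where(refractory, 0.0, dv)
    v[refractory] = p.vreset

    spikes = v >= p.vth
    group.g_adapt -= (dt / p.tau_adapt) * group.g_adapt
    if spikes.any():
        v[spikes] = p.vreset
        group.refractory_until[spikes] = group.t + p.tref
        if p.b_adapt > 0:
            group.g_adapt[spikes] += p.b_adapt
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise FloatingPointError(
            f"non-finite membrane potential in group '{group.name}', neuron {bad}"
        )
    group.v = v
    group.t += dt
    return spikes


def step_synaptic_activation(group: NeuronGroup, spikes: np.ndarray, dt: float) -> None:
    """Decay both activation channels and apply the saturating spike increment.

    The update ``s <- s + rho (1 - s)`` on a spike keeps s in [0, 1] for any
    spike sequence.
    """
    p = group.params
    group.s_fast -= (dt / p.tau_s_fast) * group.s_fast
    group.s_slow -= (dt / p.tau_s_slow) * group.s_slow
    if spikes.any():
        group.s_fast[spikes] += p.rho * (1.0 - group.s_fast[spikes])
        group.s_slow[spikes] += p.rho * (1.0 - group.s_slow[spikes])


def step_rate_estimate(group: NeuronGroup, spikes: np.ndarray, dt: float) -> None:
    """Exponential filter of the spike train with unit area (peak 1/tau_r)."""
    p = group.params
    group.r -= (dt / p.tau_r) * group.r
    if spikes.any():
        group.r[spikes] += 1.0 / p.tau_r


def compute_conductances(weights_exc: np.ndarray | None,
                         weights_inh: np.ndarray | None,
                         s_pre_exc: np.ndarray | None,
                         s_pre_inh: np.ndarray | None,
                         n_post: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Total excitatory/inhibitory conductance per postsynaptic neuron.

    ``g_i = sum_j W_ij s_j`` for each channel; weights are non-negative (the
    sign of a pathway is carried by the channel it targets, not the weight).
    """

    def one(W, s):
        if W is None:
            return None
        W = np.asarray(W, dtype=float)
        s = np.asarray(s, dtype=float)
        if W.ndim != 2 or W.shape[1] != s.shape[0]:
            raise ValueError(
                f"weight matrix shape {W.shape} incompatible with "
                f"{s.shape[0]} presynaptic activations"
            )
        return W @ s

    gE = one(weights_exc, s_pre_exc)
    gI = one(weights_inh, s_pre_inh)
    if gE is None and gI is None:
        if n_post is None:
            raise ValueError("nothing to compute: both channels empty and n_post unknown")
        return np.zeros(n_post), np.zeros(n_post)
    if gE is None:
        gE = np.zeros_like(gI)
    if gI is None:
        gI = np.zeros_like(gE)
    return gE, gI


class PoissonInput:
    """Stimulus-input population emitting Poisson spikes at a driven rate.

    Used for the cue (CS) and reward (US) input channels: each input neuron
    fires at ``rate_hz`` during the stimulus window and is silent otherwise.
    Synaptic activations and the rate estimate follow the same dynamics as
    LIF groups so that downstream conductances and Hebbian products are
    computed identically.
    """

    def __init__(self, n: int, params: NeuronParams | None = None, name: str = "input"):
        if n <= 0:
            raise ValueError(f"input group '{name}': n must be positive")
        self.n = n
        self.params = params if params is not None else NeuronParams()
        self.name = name
        self.reset_state()

    def reset_state(self) -> None:
        self.s_fast = np.zeros(self.n)
        self.s_slow = np.zeros(self.n)
        self.r = np.zeros(self.n)
        self.t = 0.0

    @property
    def rate_hz(self) -> np.ndarray:
        return self.r * 1000.0

    def step(self, rate_hz: float, dt: float, rng: np.random.Generator) -> np.ndarray:
        if rate_hz < 0:
            raise ValueError("Poisson rate must be >= 0")
        p_spike = rate_hz * dt / 1000.0
        if p_spike > 0:
            spikes = rng.random(self.n) < p_spike
        else:
            spikes = np.zeros(self.n, dtype=bool)
        p = self.params
        self.s_fast -= (dt / p.tau_s_fast) * self.s_fast
        self.s_slow -= (dt / p.tau_s_slow) * self.s_slow
        self.r -= (dt / p.tau_r) * self.r
        if spikes.any():
            self.s_fast[spikes] += p.rho * (1.0 - self.s_fast[spikes])
            self.s_slow[spikes] += p.rho * (1.0 - self.s_slow[spikes])
            self.r[spikes] += 1.0 / p.tau_r
        self.t += dt
        return spikes
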