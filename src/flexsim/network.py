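"""Full model architecture: cortical feature columns plus a VTA reward module.

Each declared stimulus owns one cortical "column" containing a core
microcircuit of three LIF populations:

* Timers    — recurrently connected (slow NMDA-like synapses); the strength
              of the learned recurrence sets how long their activity outlasts
              the cue, up to the cue-reward delay.
* Inhibitory — driven by the Timers through fast synapses; inhibit the
              Messengers.
* Messengers — receive slow Timer excitation and fast feed-forward
              inhibition. During the Timer plateau the two cancel; when the
              Timer envelope collapses the fast inhibition vanishes first,
              so the Messengers fire selectively at the *end* of the Timer
              envelope, i.e. at the expected reward time.

The reward module (VTA) holds dopaminergic (DA) and GABAergic pools, both
kept at a ~5 Hz noisy baseline. Rewards reach DA through a fixed sparse
projection from the US input channel; the GABA pool inhibits DA.

Three pathways are plastic:

* Timer -> Timer   (dTTL, cortical rule with event-boundary gating)
* CS    -> DA      (dTTL, VTA rule) — builds the cue-evoked dopamine response
* Messenger -> GABA (dopamine-modulated Hebbian) — suppresses the reward-
                    evoked response once the Messengers overlap the reward

Reinforcement D(t) is computed from the population-mean DA rate and broadcast
globally to every plastic synapse (dopamine as a volume transmitter).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lif import NeuronGroup, NeuronParams, PoissonInput
from .plasticity import (
    PlasticityConfig,
    TraceParams,
    TracePair,
    dopamine_hebbian_update,
    dopamine_reinforcement,
    apply_weight_update,
    hebbian_activity,
    step_traces,
)

__all__ = [
    "ProjectionSpec",
    "Projection",
    "NetworkSpec",
    "Network",
    "TrialRecording",
    "build_network",
    "timer_duration",
]


@dataclass
class ProjectionSpec:
    """Static description of one weight matrix between two named groups."""

    source: str
    target: str
    channel: str = "E"          # 'E' or 'I' (sign carried by channel, not weight)
    kinetics: str = "fast"      # which presynaptic activation channel to read
    sparsity: float = 1.0       # connection probability
    weight_scale: float = 1.0   # mean *total* conductance at full presyn activation
    weight_jitter: float = 0.0  # sigma of multiplicative log-normal jitter
    plastic: bool = False
    region: str = "vta"         # Hebbian rule region for dTTL ('vta'|'pfc')
    trace: TraceParams | None = None
    plasticity: PlasticityConfig | None = None

    def validate(self) -> None:
        if self.channel not in ("E", "I"):
            raise ValueError(f"projection {self.source}->{self.target}: channel must be E or I")
        if self.kinetics not in ("fast", "slow"):
            raise ValueError(f"projection {self.source}->{self.target}: kinetics must be fast or slow")
        if not (0.0 < self.sparsity <= 1.0):
            raise ValueError(f"projection {self.source}->{self.target}: sparsity must be in (0, 1]")
        if self.weight_scale < 0:
            raise ValueError(f"projection {self.source}->{self.target}: weight_scale must be >= 0")
        if self.plastic:
            if self.plasticity is None:
                raise ValueError(
                    f"projection {self.source}->{self.target}: plastic but no plasticity config"
                )
            self.plasticity.validate()
            if self.plasticity.rule == "dttl" and self.trace is None:
                raise ValueError(
                    f"projection {self.source}->{self.target}: dTTL requires trace parameters"
                )


class Projection:
    """A realized weight matrix (n_post x n_pre) plus eligibility traces."""

    def __init__(self, spec: ProjectionSpec, n_pre: int, n_post: int,
                 rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        self.mask = rng.random((n_post, n_pre)) < spec.sparsity
        # per-synapse weight such that the *expected total* conductance onto a
        # postsynaptic cell at full presynaptic activation equals weight_scale
        # conversion between per-synapse weights and total-conductance units:
        # a projection at "scale" s has per-synapse weight s * w_unit
        self.w_unit = 1.0 / max(spec.sparsity * n_pre, 1e-12)
        base = spec.weight_scale * self.w_unit
        w = np.where(self.mask, base, 0.0)
        if spec.weight_jitter > 0:
            jitter = rng.lognormal(mean=-0.5 * spec.weight_jitter ** 2,
                                   sigma=spec.weight_jitter, size=w.shape)
            w = w * jitter
        self.W = w
        self.W_init = w.copy()
        self.traces = (
            TracePair(w.shape, spec.trace)
            if spec.plastic and spec.plasticity.rule == "dttl"
            else None
        )

    @property
    def plastic(self) -> bool:
        return self.spec.plastic

    def mean_weight(self) -> float:
        """Mean connected weight in total-conductance (weight_scale) units."""
        m = self.mask.sum()
        return float(self.W.sum() / m / self.w_unit) if m else 0.0

    def reset_traces(self) -> None:
        if self.traces is not None:
            self.traces.reset()


# ---------------------------------------------------------------------------
# Network specification and defaults


@dataclass
class NetworkSpec:
    """Sizes, neuron parameters and wiring of the full model.

    ``stimuli`` lists the conditioned-stimulus ids, one cortical column each.
    Default projection set realizes the architecture described in the module
    docstring; pass ``projections`` to override wiring wholesale.
    """

    stimuli: list[str] = field(default_factory=lambda: ["cs1"])
    n_cna: int = 100        # neurons per Timer/Inhibitory/Messenger population
    n_da: int = 100
    n_gaba: int = 100
    n_input: int = 100      # neurons per CS/US input channel
    dt: float = 0.5         # simulation step (ms)

    # VTA baseline
    r0: float = 5.0         # target baseline DA/GABA rate (Hz)
    theta: float = 1.0      # neutral half-width of the reinforcement map (Hz)
    sigma_da: float = 73.0  # calibrated tonic current noise (see docs/methods.md)
    sigma_gaba: float = 68.0

    # stimulus drive
    cs_rate_hz: float = 50.0   # input-channel rate at unit stimulus amplitude
    us_rate_hz: float = 100.0  # input-channel rate at unit reward magnitude

    neuron: NeuronParams = field(default_factory=NeuronParams)
    projections: list[ProjectionSpec] | None = None

    # learning rates (exposed for experiments; defaults reproduce the
    # 40-trial single-cue acquisition timeline)
    eta_cs_da: float = 1.2e-4
    eta_tt: float = 1.2e-3
    eta_m_gaba: float = 8.0e-8
    alpha_boundary: float = 12.0   # PFC event-boundary gating strength

    # Timer adaptation: converts near-critical recurrence into graded timing
    timer_b_adapt: float = 0.06
    timer_tau_adapt: float = 1400.0

    w_tt_init: float = 1.20
    w_tt_max: float = 3.26
    w_cs_da_max: float = 2.0
    w_m_gaba_max: float = 9.0

    def validate(self) -> None:
        if len(self.stimuli) == 0:
            raise ValueError("NetworkSpec: at least one stimulus column is required")
        if len(set(self.stimuli)) != len(self.stimuli):
            raise ValueError("NetworkSpec: duplicate stimulus ids")
        for name in ("n_cna", "n_da", "n_gaba", "n_input"):
            if getattr(self, name) <= 0:
                raise ValueError(f"NetworkSpec.{name} must be positive")
        if self.dt <= 0:
            raise ValueError("NetworkSpec.dt must be > 0")
        if self.theta < 0:
            raise ValueError("NetworkSpec.theta must be >= 0")

    def default_projections(self) -> list[ProjectionSpec]:
        trace_vta = TraceParams(eta_p=4e-2, eta_d=7e-3, tau_p=2000.0, tau_d=200.0)
        trace_pfc = TraceParams(eta_p=1.25e-3, eta_d=1.3e-3, tau_p=2000.0, tau_d=200.0, tmax_d=0.94,
                               boundary_erase=1e-4, h_sat=1200.0)
        specs: list[ProjectionSpec] = []
        for sid in self.stimuli:
            cs, tim, inh, msg = f"cs_{sid}", f"timer_{sid}", f"inh_{sid}", f"msg_{sid}"
            specs += [
                ProjectionSpec(cs, tim, "E", "fast", sparsity=0.5, weight_scale=2.2),
                ProjectionSpec(tim, tim, "E", "slow", sparsity=1.0,
                               weight_scale=self.w_tt_init, weight_jitter=0.1,
                               plastic=True, region="pfc", trace=trace_pfc,
                               plasticity=PlasticityConfig(
                                   eta=self.eta_tt, alpha=self.alpha_boundary,
                                   rule="dttl", w_max=self.w_tt_max)),
                ProjectionSpec(tim, inh, "E", "fast", sparsity=0.5, weight_scale=3.0),
                # balanced feedback inhibition clamps the Timer plateau rate so
                # that adaptation, not runaway excitation, sets the duration
                ProjectionSpec(inh, tim, "I", "fast", sparsity=0.5, weight_scale=10.0),
                ProjectionSpec(tim, msg, "E", "slow", sparsity=0.5, weight_scale=1.5),
                ProjectionSpec(inh, msg, "I", "fast", sparsity=0.5, weight_scale=30.0),
                ProjectionSpec(msg, "gaba", "E", "fast", sparsity=0.5,
                               weight_scale=0.0, plastic=True,
                               plasticity=PlasticityConfig(
                                   eta=self.eta_m_gaba, rule="dopamine_hebbian",
                                   w_max=self.w_m_gaba_max)),
                ProjectionSpec(cs, "da", "E", "fast", sparsity=0.15,
                               weight_scale=0.0, weight_jitter=0.5,
                               plastic=True, region="vta", trace=trace_vta,
                               plasticity=PlasticityConfig(
                                   eta=self.eta_cs_da, rule="dttl",
                                   w_max=self.w_cs_da_max)),
            ]
        specs += [
            ProjectionSpec("us", "da", "E", "fast", sparsity=0.15,
                           weight_scale=1.6, weight_jitter=0.5),
            ProjectionSpec("gaba", "da", "I", "fast", sparsity=0.5, weight_scale=4.0),
        ]
        return specs


# ---------------------------------------------------------------------------
# Recordings


@dataclass
class TrialRecording:
    """Everything measured during one trial.

    ``rates`` holds population-mean rate traces in Hz, sampled every
    simulation step; ``counts`` holds per-neuron spike counts in
    ``count_bin``-ms bins for the groups configured for spike recording.
    """

    times: np.ndarray
    rates: dict[str, np.ndarray]
    r_da: np.ndarray
    D: np.ndarray
    r0: float
    theta: float
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    count_bin: float = 50.0
    weights: dict[str, float] = field(default_factory=dict)
    trace_series: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# The network itself


class Network:
    """Realized populations + projections + the global dopamine signal."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        self.rng = rng
        self.groups: dict[str, NeuronGroup] = {}
        self.inputs: dict[str, PoissonInput] = {}

        quiet = replace(spec.neuron, sigma=0.0)
        da_params = replace(spec.neuron, sigma=spec.sigma_da)
        gaba_params = replace(spec.neuron, sigma=spec.sigma_gaba)
        timer_params = replace(spec.neuron, sigma=0.0,
                               b_adapt=spec.timer_b_adapt,
                               tau_adapt=spec.timer_tau_adapt)
        for sid in spec.stimuli:
            self.inputs[f"cs_{sid}"] = PoissonInput(spec.n_input, replace(quiet), f"cs_{sid}")
            for pop in ("timer", "inh", "msg"):
                name = f"{pop}_{sid}"
                params = replace(timer_params) if pop == "timer" else replace(quiet)
                self.groups[name] = NeuronGroup(spec.n_cna, params, name)
        self.inputs["us"] = PoissonInput(spec.n_input, replace(quiet), "us")
        self.groups["da"] = NeuronGroup(spec.n_da, da_params, "da")
        self.groups["gaba"] = NeuronGroup(spec.n_gaba, gaba_params, "gaba")

        proj_specs = spec.projections if spec.projections is not None \
            else spec.default_projections()
        self.projections: dict[str, Projection] = {}
        for ps in proj_specs:
            pre = self._group_or_input(ps.source)
            post = self.groups.get(ps.target)
            if pre is None or post is None:
                raise ValueError(
                    f"projection {ps.source}->{ps.target}: unknown group "
                    f"('{ps.source if pre is None else ps.target}')"
                )
            self.projections[f"{ps.source}->{ps.target}"] = Projection(
                ps, pre.n, post.n, rng)

        self.learning_enabled = True
        self._step_index = 0

    # -- helpers ----------------------------------------------------------

    def _group_or_input(self, name: str):
        return self.groups.get(name) or self.inputs.get(name)

    def reset_state(self) -> None:
        """Reset neuron state and eligibility traces (weights persist)."""
        for g in self.groups.values():
            g.reset_state()
        for g in self.inputs.values():
            g.reset_state()
        for proj in self.projections.values():
            proj.reset_traces()

    @property
    def r_da_mean(self) -> float:
        return float(self.groups["da"].rate_hz.mean())

    def reinforcement(self) -> float:
        return float(dopamine_reinforcement(self.r_da_mean, self.spec.r0, self.spec.theta))

    # -- dynamics ---------------------------------------------------------

    def step(self, input_rates: dict[str, float], dt: float | None = None) -> dict[str, np.ndarray]:
        """One synchronous update of the whole network.

        Order: input channels -> conductances -> membranes/spikes ->
        activations -> rates -> D(t) -> trace and weight updates (plastic
        projections only, and only while ``learning_enabled``).
        Returns the boolean spike indicators per group.
        """
        dt = self.spec.dt if dt is None else dt
        rng = self.rng
        for name, inp in self.inputs.items():
            inp.step(input_rates.get(name, 0.0), dt, rng)

        gE = {name: np.zeros(g.n) for name, g in self.groups.items()}
        gI = {name: np.zeros(g.n) for name, g in self.groups.items()}
        for key, proj in self.projections.items():
            sp = proj.spec
            pre = self._group_or_input(sp.source)
            s = pre.s_fast if sp.kinetics == "fast" else pre.s_slow
            g = proj.W @ s
            (gE if sp.channel == "E" else gI)[sp.target] += g

        spikes: dict[str, np.ndarray] = {}
        for name, group in self.groups.items():
            try:
                spikes[name] = group.step(gE[name], gI[name], dt, rng)
            except FloatingPointError as err:
                raise FloatingPointError(f"step {self._step_index}: {err}") from err

        D = self.reinforcement()
        if self.learning_enabled:
            self._apply_plasticity(D, dt)
        self._step_index += 1
        return spikes

    def _apply_plasticity(self, D: float, dt: float) -> None:
        for proj in self.projections.values():
            if not proj.plastic:
                continue
            sp = proj.spec
            pre = self._group_or_input(sp.source)
            post = self.groups[sp.target]
            cfg = sp.plasticity
            # eta and w_max are configured in total-conductance units; convert
            # to the per-synapse representation
            eta = cfg.eta * proj.w_unit
            w_max = cfg.w_max * proj.w_unit
            if cfg.rule == "dttl":
                H = hebbian_activity(pre.rate_hz, post.rate_hz, D,
                                     region=sp.region, alpha=cfg.alpha)
                H *= proj.mask
                step_traces(proj.traces, H, dt, D)
                apply_weight_update(proj.W, proj.traces, D, eta, dt, w_max)
                proj.W *= proj.mask
            else:
                dopamine_hebbian_update(proj.W, pre.rate_hz, post.rate_hz, D,
                                        eta, dt, w_max)
                proj.W *= proj.mask


def build_network(spec: NetworkSpec, rng: np.random.Generator | int) -> Network:
    """Construct a network from its spec; deterministic given the rng seed."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return Network(spec, rng)


# ---------------------------------------------------------------------------
# Timer readout


def timer_duration(times: np.ndarray, rate_hz: np.ndarray, cs_onset: float,
                   smooth_ms: float = 50.0, min_plateau_hz: float = 5.0) -> float | None:
    """Duration of Timer population activity: CS onset to half-plateau decay.

    The population rate is boxcar-smoothed; the plateau level is the median
    rate over the active period (rate above 10% of the post-onset maximum),
    which makes the estimate robust to the onset transient and to the slow
    adaptation sag; the duration runs to the *last* time the rate still
    exceeds half the plateau. Returns None when the Timer never activates
    (plateau below ``min_plateau_hz``), distinguishable from 0.
    """
    times = np.asarray(times, dtype=float)
    rate = np.asarray(rate_hz, dtype=float)
    if times.shape != rate.shape:
        raise ValueError("times and rate must have matching shapes")
    dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    k = max(int(round(smooth_ms / dt)), 1)
    kernel = np.ones(k) / k
    sm = np.convolve(rate, kernel, mode="same")
    post = times >= cs_onset
    if not post.any():
        return None
    peak = sm[post].max()
    if peak < min_plateau_hz:
        return None
    active = post & (sm >= 0.1 * peak)
    plateau = float(np.median(sm[active]))
    above = post & (sm >= 0.5 * plateau)
    t_last = times[above][-1]
    return float(t_last - cs_onset)
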