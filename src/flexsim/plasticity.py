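"""Dopaminergic two-trace learning (dTTL).

The reinforcement signal is derived from the population-mean dopamine rate
r_DA(t) by a piecewise-linear threshold map with a neutral band of half-width
theta around the baseline r0:

    D(t) = r_DA - (r0 - theta)   if r_DA <= r0 - theta   (negative)
         = 0                     if |r_DA - r0| < theta
         = r_DA - (r0 + theta)   if r_DA >= r0 + theta   (positive)

Each plastic synapse carries a pair of Hebbian-activated eligibility traces,
one tied to potentiation (Tp) and one to depression (Td):

    tau_a dT_a/dt = -T_a + eta_a H (Tmax_a - T_a),    a in {p, d}

and the weight update is competitive, converting the dopamine-weighted
difference of the traces into synaptic change:

    dW/dt = eta D(t) (Tp - Td)

The Hebbian activity H is the product of pre- and postsynaptic rate
estimates; for cortical (PFC) synapses it is additionally divided by
(1 + alpha * max(D, 0)), which suppresses trace generation during large
positive dopamine transients (event boundaries).

Trace-parameter defaults are chosen so that the depression trace rises fast
and decays fast while the potentiation trace rises more slowly but persists:
shortly after a burst of Hebbian activity Td > Tp, and roughly a second
later Tp > Td. Under a delayed positive dopamine bump this potentiates
recently active synapses, while dopamine arriving *during* the activity
(e.g. a cue-evoked bump concurrent with the cue's own afferents) depresses
them — the competition that places the fixed point

    integral_0^T D(t) (Tp(t) - Td(t)) dt = 0

at "traces cross at the time of reward".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DopamineSignal",
    "TraceParams",
    "TracePair",
    "PlasticityConfig",
    "dopamine_reinforcement",
    "hebbian_activity",
    "step_traces",
    "apply_weight_update",
    "dopamine_hebbian_update",
    "fixed_point_residual",
]


def dopamine_reinforcement(r_da, r0: float, theta: float):
    """Signed reinforcement from the dopamine population rate (piecewise linear).

    Scalar or array ``r_da`` (Hz); zero inside the neutral band
    (r0 - theta, r0 + theta).
    """
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    r_da = np.asarray(r_da, dtype=float)
    high = r_da - (r0 + theta)
    low = r_da - (r0 - theta)
    out = np.where(r_da >= r0 + theta, high, np.where(r_da <= r0 - theta, low, 0.0))
    return out if out.ndim else float(out)


@dataclass
class DopamineSignal:
    """Recorded reinforcement time series for one trial."""

    times: np.ndarray      # ms
    r_da: np.ndarray       # population-mean DA rate (Hz)
    r0: float
    theta: float

    @property
    def D(self) -> np.ndarray:
        return np.asarray(dopamine_reinforcement(self.r_da, self.r0, self.theta))


def hebbian_activity(r_pre, r_post, D: float = 0.0, region: str = "vta",
                     alpha: float = 0.0):
    """Per-synapse Hebbian activity H_ij = r_post_i * r_pre_j (outer product).

    ``region='pfc'`` applies the event-boundary gate: division by
    (1 + alpha * D) for positive D only (negative reinforcement leaves the
    plain product).
    Rates in Hz; 1-D inputs produce the full matrix, scalars a scalar.
    """
    r_pre = np.asarray(r_pre, dtype=float)
    r_post = np.asarray(r_post, dtype=float)
    if (r_pre < 0).any() or (r_post < 0).any():
        raise ValueError("rates must be >= 0")
    if r_pre.ndim == 1 and r_post.ndim == 1:
        H = np.outer(r_post, r_pre)
    else:
        H = r_post * r_pre
    if region == "pfc":
        H = H / (1.0 + alpha * max(float(D), 0.0))
    elif region != "vta":
        raise ValueError(f"unknown region '{region}' (expected 'vta' or 'pfc')")
    return H


@dataclass
class TraceParams:
    """Eligibility-trace constants for one plastic projection.

    ``eta_p/eta_d`` are activation gains multiplying H (H has units Hz^2, so
    the gains carry 1/Hz^2); ``tau_p/tau_d`` are decay constants in ms;
    ``tmax_p/tmax_d`` saturation levels. Defaults give a fast-rising,
    fast-decaying depression trace and a slower, persistent potentiation
    trace (see module docstring).
    """

    eta_p: float = 8e-3
    eta_d: float = 4e-2
    tau_p: float = 2000.0
    tau_d: float = 200.0
    tmax_p: float = 1.0
    tmax_d: float = 1.0
    # event-boundary erasure (cortical synapses only): large positive
    # dopamine transients actively degrade existing traces at rate
    # boundary_erase * max(D, 0) per ms, implementing the disruption of
    # across-boundary associations
    boundary_erase: float = 0.0
    # saturation of the Hebbian drive: H is clipped at h_sat before entering
    # the trace dynamics, making the LTP/LTD crossing time insensitive to
    # firing-rate magnitude (only to activity timing)
    h_sat: float = float("inf")

    def validate(self) -> None:
        for name in ("eta_p", "eta_d", "tau_p", "tau_d", "tmax_p", "tmax_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TraceParams.{name} must be > 0")
        if self.boundary_erase < 0:
            raise ValueError("TraceParams.boundary_erase must be >= 0")


class TracePair:
    """LTP/LTD eligibility traces for every synapse of one projection."""

    def __init__(self, shape, params: TraceParams | None = None):
        self.params = params if params is not None else TraceParams()
        self.params.validate()
        self.Tp = np.zeros(shape)
        self.Td = np.zeros(shape)

    def reset(self) -> None:
        self.Tp.fill(0.0)
        self.Td.fill(0.0)


def step_traces(traces: TracePair, H, dt: float, D: float = 0.0) -> None:
    """Forward-Euler update of both traces under Hebbian drive H >= 0.

    The saturating form keeps each trace within [0, Tmax]: the effective
    rate constant is (1 + eta H)/tau and the instantaneous asymptote
    eta H Tmax / (1 + eta H) < Tmax. When the trace parameters enable
    event-boundary erasure, a positive reinforcement transient D adds a
    decay term ``boundary_erase * D * T`` to both traces.
    """
    p = traces.params
    H = np.asarray(H, dtype=float)
    if (H < 0).any():
        raise ValueError("Hebbian activity must be >= 0")
    if np.isfinite(p.h_sat):
        H = np.minimum(H, p.h_sat)
    traces.Tp += (dt / p.tau_p) * (-traces.Tp + p.eta_p * H * (p.tmax_p - traces.Tp))
    traces.Td += (dt / p.tau_d) * (-traces.Td + p.eta_d * H * (p.tmax_d - traces.Td))
    if p.boundary_erase > 0 and D > 0:
        decay = np.exp(-p.boundary_erase * D * dt)
        traces.Tp *= decay
        traces.Td *= decay


@dataclass
class PlasticityConfig:
    """Learning-rate block for one plastic projection."""

    eta: float = 1e-4
    alpha: float = 0.0           # PFC event-boundary gating strength
    rule: str = "dttl"           # 'dttl' or 'dopamine_hebbian'
    w_max: float = 1.0

    def validate(self) -> None:
        if self.eta <= 0:
            raise ValueError("PlasticityConfig.eta must be > 0")
        if self.alpha < 0:
            raise ValueError("PlasticityConfig.alpha must be >= 0")
        if self.w_max <= 0:
            raise ValueError("PlasticityConfig.w_max must be > 0")
        if self.rule not in ("dttl", "dopamine_hebbian"):
            raise ValueError(f"unknown plasticity rule '{self.rule}'")


def apply_weight_update(W: np.ndarray, traces: TracePair, D: float, eta: float,
                        dt: float, w_max: float = np.inf) -> np.ndarray:
    """Competitive dTTL update: dW = eta * D * (Tp - Td) * dt, clipped to [0, w_max]."""
    if D != 0.0:
        W += eta * D * (traces.Tp - traces.Td) * dt
        np.clip(W, 0.0, w_max, out=W)
    return W


def dopamine_hebbian_update(W: np.ndarray, r_pre, r_post, D: float, eta: float,
                            dt: float, w_max: float = np.inf) -> np.ndarray:
    """Dopamine-modulated Hebbian rule dW_ij = eta * D * r_post_i * r_pre_j * dt.

    Used for the Messenger -> VTA GABA pathway; imposes its own fixed point
    by potentiating until the dopamine transient it suppresses reaches D = 0.
    """
    if D != 0.0:
        W += eta * D * np.outer(np.asarray(r_post, float), np.asarray(r_pre, float)) * dt
        np.clip(W, 0.0, w_max, out=W)
    return W


def fixed_point_residual(times: np.ndarray, D: np.ndarray, Tp: np.ndarray,
                         Td: np.ndarray) -> np.ndarray:
    """Trial integral of D(t) (Tp(t) - Td(t)) per synapse.

    A synapse has converged when the residual vanishes: either D = 0
    throughout, or the positive and negative dopamine-weighted trace
    differences cancel over the trial. ``Tp``/``Td`` may carry trailing
    synapse axes; the time axis is axis 0 and must match ``times``/``D``.
    """
    times = np.asarray(times, dtype=float)
    D = np.asarray(D, dtype=float)
    Tp = np.asarray(Tp, dtype=float)
    Td = np.asarray(Td, dtype=float)
    if not (times.shape[0] == D.shape[0] == Tp.shape[0] == Td.shape[0]):
        raise ValueError(
            f"misaligned series: times {times.shape}, D {D.shape}, "
            f"Tp {Tp.shape}, Td {Td.shape}"
        )
    diff = Tp - Td
    integrand = diff * D.reshape((-1,) + (1,) * (diff.ndim - 1))
    return np.trapezoid(integrand, times, axis=0)
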