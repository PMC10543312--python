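"""Fixed random RNN as a candidate universal temporal basis.

A rate network tau du/dt = -u + W phi(u) + I(t) with fixed random recurrent
weights (entries N(0, g^2/K), the standard gain-scaled convention) and tanh
nonlinearity. Each stimulus is a unique random input vector applied as a
100 ms step. The demonstration: the post-cue trajectory depends on which
irrelevant stimuli preceded the cue, so the frozen network state cannot
serve as a repeatable cue-relative clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["RNNSpec", "simulate_rnn", "project_pca", "trajectory_divergence"]


@dataclass
class RNNSpec:
    """Fixed recurrent network: weights drawn once, never learned."""

    K: int = 500              # units
    g: float = 1.5            # recurrent gain (chaotic regime for g > 1)
    tau_net: float = 50.0     # ms
    input_strength: float = 2.0
    input_duration: float = 100.0  # ms step input per stimulus
    seed: int = 0

    W: np.ndarray = field(init=False)
    input_vectors: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        if self.K <= 0 or self.tau_net <= 0:
            raise ValueError("K and tau_net must be positive")
        rng = np.random.default_rng(self.seed)
        self.W = rng.normal(0.0, self.g / np.sqrt(self.K), size=(self.K, self.K))
        self._input_rng = rng
        self.input_vectors = {}

    def input_vector(self, stimulus: str) -> np.ndarray:
        """Unique normally distributed projection per stimulus (cached)."""
        if stimulus not in self.input_vectors:
            self.input_vectors[stimulus] = (
                self.input_strength * self._input_rng.standard_normal(self.K)
                / np.sqrt(self.K)
            )
        return self.input_vectors[stimulus]


def simulate_rnn(spec: RNNSpec, sequence: list[tuple[str, float]],
                 duration: float, dt: float = 1.0,
                 u0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Forward-Euler trajectory; returns (times, states (n_steps, K)).

    ``sequence`` lists (stimulus id, onset ms); each stimulus drives the
    network with its input vector for ``spec.input_duration`` ms.
    Deterministic given the spec and inputs.
    """
    for stim, onset in sequence:
        if not (0 <= onset <= duration):
            raise ValueError(f"stimulus '{stim}' onset {onset} outside [0, {duration}]")
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps) * dt
    u = np.zeros(spec.K) if u0 is None else np.asarray(u0, dtype=float).copy()
    drive = np.zeros((n_steps, spec.K))
    for stim, onset in sequence:
        vec = spec.input_vector(stim)
        on = (times >= onset) & (times < onset + spec.input_duration)
        drive[on] += vec
    states = np.empty((n_steps, spec.K))
    for i in range(n_steps):
        states[i] = u
        u = u + (dt / spec.tau_net) * (-u + spec.W @ np.tanh(u) + drive[i])
    return times, states


def project_pca(trajectories: list[np.ndarray], n_components: int = 2
                ) -> tuple[list[np.ndarray], np.ndarray]:
    """Project trajectories into a shared principal-component frame.

    Axes are fit on the concatenation of all trajectories, so the returned
    projections are directly comparable. Returns (projections, explained
    variance ratios). Degenerate (constant) input is signaled.
    """
    concat = np.concatenate(trajectories, axis=0)
    if concat.shape[0] < 2:
        raise ValueError("need at least 2 time points to fit principal axes")
    if np.allclose(concat.var(axis=0), 0.0):
        raise ValueError("trajectories are constant; principal axes undefined")
    pca = PCA(n_components=n_components)
    pca.fit(concat)
    return [pca.transform(tr) for tr in trajectories], pca.explained_variance_ratio_


def trajectory_divergence(traj_a: np.ndarray, traj_b: np.ndarray,
                          times: np.ndarray, align_at: float,
                          window: float = 1000.0) -> tuple[np.ndarray, float]:
    """State distance between two runs after aligning at an event time.

    Both trajectories must share the sampling grid ``times``. Returns the
    per-time-point Euclidean distance over the post-event window and a
    normalized summary: mean distance divided by the mean state norm over
    the same window (0 for identical histories).
    """
    traj_a = np.asarray(traj_a, dtype=float)
    traj_b = np.asarray(traj_b, dtype=float)
    if traj_a.shape != traj_b.shape:
        raise ValueError(f"misaligned trajectories: {traj_a.shape} vs {traj_b.shape}")
    if traj_a.shape[0] != np.asarray(times).shape[0]:
        raise ValueError("times axis does not match trajectory sampling")
    sel = (times >= align_at) & (times < align_at + window)
    if not sel.any():
        raise ValueError("alignment window contains no samples")
    diff = np.linalg.norm(traj_a[sel] - traj_b[sel], axis=1)
    scale = 0.5 * (np.linalg.norm(traj_a[sel], axis=1)
                   + np.linalg.norm(traj_b[sel], axis=1)).mean()
    summary = float(diff.mean() / scale) if scale > 0 else 0.0
    return diff, summary
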