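"""Reference TD(0)/TD(lambda) learner over a fixed temporal basis.

Implements classical temporal-difference learning with a complete serial
compound (CSC: one microstate per post-cue time bin) or Gaussian-bump
feature basis, used as the contrast model for the spiking network:

* TD(0) exhibits the backward-moving bump of prediction error across trials,
* TD(lambda) with large lambda does not,
* for every variant the per-trial integrated RPE never exceeds the first
  unexpected-reward response: it is conserved for gamma = 1 and decays
  monotonically for gamma < 1.

The value estimate is linear in the features, V(t) = w . phi(t); the
per-step error is delta(t) = r(t) + gamma V(t+1) - V(t), and eligibility
vectors decay by gamma*lambda per step. Updates are applied trial-
synchronously (deltas computed against the weights frozen at trial start,
accumulated, applied at trial end), which makes the gamma = 1 conservation
law exact; a step-online mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import EventSchedule

__all__ = ["TDModel", "td_step", "run_td_session", "integrated_rpe"]


@dataclass
class TDModel:
    """Linear TD learner on a binned trial time axis."""

    n_bins: int
    cs_bin: int                  # first bin carrying cue features
    gamma: float = 1.0
    lam: float = 0.9
    alpha: float = 0.05
    basis: str = "csc"           # 'csc' or 'gaussian'
    gaussian_centers: tuple[int, ...] = ()   # bins of the feature bumps
    gaussian_sigma: float = 1.0  # bump width in bins
    update_mode: str = "offline"  # 'offline' (trial-synchronous) or 'online'

    w: np.ndarray = field(init=False)
    eligibility: np.ndarray = field(init=False)
    _features: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must be in [0, 1]")
        if self.basis not in ("csc", "gaussian"):
            raise ValueError(f"unknown basis '{self.basis}'")
        if self.update_mode not in ("offline", "online"):
            raise ValueError(f"unknown update_mode '{self.update_mode}'")
        if not (0 <= self.cs_bin < self.n_bins):
            raise ValueError("cs_bin must lie inside the trial")
        self._features = self._build_features()
        self.w = np.zeros(self._features.shape[1])
        self.eligibility = np.zeros_like(self.w)

    def _build_features(self) -> np.ndarray:
        """Feature matrix phi, shape (n_bins + 1, n_features); row n_bins = terminal."""
        if self.basis == "csc":
            n_states = self.n_bins - self.cs_bin
            phi = np.zeros((self.n_bins + 1, n_states))
            for t in range(self.cs_bin, self.n_bins):
                phi[t, t - self.cs_bin] = 1.0
            return phi
        centers = np.asarray(self.gaussian_centers, dtype=float)
        if centers.size == 0:
            raise ValueError("gaussian basis requires at least one center")
        t = np.arange(self.n_bins + 1, dtype=float)[:, None]
        phi = np.exp(-0.5 * ((t - centers[None, :]) / self.gaussian_sigma) ** 2)
        phi[self.n_bins] = 0.0      # terminal state
        phi[: self.cs_bin] = 0.0    # no features before the cue
        return phi

    def value(self, t: int) -> float:
        return float(self._features[t] @ self.w)

    def reset_eligibility(self) -> None:
        self.eligibility[:] = 0.0


def td_step(model: TDModel, t: int, reward: float,
            w_eval: np.ndarray | None = None) -> float:
    """One transition t -> t+1: returns the RPE and applies the TD(lambda) update.

    ``w_eval`` evaluates values against frozen weights (trial-synchronous
    mode) while the eligibility-weighted update is accumulated on model.w.
    """
    phi_t = model._features[t]
    phi_next = model._features[t + 1]
    w = model.w if w_eval is None else w_eval
    delta = reward + model.gamma * float(phi_next @ w) - float(phi_t @ w)
    model.eligibility = model.gamma * model.lam * model.eligibility + phi_t
    model.w = model.w + model.alpha * delta * model.eligibility
    return delta


def _reward_vector(schedule: EventSchedule, n_bins: int, bin_ms: float) -> np.ndarray:
    r = np.zeros(n_bins)
    for ev in schedule.rewards:
        b = int(ev.onset // bin_ms)
        if b < n_bins:
            r[b] += ev.magnitude
    return r


def run_td_session(model: TDModel, schedule: EventSchedule, n_trials: int,
                   bin_ms: float = 50.0) -> np.ndarray:
    """Trial-by-trial RPE matrix (n_trials x n_bins) for a single-reward trial."""
    if n_trials == 0:
        return np.zeros((0, model.n_bins))
    if len(schedule.rewards) != 1:
        raise ValueError("run_td_session expects a schedule with a single reward")
    rewards = _reward_vector(schedule, model.n_bins, bin_ms)
    rpe = np.zeros((n_trials, model.n_bins))
    for trial in range(n_trials):
        model.reset_eligibility()
        w_frozen = model.w.copy() if model.update_mode == "offline" else None
        for t in range(model.n_bins):
            rpe[trial, t] = td_step(model, t, rewards[t], w_eval=w_frozen)
    return rpe


def integrated_rpe(rpe_matrix: np.ndarray) -> np.ndarray:
    """Per-trial total RPE (row sums)."""
    return np.asarray(rpe_matrix, dtype=float).sum(axis=1)
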