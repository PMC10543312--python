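"""Trial protocols: event schedules for every conditioning paradigm.

A trial is a fixed-length episode with cue (CS) and reward (US) events;
between trials the network's neuronal state and eligibility traces are reset
(the inter-trial interval is assumed long relative to every trace constant),
while synaptic weights persist. Provided paradigms:

* single-cue trace conditioning (default: CS at 100 ms, reward at 1100 ms,
  40 trials)
* sequential conditioning (CS1 at 100 ms, CS2 at 800 ms, reward at 1500 ms)
* reward-only blocks (pre-training baseline for integrated-signal
  comparisons)
* omission / extinction blocks (cue without reward)
* blocking / unblocking (pre-train one cue, insert a second, optionally
  boost reward magnitude)
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .network import Network, TrialRecording

__all__ = [
    "StimulusEvent",
    "RewardEvent",
    "EventSchedule",
    "Session",
    "trace_conditioning",
    "sequential_conditioning",
    "us_only",
    "omission_extinction",
    "blocking_unblocking",
    "probe_trial",
    "run_session",
]

DEFAULT_CS_DURATION = 150.0   # ms
DEFAULT_US_DURATION = 100.0   # ms


@dataclass
class StimulusEvent:
    stimulus: str
    onset: float
    duration: float = DEFAULT_CS_DURATION
    amplitude: float = 1.0


@dataclass
class RewardEvent:
    onset: float
    magnitude: float = 1.0
    duration: float = DEFAULT_US_DURATION


@dataclass
class EventSchedule:
    """One trial: cue and reward events on a fixed-length time axis (ms)."""

    trial_length: float = 1600.0
    stimuli: list[StimulusEvent] = field(default_factory=list)
    rewards: list[RewardEvent] = field(default_factory=list)
    learning_enabled: bool = True

    def validate(self) -> None:
        if self.trial_length <= 0:
            raise ValueError("trial_length must be > 0")
        for ev in self.stimuli:
            if ev.onset < 0 or ev.onset + ev.duration > self.trial_length:
                raise ValueError(
                    f"stimulus '{ev.stimulus}' at {ev.onset}+{ev.duration} ms exceeds "
                    f"trial length {self.trial_length} ms"
                )
            if ev.amplitude < 0:
                raise ValueError("stimulus amplitude must be >= 0")
        for ev in self.rewards:
            if ev.onset < 0 or ev.onset + ev.duration > self.trial_length:
                raise ValueError("reward event exceeds trial length")
            if ev.magnitude < 0:
                raise ValueError("reward magnitude must be >= 0")

    def stimulus_ids(self) -> set[str]:
        return {ev.stimulus for ev in self.stimuli}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EventSchedule":
        sched = cls(
            trial_length=d["trial_length"],
            stimuli=[StimulusEvent(**s) for s in d.get("stimuli", [])],
            rewards=[RewardEvent(**r) for r in d.get("rewards", [])],
            learning_enabled=d.get("learning_enabled", True),
        )
        sched.validate()
        return sched


@dataclass
class Session:
    """An ordered list of trials, executed with persistent weights."""

    trials: list[EventSchedule]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("a session must contain at least one trial")
        for tr in self.trials:
            tr.validate()

    def __add__(self, other: "Session") -> "Session":
        return Session(self.trials + other.trials,
                       description=f"{self.description}+{other.description}")

    def __len__(self) -> int:
        return len(self.trials)

    def to_dict(self) -> dict:
        return {"description": self.description,
                "trials": [t.to_dict() for t in self.trials]}

    @classmethod
    def from_dict(cls, d: dict) -> "Session":
        return cls([EventSchedule.from_dict(t) for t in d["trials"]],
                   description=d.get("description", ""))


# ---------------------------------------------------------------------------
# Paradigm constructors


def trace_conditioning(n_trials: int = 40, cs_onset: float = 100.0,
                       us_onset: float = 1100.0, trial_length: float = 1600.0,
                       stimulus: str = "cs1", cs_duration: float = DEFAULT_CS_DURATION,
                       reward_magnitude: float = 1.0) -> Session:
    """Single-cue trace conditioning (defaults: 40 trials, CS 100 ms, US 1100 ms)."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive (empty session)")
    if not (0 <= cs_onset < us_onset < trial_length):
        raise ValueError(
            f"need 0 <= cs_onset < us_onset < trial_length, got "
            f"({cs_onset}, {us_onset}, {trial_length})"
        )
    trial = EventSchedule(
        trial_length=trial_length,
        stimuli=[StimulusEvent(stimulus, cs_onset, cs_duration)],
        rewards=[RewardEvent(us_onset, reward_magnitude)],
    )
    trial.validate()
    return Session([trial] * n_trials, description="trace_conditioning")


def sequential_conditioning(n_trials: int = 60, cs1_onset: float = 100.0,
                            cs2_onset: float = 800.0, us_onset: float = 1500.0,
                            trial_length: float = 2000.0,
                            stimuli: tuple[str, str] = ("cs1", "cs2"),
                            cs_duration: float = DEFAULT_CS_DURATION,
                            reward_magnitude: float = 1.0) -> Session:
    """Two-cue sequential conditioning (defaults: 100 / 800 / 1500 ms)."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not (0 <= cs1_onset < cs2_onset < us_onset < trial_length):
        raise ValueError(
            f"need cs1 < cs2 < us < trial_length, got "
            f"({cs1_onset}, {cs2_onset}, {us_onset}, {trial_length})"
        )
    trial = EventSchedule(
        trial_length=trial_length,
        stimuli=[StimulusEvent(stimuli[0], cs1_onset, cs_duration),
                 StimulusEvent(stimuli[1], cs2_onset, cs_duration)],
        rewards=[RewardEvent(us_onset, reward_magnitude)],
    )
    trial.validate()
    return Session([trial] * n_trials, description="sequential_conditioning")


def us_only(n_trials: int = 100, us_onset: float = 1100.0,
            trial_length: float = 1600.0, reward_magnitude: float = 1.0,
            learning_enabled: bool = False) -> Session:
    """Reward-only block (pre-learning baseline; learning off by default)."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    trial = EventSchedule(
        trial_length=trial_length,
        rewards=[RewardEvent(us_onset, reward_magnitude)],
        learning_enabled=learning_enabled,
    )
    trial.validate()
    return Session([trial] * n_trials, description="us_only")


def omission_extinction(trained_session: Session, n_omit: int = 1,
                        mode: str = "single_omission") -> Session:
    """Append cue-only (no reward) trials to a training session.

    ``single_omission`` appends one probe trial; ``repeated_extinction``
    appends ``n_omit`` unrewarded trials.
    """
    if mode not in ("single_omission", "repeated_extinction"):
        raise ValueError(f"unknown mode '{mode}'")
    if mode == "repeated_extinction" and n_omit <= 0:
        raise ValueError("extinction requires n_omit > 0")
    template = trained_session.trials[-1]
    omit = EventSchedule(
        trial_length=template.trial_length,
        stimuli=[StimulusEvent(**asdict(ev)) for ev in template.stimuli],
        rewards=[],
        learning_enabled=template.learning_enabled,
    )
    n = 1 if mode == "single_omission" else n_omit
    return Session(trained_session.trials + [omit] * n,
                   description=f"{trained_session.description}+{mode}")


def blocking_unblocking(phase1_trials: int = 40, phase2_trials: int = 25,
                        reward_boost: float = 1.0, cs1_onset: float = 100.0,
                        cs2_onset: float = 600.0, us_onset: float = 1100.0,
                        trial_length: float = 1600.0) -> Session:
    """Blocking/unblocking: pre-train CS1->US, then insert CS2 before the reward.

    ``reward_boost`` multiplies the phase-2 reward magnitude: 1 reproduces
    blocking (CS2 acquires nothing), > 1 probes unblocking. The default
    timing keeps the CS1-reward delay at the standard 1000 ms (within the
    Timers' learnable range) and inserts CS2 at its midpoint.
    """
    if reward_boost < 1.0:
        raise ValueError("reward_boost must be >= 1")
    phase1 = trace_conditioning(phase1_trials, cs_onset=cs1_onset,
                                us_onset=us_onset, trial_length=trial_length)
    if phase2_trials <= 0:
        return phase1
    phase2 = sequential_conditioning(
        phase2_trials, cs1_onset=cs1_onset, cs2_onset=cs2_onset,
        us_onset=us_onset, trial_length=trial_length,
        reward_magnitude=reward_boost)
    out = phase1 + phase2
    out.description = f"blocking(x{reward_boost})"
    return out


def probe_trial(template: EventSchedule, drop_stimuli: tuple[str, ...] = (),
                drop_reward: bool = False) -> EventSchedule:
    """A non-learning copy of a trial with selected events removed."""
    probe = EventSchedule(
        trial_length=template.trial_length,
        stimuli=[StimulusEvent(**asdict(ev)) for ev in template.stimuli
                 if ev.stimulus not in drop_stimuli],
        rewards=[] if drop_reward else [RewardEvent(**asdict(ev))
                                        for ev in template.rewards],
        learning_enabled=False,
    )
    probe.validate()
    return probe


# ---------------------------------------------------------------------------
# Session runner


def _input_rate_profiles(net: Network, sched: EventSchedule,
                         n_steps: int, dt: float) -> dict[str, np.ndarray]:
    spec = net.spec
    t = np.arange(n_steps) * dt
    rates = {name: np.zeros(n_steps) for name in net.inputs}
    for ev in sched.stimuli:
        chan = f"cs_{ev.stimulus}"
        if chan not in rates:
            raise ValueError(
                f"schedule references stimulus '{ev.stimulus}' but the network has "
                f"no column for it (known: {sorted(net.inputs)})"
            )
        on = (t >= ev.onset) & (t < ev.onset + ev.duration)
        rates[chan][on] += ev.amplitude * spec.cs_rate_hz
    for ev in sched.rewards:
        on = (t >= ev.onset) & (t < ev.onset + ev.duration)
        rates["us"][on] += ev.magnitude * spec.us_rate_hz
    return rates


def run_trial(net: Network, sched: EventSchedule,
              record_counts: tuple[str, ...] = ("da", "gaba"),
              count_bin: float = 50.0,
              record_traces: tuple[str, ...] = ()) -> TrialRecording:
    """Simulate one trial from a reset state; weights carry over."""
    sched.validate()
    spec = net.spec
    dt = spec.dt
    n_steps = int(round(sched.trial_length / dt))
    profiles = _input_rate_profiles(net, sched, n_steps, dt)

    net.reset_state()
    net.learning_enabled = sched.learning_enabled

    times = np.arange(n_steps) * dt
    rates = {name: np.empty(n_steps) for name in net.groups}
    r_da = np.empty(n_steps)
    D = np.empty(n_steps)
    n_bins = int(sched.trial_length // count_bin)
    counts = {name: np.zeros((net.groups[name].n, n_bins))
              for name in record_counts if name in net.groups}
    tr_series = {key: (np.empty(n_steps), np.empty(n_steps))
                 for key in record_traces if net.projections[key].traces is not None}

    for i in range(n_steps):
        input_rates = {name: prof[i] for name, prof in profiles.items()}
        spikes = net.step(input_rates, dt)
        for name, group in net.groups.items():
            rates[name][i] = group.rate_hz.mean()
        r_da[i] = net.r_da_mean
        D[i] = net.reinforcement()
        b = int(times[i] // count_bin)
        if b < n_bins:
            for name, arr in counts.items():
                arr[:, b] += spikes[name]
        for key, (tp, td) in tr_series.items():
            tr = net.projections[key].traces
            mask = net.projections[key].mask
            tp[i] = tr.Tp[mask].mean()
            td[i] = tr.Td[mask].mean()

    weights = {key: proj.mean_weight() for key, proj in net.projections.items()
               if proj.plastic}
    return TrialRecording(times=times, rates=rates, r_da=r_da, D=D,
                          r0=spec.r0, theta=spec.theta, counts=counts,
                          count_bin=count_bin, weights=weights,
                          trace_series=tr_series)


def run_session(net: Network, session: Session,
                record_counts: tuple[str, ...] = ("da", "gaba"),
                count_bin: float = 50.0,
                record_traces: tuple[str, ...] = ()) -> list[TrialRecording]:
    """Run all trials in order; returns one TrialRecording per trial."""
    for sched in session.trials:
        missing = {s for s in sched.stimulus_ids() if f"cs_{s}" not in net.inputs}
        if missing:
            raise ValueError(f"network has no column for stimuli: {sorted(missing)}")
    return [run_trial(net, sched, record_counts, count_bin, record_traces)
            for sched in session.trials]
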