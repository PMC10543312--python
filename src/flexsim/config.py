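"""Experiment configuration: YAML/JSON loading, validation, echoing.

A configuration file has up to six blocks — ``seed``, ``protocol``,
``network``, ``neuron``, ``analysis``, ``output_dir`` — all optional except
``protocol``. Unknown keys anywhere are rejected with their field path, and
every load returns the fully resolved configuration (defaults filled) so
that a run can echo exactly what it used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .lif import NeuronParams
from .network import NetworkSpec
from . import protocols

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "resolve_config", "dump_config"]


class ConfigError(ValueError):
    """Schema violation, reported with the offending field path."""


_PROTOCOL_KINDS = {
    "trace": protocols.trace_conditioning,
    "sequential": protocols.sequential_conditioning,
    "us_only": protocols.us_only,
    "blocking": protocols.blocking_unblocking,
    "unblocking": protocols.blocking_unblocking,
}

_PROTOCOL_KEYS = {
    "trace": {"n_trials", "cs_onset", "us_onset", "trial_length", "stimulus",
              "cs_duration", "reward_magnitude"},
    "sequential": {"n_trials", "cs1_onset", "cs2_onset", "us_onset",
                   "trial_length", "cs_duration", "reward_magnitude"},
    "us_only": {"n_trials", "us_onset", "trial_length", "reward_magnitude",
                "learning_enabled"},
    "blocking": {"phase1_trials", "phase2_trials", "reward_boost", "cs1_onset",
                 "cs2_onset", "us_onset", "trial_length"},
    "unblocking": {"phase1_trials", "phase2_trials", "reward_boost", "cs1_onset",
                   "cs2_onset", "us_onset", "trial_length"},
}


@dataclass
class AnalysisConfig:
    count_bin: float = 50.0
    record_counts: list[str] = field(default_factory=lambda: ["da", "gaba"])

    def validate(self) -> None:
        if self.count_bin <= 0:
            raise ConfigError("analysis.count_bin must be > 0")


@dataclass
class ExperimentConfig:
    """Fully resolved experiment description."""

    protocol_kind: str
    protocol_args: dict
    network: NetworkSpec
    analysis: AnalysisConfig
    seed: int = 0
    output_dir: str = "out"

    def build_session(self) -> protocols.Session:
        return _PROTOCOL_KINDS[self.protocol_kind](**self.protocol_args)

    def to_dict(self) -> dict:
        net = dataclasses.asdict(self.network)
        net.pop("projections", None)
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "protocol": {"kind": self.protocol_kind, **self.protocol_args},
            "network": {k: v for k, v in net.items() if k != "neuron"},
            "neuron": dataclasses.asdict(self.network.neuron),
            "analysis": dataclasses.asdict(self.analysis),
        }


def _apply_block(obj, block: dict, path: str):
    valid = {f.name for f in dataclasses.fields(obj)}
    for key, value in block.items():
        if key not in valid:
            raise ConfigError(f"unknown key '{path}.{key}'")
        current = getattr(obj, key)
        if isinstance(current, bool) and not isinstance(value, bool):
            raise ConfigError(f"type mismatch at '{path}.{key}': expected bool")
        if isinstance(current, (int, float)) and not isinstance(current, bool):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"type mismatch at '{path}.{key}': expected number")
        setattr(obj, key, value)
    return obj


def resolve_config(raw: dict) -> ExperimentConfig:
    """Validate a parsed config dict and fill every default."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known_top = {"seed", "protocol", "network", "neuron", "plasticity",
                 "analysis", "output_dir"}
    for key in raw:
        if key not in known_top:
            raise ConfigError(f"unknown key '{key}'")

    proto = dict(raw.get("protocol") or {})
    kind = proto.pop("kind", "trace")
    if kind not in _PROTOCOL_KINDS:
        raise ConfigError(
            f"unknown protocol.kind '{kind}' (choose from {sorted(_PROTOCOL_KINDS)})"
        )
    bad = set(proto) - _PROTOCOL_KEYS[kind]
    if bad:
        raise ConfigError(f"unknown key 'protocol.{sorted(bad)[0]}' for kind '{kind}'")

    network = NetworkSpec()
    _apply_block(network, dict(raw.get("network") or {}), "network")
    # 'plasticity' block is an alias for the learning-rate fields of the
    # network spec, kept separate in files for readability
    plast_keys = {"eta_cs_da", "eta_tt", "eta_m_gaba", "alpha_boundary",
                  "w_tt_init", "w_tt_max", "w_cs_da_max", "w_m_gaba_max"}
    plast = dict(raw.get("plasticity") or {})
    for key in plast:
        if key not in plast_keys:
            raise ConfigError(f"unknown key 'plasticity.{key}'")
    _apply_block(network, plast, "plasticity")

    neuron = NeuronParams()
    neuron_block = dict(raw.get("neuron") or {})
    alias = {"tau_s": "tau_s_fast"}  # friendlier name in files
    neuron_block = {alias.get(k, k): v for k, v in neuron_block.items()}
    _apply_block(neuron, neuron_block, "neuron")
    try:
        neuron.validate()
    except ValueError as err:
        raise ConfigError(f"neuron block invalid: {err}") from err
    network.neuron = neuron

    if kind == "sequential" or kind in ("blocking", "unblocking"):
        if len(network.stimuli) < 2:
            network.stimuli = ["cs1", "cs2"]
    try:
        network.validate()
    except ValueError as err:
        raise ConfigError(f"network block invalid: {err}") from err

    analysis = AnalysisConfig()
    _apply_block(analysis, dict(raw.get("analysis") or {}), "analysis")
    analysis.validate()

    cfg = ExperimentConfig(
        protocol_kind=kind,
        protocol_args=proto,
        network=network,
        analysis=analysis,
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "out")),
    )
    try:
        cfg.build_session()
    except (TypeError, ValueError) as err:
        raise ConfigError(f"protocol block invalid: {err}") from err
    return cfg


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML or JSON experiment configuration."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return resolve_config(raw)


def dump_config(cfg: ExperimentConfig, path: str | Path) -> None:
    """Write the resolved configuration (defaults filled) as YAML or JSON."""
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
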