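"""End-to-end reproduction drivers: one command per simulation figure.

Each driver generates its inputs, runs the corresponding protocol and
analyses, and writes plotting-ready CSVs plus a manifest (resolved
parameters, seed, package version) sufficient to re-run the experiment
bit-identically. Naming: the cue-conditioning session drivers are

* ``rnn_history``      — fixed-RNN temporal-basis demonstration (PCA
                         trajectories for two stimulus orders)
* ``trace_session``    — 40-trial single-cue trace conditioning with
                         auROC maps and response trajectories
* ``integrated_signal`` — per-trial integrated reinforcement for the
                         spiking model next to TD(lambda) integrated RPE
                         at several discounts
* ``sequential_session`` — two-cue sequential conditioning with stage labels
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    auroc_map,
    counts_from_recordings,
    response_magnitudes,
    stage_classifier,
    trial_integral,
)
from .network import NetworkSpec, build_network, timer_duration
from .protocols import (
    EventSchedule,
    RewardEvent,
    Session,
    StimulusEvent,
    run_session,
    sequential_conditioning,
    trace_conditioning,
    us_only,
)
from .rnn import RNNSpec, project_pca, simulate_rnn, trajectory_divergence
from .td import TDModel, integrated_rpe, run_td_session

__all__ = ["reproduce", "FIGURES", "named_streams"]


def named_streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """Expand one seed into independent named generator streams.

    Streams are keyed by position in ``names``, so adding a stream at the
    end never perturbs the earlier ones.
    """
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _write_manifest(out: Path, figure: str, seed: int, params: dict) -> None:
    manifest = {
        "figure": figure,
        "seed": seed,
        "version": __version__,
        "params": params,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def _rate_frame(recordings, groups) -> pd.DataFrame:
    frames = []
    for i, rec in enumerate(recordings):
        df = pd.DataFrame({"trial": i + 1, "time_ms": rec.times})
        for g in groups:
            df[g] = rec.rates[g]
        df["D"] = rec.D
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def rnn_history(seed: int, out: Path) -> dict:
    """History dependence of a fixed RNN's post-cue trajectory."""
    spec = RNNSpec(seed=seed)
    seq_abc = [("A", 100.0), ("B", 500.0), ("C", 900.0)]
    seq_bac = [("B", 100.0), ("A", 500.0), ("C", 900.0)]
    duration, dt = 2400.0, 1.0
    times, traj_abc = simulate_rnn(spec, seq_abc, duration, dt)
    _, traj_bac = simulate_rnn(spec, seq_bac, duration, dt)
    projections, evr = project_pca([traj_abc, traj_bac])
    div_curve, div_summary = trajectory_divergence(traj_abc, traj_bac, times, 900.0)
    for name, proj in zip(("abc", "bac"), projections):
        pd.DataFrame({"time_ms": times, "pc1": proj[:, 0], "pc2": proj[:, 1]}
                     ).to_csv(out / f"trajectory_{name}.csv", index=False)
    sel = (times >= 900.0) & (times < 1900.0)
    pd.DataFrame({"time_ms": times[sel], "distance": div_curve}
                 ).to_csv(out / "divergence.csv", index=False)
    return {"explained_variance": evr.tolist(),
            "normalized_divergence": div_summary}


def trace_session(seed: int, out: Path, n_trials: int = 40,
                  n_auroc_trials: int = 15) -> dict:
    """Single-cue trace conditioning with auROC maps and response curves."""
    streams = named_streams(seed, ("network", "baseline"))
    spec = NetworkSpec()
    net = build_network(spec, streams["network"])

    # spontaneous baseline trials for the auROC reference distribution
    quiet = Session([EventSchedule(trial_length=1600.0, learning_enabled=False)]
                    * n_auroc_trials, description="baseline")
    base_recs = run_session(net, quiet)

    us_block = us_only(n_auroc_trials)
    us_recs = run_session(net, us_block)

    session = trace_conditioning(n_trials)
    recs = run_session(net, session)

    windows = {"cs": (100.0, 350.0), "us": (1100.0, 1350.0)}
    rows = []
    for i, rec in enumerate(recs):
        rm = response_magnitudes(rec, windows)
        rows.append({
            "trial": i + 1,
            "cs_response_hz": rm["cs"],
            "us_response_hz": rm["us"],
            "integrated_D": trial_integral(rec.D, spec.dt),
            "timer_duration_ms": timer_duration(rec.times, rec.rates["timer_cs1"], 100.0),
            **{f"w_{k}": v for k, v in rec.weights.items()},
        })
    pd.DataFrame(rows).to_csv(out / "learning_curve.csv", index=False)

    stages = {"naive": recs[0], "intermediate": recs[4], "converged": recs[-1]}
    _rate_frame(list(stages.values()),
                ["timer_cs1", "inh_cs1", "msg_cs1", "da", "gaba"]
                ).to_csv(out / "stage_rates.csv", index=False)

    base_counts = counts_from_recordings(base_recs, "da")
    for label, cond in (("before", us_recs),
                        ("during", recs[:n_auroc_trials]),
                        ("after", recs[-n_auroc_trials:])):
        amap = auroc_map(base_counts, counts_from_recordings(cond, "da"))
        values, order = amap.sorted_by_profile()
        pd.DataFrame(values).to_csv(out / f"auroc_{label}.csv", index=False)
        pd.DataFrame({"neuron": order}).to_csv(out / f"auroc_{label}_order.csv", index=False)

    return {"final_cs_response_hz": rows[-1]["cs_response_hz"],
            "final_us_response_hz": rows[-1]["us_response_hz"],
            "final_timer_duration_ms": rows[-1]["timer_duration_ms"]}


def integrated_signal(seed: int, out: Path, n_trials: int = 40,
                      n_us_only: int = 20) -> dict:
    """Per-trial integrated reinforcement: spiking model vs TD(lambda)."""
    streams = named_streams(seed, ("network",))
    spec = NetworkSpec()
    net = build_network(spec, streams["network"])
    us_block = us_only(n_us_only)
    us_recs = run_session(net, us_block)
    session = trace_conditioning(n_trials)
    recs = run_session(net, session)
    flex_rows = [{"trial": i + 1 - n_us_only, "phase": "us_only" if i < n_us_only else "training",
                  "integrated_D": trial_integral(r.D, spec.dt)}
                 for i, r in enumerate(us_recs + recs)]
    pd.DataFrame(flex_rows).to_csv(out / "flex_integrated.csv", index=False)

    schedule = session.trials[0]
    n_bins = int(schedule.trial_length // 50)
    td_rows = []
    for gamma in (1.0, 0.99, 0.95):
        model = TDModel(n_bins=n_bins, cs_bin=2, gamma=gamma, lam=0.9, alpha=0.05)
        rpe = run_td_session(model, schedule, n_us_only + n_trials)
        for i, total in enumerate(integrated_rpe(rpe)):
            td_rows.append({"trial": i + 1 - n_us_only, "gamma": gamma,
                            "integrated_rpe": total})
    pd.DataFrame(td_rows).to_csv(out / "td_integrated.csv", index=False)

    training = [r["integrated_D"] for r in flex_rows if r["phase"] == "training"]
    ref = np.mean([r["integrated_D"] for r in flex_rows if r["phase"] == "us_only"])
    return {"us_only_mean_integral": float(ref),
            "max_training_integral": float(max(training)),
            "max_over_us_only_ratio": float(max(training) / ref)}


def sequential_session(seed: int, out: Path, n_trials: int = 60) -> dict:
    """Two-cue sequential conditioning with learning-stage labels."""
    streams = named_streams(seed, ("network",))
    spec = NetworkSpec(stimuli=["cs1", "cs2"])
    net = build_network(spec, streams["network"])
    session = sequential_conditioning(n_trials)
    recs = run_session(net, session)
    windows = {"cs1": (100.0, 350.0), "cs2": (800.0, 1050.0), "us": (1500.0, 1750.0)}
    labels = stage_classifier(recs, windows["cs1"], windows["cs2"], windows["us"])
    rows = []
    for i, (rec, stage) in enumerate(zip(recs, labels)):
        rm = response_magnitudes(rec, windows)
        rows.append({"trial": i + 1, "stage": stage,
                     "cs1_response_hz": rm["cs1"], "cs2_response_hz": rm["cs2"],
                     "us_response_hz": rm["us"],
                     **{f"w_{k}": v for k, v in rec.weights.items()}})
    pd.DataFrame(rows).to_csv(out / "sequential_curve.csv", index=False)
    _rate_frame([recs[0], recs[-1]], ["timer_cs1", "timer_cs2", "da"]
                ).to_csv(out / "stage_rates.csv", index=False)
    return {"stages": labels, "final_stage": labels[-1]}


FIGURES = {
    "fig2": rnn_history,
    "fig6": trace_session,
    "fig7": integrated_signal,
    "fig8": sequential_session,
}


def reproduce(figure: str, seed: int, out_dir: str | Path, **kwargs) -> dict:
    """Regenerate one simulation figure's data from scratch; returns a summary."""
    if figure not in FIGURES:
        raise ValueError(f"unknown figure id '{figure}' (choose from {sorted(FIGURES)})")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = FIGURES[figure](seed, out, **kwargs)
    _write_manifest(out, figure, seed, {"kwargs": kwargs})
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
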