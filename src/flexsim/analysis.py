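"""Quantitative readouts: auROC maps, per-trial integrals, response stages.

The auROC statistic follows the calcium-imaging convention: time is tiled
into 50 ms bins, and for each neuron and bin the distribution of spike
counts over baseline trials is compared with the distribution over
condition trials by sweeping an integer criterion from zero to the maximum
count and plotting P(active > criterion) against P(baseline > criterion).
The area under that curve is 0.5 for indistinguishable distributions, 1 for
a maximally discriminable increase and 0 for a maximally discriminable
decrease. With every integer criterion included, the trapezoidal area
equals the tie-corrected Mann-Whitney statistic P(a > b) + P(a = b)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import TrialRecording

__all__ = [
    "AUROCMap",
    "auroc",
    "auroc_map",
    "counts_from_recordings",
    "population_psth",
    "peak_response_time",
    "trial_integral",
    "response_magnitudes",
    "stage_classifier",
    "STAGES",
]


def auroc(baseline_counts, active_counts) -> float:
    """Area under the swept-criterion ROC for two spike-count samples."""
    b = np.asarray(baseline_counts, dtype=float).ravel()
    a = np.asarray(active_counts, dtype=float).ravel()
    if b.size == 0 or a.size == 0:
        raise ValueError("auroc requires non-empty baseline and active samples")
    cmax = int(max(b.max(), a.max()))
    # sweep the criterion from the maximum count down to zero: the curve
    # (P(baseline > c), P(active > c)) then runs monotonically from (0, 0)
    # toward (1, 1); a final criterion below every count closes it at (1, 1)
    criteria = np.arange(cmax, -1, -1)
    fpr = (b[None, :] > criteria[:, None]).mean(axis=1)
    tpr = (a[None, :] > criteria[:, None]).mean(axis=1)
    x = np.concatenate((fpr, [1.0]))
    y = np.concatenate((tpr, [1.0]))
    return float(np.trapezoid(y, x))


@dataclass
class AUROCMap:
    """Per-neuron, per-bin auROC values (all in [0, 1])."""

    values: np.ndarray          # (n_neurons, n_bins)
    bin_ms: float = 50.0

    def sorted_by_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """Rows ordered by the time bin of their strongest deviation from 0.5."""
        peak_bin = np.argmax(np.abs(self.values - 0.5), axis=1)
        order = np.argsort(peak_bin, kind="stable")
        return self.values[order], order


def auroc_map(baseline_counts: np.ndarray, active_counts: np.ndarray,
              bin_ms: float = 50.0) -> AUROCMap:
    """auROC per neuron and time bin.

    Inputs are spike-count arrays of shape (n_trials, n_neurons, n_bins);
    trial counts may differ between conditions, neuron/bin axes must match.
    """
    b = np.asarray(baseline_counts)
    a = np.asarray(active_counts)
    if b.ndim != 3 or a.ndim != 3 or b.shape[1:] != a.shape[1:]:
        raise ValueError(
            f"expected (trials, neurons, bins) arrays with matching neuron/bin "
            f"axes, got {b.shape} and {a.shape}"
        )
    n_neurons, n_bins = b.shape[1], b.shape[2]
    values = np.empty((n_neurons, n_bins))
    for i in range(n_neurons):
        for j in range(n_bins):
            values[i, j] = auroc(b[:, i, j], a[:, i, j])
    return AUROCMap(values=values, bin_ms=bin_ms)


def counts_from_recordings(recordings: list[TrialRecording], group: str = "da") -> np.ndarray:
    """Stack per-trial binned spike counts into a (trials, neurons, bins) array."""
    missing = [i for i, r in enumerate(recordings) if group not in r.counts]
    if missing:
        raise ValueError(f"recordings {missing} carry no spike counts for group '{group}'")
    return np.stack([r.counts[group] for r in recordings])


def population_psth(recordings: list[TrialRecording], group: str = "da"
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Trial- and neuron-averaged firing rate from binned spike counts.

    Unlike the online rate estimate (an exponential filter that lags by its
    time constant), the PSTH localizes response peaks to their bin. Returns
    (bin centers in ms, rate in Hz).
    """
    counts = counts_from_recordings(recordings, group)
    bin_ms = recordings[0].count_bin
    rate = counts.mean(axis=(0, 1)) / bin_ms * 1000.0
    centers = (np.arange(counts.shape[2]) + 0.5) * bin_ms
    return centers, rate


def peak_response_time(recordings: list[TrialRecording], group: str = "da",
                       within: tuple[float, float] | None = None) -> float:
    """Time (bin center, ms) of the largest PSTH excursion, optionally
    restricted to a window."""
    centers, rate = population_psth(recordings, group)
    if within is not None:
        sel = (centers >= within[0]) & (centers < within[1])
        centers, rate = centers[sel], rate[sel]
    return float(centers[np.argmax(rate)])


def trial_integral(signal, dt: float) -> float:
    """dt-weighted (rectangle-rule) integral of a time series."""
    return float(np.asarray(signal, dtype=float).sum() * dt)


def response_magnitudes(recording: TrialRecording,
                        windows: dict[str, tuple[float, float]],
                        group: str = "da") -> dict[str, float]:
    """Mean DA-rate excess over baseline r0 within each named window (Hz)."""
    t = recording.times
    rate = recording.rates[group]
    out = {}
    for name, (lo, hi) in windows.items():
        if lo < 0 or hi > t[-1] + (t[1] - t[0]):
            raise ValueError(f"window '{name}' = ({lo}, {hi}) outside trial")
        sel = (t >= lo) & (t < hi)
        out[name] = float(rate[sel].mean() - recording.r0)
    return out


STAGES = ("initialization", "acquisition", "reward_depression", "serial_transfer")


def stage_classifier(recordings: list[TrialRecording],
                     cs1_window: tuple[float, float],
                     cs2_window: tuple[float, float],
                     us_window: tuple[float, float],
                     threshold_frac: float = 0.25,
                     smooth: int = 3) -> list[str]:
    """Label each sequential-conditioning trial with its learning stage.

    The sign pattern of (CS1, CS2, US) responses — each thresholded at
    ``threshold_frac`` of the trial-1 US response — maps to:
    (0,0,+) initialization, (+,+,+) acquisition, (+,+,0) reward_depression,
    (+,0,0) serial_transfer. Any other pattern is labeled 'transitional'.
    Responses are median-smoothed over ``smooth`` trials before
    classification to suppress single-trial noise.
    """
    if not recordings:
        raise ValueError("no recordings to classify")
    windows = {"cs1": cs1_window, "cs2": cs2_window, "us": us_window}
    resp = np.array([
        [response_magnitudes(r, windows)[k] for k in ("cs1", "cs2", "us")]
        for r in recordings
    ])
    ref = resp[0, 2]
    if ref <= 0:
        raise ValueError("trial-1 US response is non-positive; cannot set thresholds")
    thr = threshold_frac * ref
    if smooth > 1:
        k = smooth
        pad = k // 2
        padded = np.pad(resp, ((pad, pad), (0, 0)), mode="edge")
        resp = np.stack([
            np.median(padded[i:i + k], axis=0) for i in range(len(recordings))
        ])
    labels = []
    pattern_map = {
        (False, False, True): "initialization",
        (True, True, True): "acquisition",
        (True, True, False): "reward_depression",
        (True, False, False): "serial_transfer",
    }
    for cs1, cs2, us in resp:
        key = (cs1 > thr, cs2 > thr, us > thr)
        labels.append(pattern_map.get(key, "transitional"))
    return labels
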