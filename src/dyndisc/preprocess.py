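"""Downsampling, spike removal, onset detection, epochs, and deflection.

Raw experimental signals arrive at 20 kHz (simulations at 10 kHz) and are
reduced to 1 kHz by block averaging.  Spikes in membrane-potential traces are
suppressed with a 5 ms sliding median.  The per-trial *deflection* — the
absolute difference between a pre-stimulus baseline and the mean of a 166 ms
response window around the cross-trial-mean peak — is the classic tuning-curve
statistic that the dynamical pipeline is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CellRecord, Recording


@dataclass(frozen=True)
class EpochWindow:
    name: str  # "on" | "full" | "off"
    start_ms: float
    end_ms: float

    def __post_init__(self):
        if not self.start_ms < self.end_ms:
            raise ValueError("epoch start must precede end")

    def slice(self) -> slice:
        return slice(int(round(self.start_ms)), int(round(self.end_ms)))


@dataclass
class DeflectionRecord:
    trial_id: str
    stimulus_index: int
    baseline: float
    window: tuple[float, float]
    deflection: float


def downsample(raw: np.ndarray, fs: float) -> np.ndarray:
    """Block-average a series at ``fs`` Hz down to 1 kHz.

    Each output sample is the mean of the ``fs/1000`` consecutive raw samples
    in its 1 ms block; a trailing partial block is dropped.
    """
    raw = np.asarray(raw, dtype=float)
    block = fs / 1000.0
    if block != int(block) or block <= 0:
        raise ValueError("sampling rate must be a positive multiple of 1000 Hz")
    block = int(block)
    n = len(raw) // block
    return raw[: n * block].reshape(n, block).mean(axis=1)


def remove_spikes(series: np.ndarray, window_ms: int = 5) -> np.ndarray:
    """Centered sliding-median filter (5 ms default) with truncated edges."""
    x = np.asarray(series, dtype=float)
    if len(x) < window_ms:
        raise ValueError(f"series shorter than the {window_ms} ms window")
    half = window_ms // 2
    out = np.empty_like(x)
    # interior: vectorized via a strided window stack
    if len(x) >= window_ms:
        from numpy.lib.stride_tricks import sliding_window_view

        out[half: len(x) - half] = np.median(
            sliding_window_view(x, window_ms), axis=1
        )
    # edges: symmetric windows truncated to the available half-width
    for i in range(half):
        out[i] = np.median(x[: 2 * i + 1])
        out[len(x) - 1 - i] = np.median(x[len(x) - 1 - 2 * i:])
    return out


def _running_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centered running average with truncated edges."""
    c = np.cumsum(np.concatenate(([0.0], x)))
    n = len(x)
    half = w // 2
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def detect_onset(trials: list[np.ndarray] | list[Recording]) -> float:
    """Estimate the stimulus-onset time (ms) of a cell from all its trials.

    Cross-trial mean -> 50 ms running average -> largest extremum (relative to
    the mean of its first 100 ms) in the first half -> 50 ms binning -> the
    largest-magnitude first-difference at or before the extremum's bin marks
    the onset bin -> subtract 100 ms -> round to the nearest 25 ms.
    """
    series = [
        np.asarray(t.samples if isinstance(t, Recording) else t, dtype=float)
        for t in trials
    ]
    if len(series) < 2:
        raise ValueError("need >=2 trials for onset detection")
    n = min(len(s) for s in series)
    if n < 200:
        raise ValueError("series shorter than 200 ms")
    mean = np.mean([s[:n] for s in series], axis=0)
    smooth = _running_mean(mean, 50)
    dev = np.abs(smooth - smooth[:100].mean())
    half_n = n // 2
    if np.max(dev[:half_n]) <= 1e-12 * max(1.0, np.max(np.abs(smooth))):
        raise ValueError("no response detected")
    peak_idx = int(np.argmax(dev[:half_n]))
    # 50 ms bins of the (unsmoothed) cross-trial mean
    nbins = n // 50
    binned = mean[: nbins * 50].reshape(nbins, 50).mean(axis=1)
    deriv = np.diff(binned)  # deriv[k] = binned[k+1] - binned[k]
    peak_bin = min(peak_idx // 50, nbins - 1)
    # largest-magnitude derivative immediately prior to (into) the extremum bin
    upto = max(peak_bin, 1)
    k = int(np.argmax(np.abs(deriv[:upto]))) + 1  # bin the rise lands in
    onset_ms = k * 50 - 100
    return round(onset_ms / 25.0) * 25.0


def epoch_windows(t_on: float, t_off: float) -> dict[str, EpochWindow]:
    """The three response epochs derived from the on/off times (ms)."""
    if not t_on < t_off:
        raise ValueError("require t_on < t_off")
    return {
        "on": EpochWindow("on", t_on, t_on + 250.0),
        "full": EpochWindow("full", t_on, t_off + 250.0),
        "off": EpochWindow("off", t_off - 70.0, t_off + 250.0),
    }


def _min_variance_baseline(series: np.ndarray, t_on: float) -> tuple[float, int]:
    """Mean of the minimum-variance 100 ms window starting in
    [t_on-200, t_on-100] (1 ms steps, ties -> earliest start)."""
    if t_on < 200:
        raise ValueError("t_on < 200 ms: no room for baseline search")
    starts = np.arange(int(t_on) - 200, int(t_on) - 100 + 1)
    from numpy.lib.stride_tricks import sliding_window_view

    wins = sliding_window_view(series, 100)[starts]
    best = int(np.argmin(wins.var(axis=1)))
    return float(wins[best].mean()), int(starts[best])


def response_window(
    cross_trial_mean: np.ndarray, epoch: EpochWindow, t_on: float
) -> tuple[int, int]:
    """The 166 ms response window around the cross-trial-mean peak in
    ``epoch`` (raw mean; peak = largest |mean - baseline| sample)."""
    base, _ = _min_variance_baseline(cross_trial_mean, t_on)
    sl = epoch.slice()
    seg = np.abs(cross_trial_mean[sl] - base)
    peak = sl.start + int(np.argmax(seg))
    if peak - sl.start < 66:
        start = sl.start + (peak - sl.start) // 2
    else:
        start = peak - 66
    end = min(start + 166, len(cross_trial_mean))
    return int(start), int(end)


def compute_deflection(
    trial: Recording,
    epoch: EpochWindow,
    cross_trial_mean: np.ndarray,
) -> DeflectionRecord:
    """Absolute deflection of one trial within the epoch's response window."""
    baseline, _ = _min_variance_baseline(trial.samples, trial.t_on)
    start, end = response_window(cross_trial_mean, epoch, trial.t_on)
    deflection = abs(float(trial.samples[start:end].mean()) - baseline)
    return DeflectionRecord(
        trial_id=trial.trial_id,
        stimulus_index=trial.stimulus_index,
        baseline=baseline,
        window=(float(start), float(end)),
        deflection=deflection,
    )


def cell_deflections(
    cell: CellRecord, epoch_name: str = "on"
) -> list[DeflectionRecord]:
    """Deflection records for every trial of a cell, using the cross-trial
    mean (over the common prefix length) to locate the response window."""
    n = min(len(t.samples) for t in cell.trials)
    mean = np.mean([t.samples[:n] for t in cell.trials], axis=0)
    recs = []
    for t in cell.trials:
        epoch = epoch_windows(t.t_on, t.t_off)[epoch_name]
        recs.append(compute_deflection(t, epoch, mean))
    return recs
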