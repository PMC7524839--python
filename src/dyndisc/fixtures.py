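"""Deterministic synthetic trial stores for tests and demos.

Each trial is baseline + a stimulus-dependent step (the deflection) + a
stimulus-dependent damped oscillation + Gaussian noise, at 1 kHz with
embedded on/off times.  Tuning shapes mirror the taxonomy seen in cortical
recordings (ramp, sigmoid, Gaussian); the damped second-order oscillation is
the minimal stimulus-coded dynamical structure a 3-D embedding with a cubic
library can represent, so the genetic search has a recoverable ground truth.
A Gaussian (non-invertible) deflection tuning with distinct per-stimulus
frequencies produces stimuli that deflection decoding confuses but dynamical
discrimination separates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CellRecord, Recording, TrialStore


@dataclass
class FixtureSpec:
    n_stimuli: int = 6
    trials_per_stimulus: int = 11  # matches the typical repeat count
    tuning_shape: str = "ramp"  # ramp | sigmoid | gaussian
    deflection_scale: float = 10.0  # signal units (pA or mV)
    osc_freqs_hz: tuple | None = None  # per stimulus; default 8..8+5k Hz
    osc_amp: float = 3.0
    osc_decay_ms: float = 120.0
    noise_sd: float = 0.5
    baseline: float = -60.0
    t_on: float = 300.0
    t_off: float = 900.0
    trial_len_ms: int = 1400
    signal_kind: str = "potential_spikes_removed"
    stimulus_axis: str = "size"
    seed: int = 0


def tuning_curve(spec: FixtureSpec) -> np.ndarray:
    """Per-stimulus deflection means for the chosen tuning shape."""
    i = np.arange(1, spec.n_stimuli + 1, dtype=float)
    u = (i - 1) / (spec.n_stimuli - 1)
    if spec.tuning_shape == "ramp":
        shape = u
    elif spec.tuning_shape == "sigmoid":
        shape = 1.0 / (1.0 + np.exp(-10 * (u - 0.5)))
    elif spec.tuning_shape == "gaussian":
        shape = np.exp(-((u - 0.5) ** 2) / (2 * 0.2**2))
    else:
        raise ValueError(f"unknown tuning shape {spec.tuning_shape!r}")
    return spec.deflection_scale * shape


def generate_fixture(spec: FixtureSpec) -> TrialStore:
    """Seed-deterministic synthetic store; validates under the trial-store
    contract."""
    rng = np.random.default_rng(spec.seed)
    deflections = tuning_curve(spec)
    freqs = spec.osc_freqs_hz
    if freqs is None:
        freqs = tuple(8.0 + 5.0 * k for k in range(spec.n_stimuli))
    t = np.arange(spec.trial_len_ms, dtype=float)
    on = (t >= spec.t_on) & (t < spec.t_off)
    t_rel = np.clip(t - spec.t_on, 0, None)
    cell = CellRecord(
        cell_id="synthetic_cell", signal_kind=spec.signal_kind,
        stimulus_axis=spec.stimulus_axis,
    )
    for stim in range(1, spec.n_stimuli + 1):
        f = freqs[stim - 1]
        for rep in range(spec.trials_per_stimulus):
            phase = rng.uniform(0, 2 * np.pi)
            osc = (
                spec.osc_amp
                * np.exp(-t_rel / spec.osc_decay_ms)
                * np.sin(2 * np.pi * f * t_rel / 1000.0 + phase)
            )
            series = (
                spec.baseline
                + deflections[stim - 1] * on
                + osc * on
                + rng.normal(0, spec.noise_sd, len(t))
            )
            cell.trials.append(
                Recording(
                    samples=series,
                    stimulus_index=stim,
                    t_on=spec.t_on,
                    t_off=spec.t_off,
                    trial_id=f"s{stim:02d}_r{rep:02d}",
                )
            )
    store = TrialStore(cells=[cell])
    store.validate()
    return store
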