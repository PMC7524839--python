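"""Trial stores, run configuration, and deterministic seeding.

A :class:`TrialStore` holds per-cell lists of 1 kHz recordings with stimulus
labels and stimulus on/off times.  The canonical on-disk format is HDF5 (one
group per cell, one dataset per trial); a CSV-per-trial directory with a JSON
manifest is supported as an import/export convenience.  Time is in
milliseconds throughout and series are index-aligned: sample ``k`` of a trial
is at ``k`` ms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

SIGNAL_KINDS = (
    "excitatory_current",
    "inhibitory_current",
    "potential_spikes_kept",
    "potential_spikes_removed",
)
STIMULUS_AXES = ("orientation", "size", "contrast", "rho")

FORMAT_VERSION = "1"


class TrialStoreError(ValueError):
    """Raised when a store violates the trial-store contract."""


@dataclass
class Recording:
    """One trial: a scalar series at 1 kHz plus stimulus metadata.

    ``samples`` are in pA (current) or mV (potential); ``t_on``/``t_off`` are
    the stimulus on/off times in ms, index-aligned with ``samples``.
    """

    samples: np.ndarray
    stimulus_index: int
    t_on: float
    t_off: float
    trial_id: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def validate(self) -> None:
        if self.samples.ndim != 1:
            raise TrialStoreError(f"trial {self.trial_id}: samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise TrialStoreError(
                f"trial {self.trial_id}: samples contain NaN/inf"
            )
        if self.t_on is None or self.t_off is None:
            raise TrialStoreError(f"trial {self.trial_id}: missing t_on/t_off")
        if not (self.t_on < self.t_off):
            raise TrialStoreError(
                f"trial {self.trial_id}: require t_on < t_off"
            )
        if self.t_off >= len(self.samples):
            raise TrialStoreError(
                f"trial {self.trial_id}: t_off beyond end of series"
            )
        if self.stimulus_index < 1:
            raise TrialStoreError(
                f"trial {self.trial_id}: stimulus_index must be >= 1"
            )


@dataclass
class CellRecord:
    """All trials of one cell recorded in one signal mode."""

    cell_id: str
    signal_kind: str
    stimulus_axis: str
    trials: list[Recording] = field(default_factory=list)

    def validate(self, warn: callable = None) -> None:
        if self.signal_kind not in SIGNAL_KINDS:
            raise TrialStoreError(
                f"cell {self.cell_id}: unknown signal_kind {self.signal_kind!r}"
            )
        if self.stimulus_axis not in STIMULUS_AXES:
            raise TrialStoreError(
                f"cell {self.cell_id}: unknown stimulus_axis "
                f"{self.stimulus_axis!r}"
            )
        for t in self.trials:
            t.validate()
        ordinals = sorted({t.stimulus_index for t in self.trials})
        if self.trials:
            if len(ordinals) < 2:
                raise TrialStoreError(
                    f"cell {self.cell_id}: need >=2 distinct stimulus ordinals"
                )
            if ordinals != list(range(1, len(ordinals) + 1)):
                raise TrialStoreError(
                    f"cell {self.cell_id}: non-contiguous ordinals {ordinals}"
                )
            if warn is not None:
                counts = self.counts_per_stimulus()
                for s, n in counts.items():
                    if not (3 <= n <= 21):
                        warn(
                            f"cell {self.cell_id}: stimulus {s} has {n} "
                            "examples (expected 3-21)"
                        )

    def counts_per_stimulus(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for t in self.trials:
            counts[t.stimulus_index] = counts.get(t.stimulus_index, 0) + 1
        return counts

    @property
    def n_stimuli(self) -> int:
        return len({t.stimulus_index for t in self.trials})


@dataclass
class TrialStore:
    cells: list[CellRecord] = field(default_factory=list)
    format_version: str = FORMAT_VERSION

    def validate(self, warn: callable = None) -> None:
        for c in self.cells:
            c.validate(warn=warn)

    def cell(self, cell_id: str) -> CellRecord:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)


@dataclass
class RunConfig:
    """Resolved hyperparameters for one pipeline run.

    Defaults are the selected operating point: 100 one-millisecond delays
    reduced to 3 dimensions by SVD, cubic polynomial library with first-order
    derivatives, GA population 300 / 45 elites with the published mutation
    schedule, 0.2 sparsity regularization weight, 5-tree interim and 51-tree
    final forests, and the stimulus-onset epoch.
    """

    # embedding
    n_delays: int = 100
    delay_ms: int = 1
    dims: int = 3
    mask_boundaries: bool = False
    # sindy
    max_degree: int = 3
    derivative_order: int = 1  # pass-through; only 1 is exercised
    # genetic algorithm
    population: int = 300
    elites: int = 45
    generations_per_3cols: int = 100
    generations: int | None = None  # explicit override for scaled runs
    seed_mutation_rate: float = 0.15
    gen1_mutation_rate: float = 0.05
    sparsity_weight: float = 0.2
    # decoding
    interim_trees: int = 5
    final_trees: int = 51
    holdout_fraction: float = 0.25
    objective_repeats: int = 10
    outer_repeats: int = 20
    # preprocessing
    epoch: str = "on"
    # seeding
    seed: int = 0

    def resolved_generations(self, d_out: int) -> int:
        if self.generations is not None:
            return int(self.generations)
        return int(self.generations_per_3cols * int(np.ceil(d_out / 3)))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise TrialStoreError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent stage seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# HDF5 dialect (canonical)
# ---------------------------------------------------------------------------

def _write_hdf5(store: TrialStore, path: Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = store.format_version
        fh.attrs["sampling_rate_hz"] = 1000
        for cell in store.cells:
            g = fh.create_group(f"cells/{cell.cell_id}")
            g.attrs["signal_kind"] = cell.signal_kind
            g.attrs["stimulus_axis"] = cell.stimulus_axis
            for i, tr in enumerate(cell.trials):
                ds = g.create_dataset(f"trial_{i:05d}", data=tr.samples)
                ds.attrs["trial_id"] = tr.trial_id
                ds.attrs["stimulus_index"] = int(tr.stimulus_index)
                ds.attrs["t_on"] = float(tr.t_on)
                ds.attrs["t_off"] = float(tr.t_off)


def _read_hdf5(path: Path) -> TrialStore:
    store = TrialStore(cells=[])
    with h5py.File(path, "r") as fh:
        store.format_version = str(fh.attrs.get("format_version", FORMAT_VERSION))
        cells_grp = fh.get("cells")
        if cells_grp is not None:
            for cell_id in sorted(cells_grp):
                g = cells_grp[cell_id]
                cell = CellRecord(
                    cell_id=cell_id,
                    signal_kind=str(g.attrs["signal_kind"]),
                    stimulus_axis=str(g.attrs["stimulus_axis"]),
                )
                for name in sorted(g):
                    ds = g[name]
                    attrs = dict(ds.attrs)
                    if "t_on" not in attrs or "t_off" not in attrs:
                        raise TrialStoreError(
                            f"trial {attrs.get('trial_id', name)}: "
                            "missing t_on/t_off"
                        )
                    cell.trials.append(
                        Recording(
                            samples=np.asarray(ds[()], dtype=float),
                            stimulus_index=int(attrs["stimulus_index"]),
                            t_on=float(attrs["t_on"]),
                            t_off=float(attrs["t_off"]),
                            trial_id=str(attrs["trial_id"]),
                        )
                    )
                store.cells.append(cell)
    return store


# ---------------------------------------------------------------------------
# CSV + JSON-manifest dialect
# ---------------------------------------------------------------------------

def _write_csv(store: TrialStore, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"format_version": store.format_version, "cells": []}
    for cell in store.cells:
        entry = {
            "cell_id": cell.cell_id,
            "signal_kind": cell.signal_kind,
            "stimulus_axis": cell.stimulus_axis,
            "trials": [],
        }
        for i, tr in enumerate(cell.trials):
            fname = f"{cell.cell_id}_trial_{i:05d}.csv"
            np.savetxt(path / fname, tr.samples, fmt="%.17g")
            entry["trials"].append(
                {
                    "file": fname,
                    "trial_id": tr.trial_id,
                    "stimulus_index": int(tr.stimulus_index),
                    "t_on": float(tr.t_on),
                    "t_off": float(tr.t_off),
                }
            )
        manifest["cells"].append(entry)
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _read_csv(path: Path) -> TrialStore:
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    store = TrialStore(
        cells=[], format_version=manifest.get("format_version", FORMAT_VERSION)
    )
    for entry in manifest["cells"]:
        cell = CellRecord(
            cell_id=entry["cell_id"],
            signal_kind=entry["signal_kind"],
            stimulus_axis=entry["stimulus_axis"],
        )
        for t in entry["trials"]:
            if "t_on" not in t or "t_off" not in t:
                raise TrialStoreError(
                    f"trial {t.get('trial_id', t['file'])}: missing t_on/t_off"
                )
            samples = np.atleast_1d(np.loadtxt(path / t["file"], dtype=float))
            cell.trials.append(
                Recording(
                    samples=samples,
                    stimulus_index=int(t["stimulus_index"]),
                    t_on=float(t["t_on"]),
                    t_off=float(t["t_off"]),
                    trial_id=str(t["trial_id"]),
                )
            )
        store.cells.append(cell)
    return store


def write_trial_store(store: TrialStore, path: str | Path) -> None:
    """Write a validated store; HDF5 if ``path`` is a file path, CSV if a
    directory (or path ending without ``.h5``/``.hdf5`` that already exists as
    a directory)."""
    store.validate()
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_hdf5(store, path)
    else:
        _write_csv(store, path)


def read_trial_store(path: str | Path, warn: callable = None) -> TrialStore:
    """Read and validate a trial store from HDF5 or a CSV+manifest directory."""
    path = Path(path)
    if path.is_dir():
        store = _read_csv(path)
    else:
        store = _read_hdf5(path)
    store.validate(warn=warn)
    return store
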