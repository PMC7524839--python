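"""Time-delay dimensionality expansion (Hankel matrix + SVD).

The scalar epochs of interest from all trials of a cell are concatenated,
stacked into a Hankel matrix of ``n_delays + 1`` time-shifted rows, and
reduced by SVD.  Trajectory coordinates are the singular-value-scaled
right-singular-vector time courses (principal-component scores), so that
amplitude information survives the expansion.  Rows are deliberately not
Z-scored.  After slicing the embedded points back into per-trial
trajectories, the grand mean point over the whole cell is subtracted so the
trajectory cloud is centered at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CellRecord
from .preprocess import EpochWindow, epoch_windows


@dataclass
class EmbeddingBasis:
    n_delays: int
    delay_ms: int
    singular_values: np.ndarray
    modes: np.ndarray  # left singular vectors, (n_delays+1, d_kept)
    d_kept: int
    grand_mean: np.ndarray = field(default=None)


@dataclass
class Trajectory:
    points: np.ndarray  # (T, d)
    trial_id: str
    stimulus_index: int
    centered: bool = False

    def __len__(self) -> int:
        return len(self.points)


def build_hankel(series: np.ndarray, n_delays: int) -> np.ndarray:
    """Hankel matrix with ``n_delays + 1`` rows; row k is the series shifted
    by k samples; ``len(series) - n_delays`` columns."""
    x = np.asarray(series, dtype=float)
    if len(x) <= n_delays:
        raise ValueError("series must be longer than n_delays")
    ncols = len(x) - n_delays
    from numpy.lib.stride_tricks import sliding_window_view

    # sliding windows of length ncols, one per shift
    return sliding_window_view(x, ncols)[: n_delays + 1].copy()


def expand_series(
    segments: list[np.ndarray],
    n_delays: int = 100,
    d: int = 3,
    delay_ms: int = 1,
    mask_boundaries: bool = False,
) -> tuple[EmbeddingBasis, list[np.ndarray]]:
    """Embed a list of per-trial scalar segments into per-trial trajectories.

    Segments are concatenated before building the Hankel matrix (delay windows
    may straddle trial boundaries); each embedded point is assigned to the
    segment that owns its first, undelayed sample.  With
    ``mask_boundaries=True``, points whose delay window crosses a boundary are
    dropped instead.  Returns the basis and one (T_i, d) array per segment,
    already centered on the grand mean.
    """
    if d > n_delays + 1:
        raise ValueError("cannot keep more dimensions than Hankel rows")
    concat = np.concatenate([np.asarray(s, dtype=float) for s in segments])
    H = build_hankel(concat, n_delays)
    # SVD via the small Gram matrix: H = U S Vt with H H^T = U S^2 U^T
    G = H @ H.T
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    svals = np.sqrt(evals)
    U = evecs[:, order]
    # scores = S * Vt rows = U^T H ; keep first d rows -> (ncols, d)
    scores = (U[:, :d].T @ H).T
    # deterministic sign convention: largest-|.| element of each mode positive
    for j in range(d):
        col = U[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            U[:, j] = -col
            scores[:, j] = -scores[:, j]
    basis = EmbeddingBasis(
        n_delays=n_delays,
        delay_ms=delay_ms,
        singular_values=svals,
        modes=U[:, :d].copy(),
        d_kept=d,
    )
    grand_mean = scores.mean(axis=0)
    scores = scores - grand_mean
    basis.grand_mean = grand_mean

    # slice back into per-segment trajectories by the first (undelayed) sample
    lengths = [len(s) for s in segments]
    bounds = np.cumsum([0] + lengths)
    ncols = H.shape[1]
    out: list[np.ndarray] = []
    for i in range(len(segments)):
        lo, hi = bounds[i], min(bounds[i + 1], ncols)
        if mask_boundaries:
            hi = min(hi, bounds[i + 1] - n_delays)
        out.append(scores[lo:hi] if hi > lo else scores[lo:lo])
    return basis, out


def expand_and_center(
    cell: CellRecord,
    epoch_name: str = "on",
    n_delays: int = 100,
    d: int = 3,
    delay_ms: int = 1,
    mask_boundaries: bool = False,
) -> tuple[EmbeddingBasis, list[Trajectory]]:
    """Delay-embed the chosen epoch of every trial of a cell."""
    segments = []
    for t in cell.trials:
        epoch = epoch_windows(t.t_on, t.t_off)[epoch_name]
        seg = t.samples[epoch.slice()]
        if len(seg) == 0:
            raise ValueError(f"trial {t.trial_id}: epoch outside series")
        segments.append(seg)
    basis, arrays = expand_series(
        segments,
        n_delays=n_delays,
        d=d,
        delay_ms=delay_ms,
        mask_boundaries=mask_boundaries,
    )
    trajs = [
        Trajectory(
            points=a,
            trial_id=t.trial_id,
            stimulus_index=t.stimulus_index,
            centered=True,
        )
        for a, t in zip(arrays, cell.trials)
    ]
    return basis, trajs
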