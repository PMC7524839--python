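"""Tuning curves, reliability, and association statistics.

The tuning curve D_i is the mean absolute deflection per stimulus; its
reliability R_i = mean/std across repeats; the least/most similarity
S_i = min(|i - argmin D|, |i - argmax D|)/N measures ordinal distance to the
nearer of the least- and most-preferred stimuli.  Noise measures (coefficient
of variation, mean normalized residual) decompose why reliability varies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CellRecord


@dataclass
class TuningSummary:
    stimuli: np.ndarray  # ordinals, 1..N
    mean_deflection: np.ndarray  # D_i
    reliability: np.ndarray  # R_i (nan where std == 0)
    reliability_defined: np.ndarray  # bool flags
    similarity: np.ndarray  # S_i in [0, 1/2]
    key_distance: np.ndarray  # ordinal distance to nearer extreme


@dataclass
class NoiseSummary:
    trial_ids: list
    cv: np.ndarray
    mean_residual: np.ndarray
    mean_abs_residual: np.ndarray
    frac_excluded: np.ndarray


def tuning_summary(deflections, stimulus_ordinals) -> TuningSummary:
    """Per-stimulus deflection tuning curve and derived quantities.

    Ties in argmin/argmax of D are broken toward the lower ordinal.
    """
    d = np.asarray(deflections, dtype=float)
    s = np.asarray(stimulus_ordinals, dtype=int)
    stimuli = np.unique(s)
    N = len(stimuli)
    if N < 2:
        raise ValueError("need >=2 stimuli")
    D = np.array([d[s == i].mean() for i in stimuli])
    std = np.array([d[s == i].std(ddof=1) if (s == i).sum() > 1 else np.nan
                    for i in stimuli])
    defined = np.isfinite(std) & (std > 0)
    R = np.where(defined, D / np.where(std > 0, std, np.nan), np.nan)
    i_min = stimuli[int(np.argmin(D))]
    i_max = stimuli[int(np.argmax(D))]
    key = np.minimum(np.abs(stimuli - i_min), np.abs(stimuli - i_max))
    return TuningSummary(
        stimuli=stimuli,
        mean_deflection=D,
        reliability=R,
        reliability_defined=defined,
        similarity=key / N,
        key_distance=key,
    )


def noise_summary(cell: CellRecord, eps: float = 1e-9) -> NoiseSummary:
    """Per-trial fluctuation (CV) and noise (normalized residual) measures.

    Residuals compare each trial to the leave-self-in cross-trial mean
    response of its own stimulus; samples where |mean response| < eps (in
    units of the mean absolute response) are excluded and the excluded
    fraction reported.
    """
    by_stim: dict[int, list] = {}
    for t in cell.trials:
        by_stim.setdefault(t.stimulus_index, []).append(t)
    ids, cvs, mres, mares, fexc = [], [], [], [], []
    for stim, trials in sorted(by_stim.items()):
        if len(trials) < 2:
            raise ValueError(f"stimulus {stim}: need >=2 trials")
        n = min(len(t.samples) for t in trials)
        mean_resp = np.mean([t.samples[:n] for t in trials], axis=0)
        thresh = eps * max(float(np.mean(np.abs(mean_resp))), 1e-300)
        ok = np.abs(mean_resp) >= thresh
        for t in trials:
            x = t.samples[:n]
            mu = float(x.mean())
            cvs.append(float(x.std(ddof=1)) / mu if mu != 0 else np.nan)
            resid = (x[ok] - mean_resp[ok]) / mean_resp[ok]
            mres.append(float(resid.mean()) if len(resid) else np.nan)
            mares.append(float(np.abs(resid).mean()) if len(resid) else np.nan)
            fexc.append(1.0 - ok.mean())
            ids.append(t.trial_id)
    return NoiseSummary(
        trial_ids=ids,
        cv=np.array(cvs),
        mean_residual=np.array(mres),
        mean_abs_residual=np.array(mares),
        frac_excluded=np.array(fexc),
    )


def association_stats(x, y, paired: bool = True) -> dict:
    """Pearson r (two-sided), simple-difference-formula effect size, and a
    one-tailed Wilcoxon test with direction chosen by the median difference.

    r_SDF = P(x > y) - P(x < y) over matched pairs (paired data only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with >=3 values")
    pr, pp = stats.pearsonr(x, y)
    if paired:
        diff = x - y
        r_sdf = float(np.mean(diff > 0) - np.mean(diff < 0))
        alternative = "greater" if np.median(diff) >= 0 else "less"
        if np.all(diff == 0):
            wp = 1.0
        else:
            wp = float(
                stats.wilcoxon(x, y, alternative=alternative).pvalue
            )
    else:
        r_sdf = float("nan")
        alternative = "greater" if np.median(x) >= np.median(y) else "less"
        wp = float(stats.ranksums(x, y, alternative=alternative).pvalue)
    return {
        "pearson_r": float(pr),
        "pearson_p": float(pp),
        "r_sdf": r_sdf,
        "wilcoxon_p": wp,
    }


def deflection_decile_table(deflections, values, n_deciles: int = 10):
    """Median of ``values`` within deciles of normalized deflection
    (reporting helper for U-shape style summaries)."""
    d = np.asarray(deflections, dtype=float)
    v = np.asarray(values, dtype=float)
    dn = (d - d.min()) / (d.max() - d.min()) if d.max() > d.min() else d * 0
    edges = np.quantile(dn, np.linspace(0, 1, n_deciles + 1))
    rows = []
    for k in range(n_deciles):
        lo, hi = edges[k], edges[k + 1]
        sel = (dn >= lo) & (dn <= hi if k == n_deciles - 1 else dn < hi)
        rows.append(
            {"decile": k + 1, "n": int(sel.sum()),
             "median_value": float(np.median(v[sel])) if sel.any() else np.nan}
        )
    return rows
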