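"""Objective functions, the 45-classifier ensemble, and the decoders.

The genetic algorithm scores a mask by how well random forests classify (or
regress) the stimulus from the Xi coefficients fitted under that mask: the
error term (1 - mean macro-F1, or 1 - R^2) carries 80% of the fitness and the
mask density (fraction of live terms) the remaining 20%.  The final decoder
is an ensemble of one forest per elite mask, voting by mode (classification,
ties broken by the highest-ranked elite) or median (regression).  Honest
out-of-sample numbers come from an outer protocol that holds out one example
of every stimulus, runs the entire pipeline on the remainder, and repeats 20
times; scrambling the labels first (surrogate mode) measures the overfitting
floor.  Baseline decoders: a forest on the scalar deflection, and a
maximum-likelihood classifier on axial/radial phase-space occupancy maps.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.ensemble import (
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.metrics import f1_score

from .evolve import (
    Individual,
    Mask,
    MutationSchedule,
    TrajectoryData,
    fit_all,
    prepare_trajectories,
    run_evolution,
)
from .io import RunConfig
from .sindy import LibrarySpec, build_library, multi_step_prediction


@dataclass
class ObjectiveResult:
    fitness: float
    error_term: float
    sparsity_term: float


@dataclass
class F1Summary:
    per_label: dict
    macro: float
    ccr: float
    n_predictions: int = 0


@dataclass
class EnsembleModel:
    members: list  # (Individual, fitted estimator) pairs, best rank last
    task: str  # "classify" | "regress"


def summarize_predictions(y_true, y_pred) -> F1Summary:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = sorted(set(y_true))
    per = f1_score(y_true, y_pred, labels=labels, average=None,
                   zero_division=0.0)
    keys = [lab.item() if hasattr(lab, "item") else lab for lab in labels]
    return F1Summary(
        per_label=dict(zip(keys, per.tolist())),
        macro=float(np.mean(per)),
        ccr=float(np.mean(y_true == y_pred)),
        n_predictions=len(y_true),
    )


def _holdout_split(labels: np.ndarray, frac: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Boolean holdout mask taking ceil(frac * n_i) (>=1) of each label."""
    labels = np.asarray(labels)
    hold = np.zeros(len(labels), dtype=bool)
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        k = max(1, int(np.ceil(frac * len(idx))))
        hold[rng.choice(idx, size=k, replace=False)] = True
    return hold


def _features(data: list[TrajectoryData], mask: Mask,
              library: LibrarySpec) -> np.ndarray:
    from .evolve import feature_matrix

    return feature_matrix(data, mask)


def make_classification_objective(
    data: list[TrajectoryData],
    labels,
    library: LibrarySpec,
    rng: np.random.Generator,
    interim_trees: int = 5,
    repeats: int = 10,
    holdout_fraction: float = 0.25,
    sparsity_weight: float = 0.2,
    regression: bool = False,
):
    """Build the GA objective closure.

    Fits Xi per trajectory under the mask, then ``repeats`` rounds of
    per-stimulus 25% holdout with a small interim forest; the error term is
    1 - mean macro-F1 (classification) or 1 - mean R^2 (regression of the
    continuous label), clipped to [0, 1].
    """
    y = np.asarray(labels)
    uniq, counts = np.unique(y, return_counts=True)
    if not regression:
        if len(uniq) < 2:
            raise ValueError("need >=2 labels")
        if counts.min() < 2:
            raise ValueError("every label needs >=2 examples")

    def objective(mask: Mask, *, details: bool = False):
        X = _features(data, mask, library)
        scores = []
        for _ in range(repeats):
            hold = _holdout_split(y, holdout_fraction, rng)
            if regression:
                est = RandomForestRegressor(
                    n_estimators=interim_trees,
                    max_features=1 / 3,  # the classic bagged-tree default
                    random_state=int(rng.integers(2**31)),
                    n_jobs=1,
                )
                est.fit(X[~hold], y[~hold])
                pred = est.predict(X[hold])
                ss_res = float(((y[hold] - pred) ** 2).sum())
                ss_tot = float(((y[hold] - y[hold].mean()) ** 2).sum())
                scores.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
            else:
                est = RandomForestClassifier(
                    n_estimators=interim_trees,
                    random_state=int(rng.integers(2**31)),
                    n_jobs=1,
                )
                est.fit(X[~hold], y[~hold])
                pred = est.predict(X[hold])
                per = f1_score(y[hold], pred, labels=uniq, average=None,
                               zero_division=0.0)
                scores.append(float(np.mean(per)))
        error = float(np.clip(1.0 - np.mean(scores), 0.0, 1.0))
        sparsity = mask.density()
        fitness = (1 - sparsity_weight) * error + sparsity_weight * sparsity
        if details:
            return ObjectiveResult(fitness, error, sparsity)
        return fitness

    return objective


def make_gof_objective(
    data: list[TrajectoryData],
    library: LibrarySpec,
    n_steps: int = 4,
    sparsity_weight: float = 0.2,
):
    """Goodness-of-fit objective.

    From every trajectory point, Euler-integrate the fitted ODE 4 timesteps
    and compare the *derivatives* the model predicts at the endpoint against
    the data's estimated derivatives 4 steps ahead, via pooled R^2; the
    error term is mean(1 - R^2) over trajectories, clipped to [0, 1].
    (Comparing states instead is uninformative at 1 kHz: over 4 ms any
    fit trivially tracks the trajectory's slow drift.)
    """
    from .sindy import rhs

    def objective(mask: Mask, *, details: bool = False):
        coeffs = fit_all(data, mask, library)
        errs = []
        for td, cm in zip(data, coeffs):
            pts = td.points
            if len(pts) <= n_steps:
                errs.append(1.0)
                continue
            end_states = multi_step_prediction(cm, pts[:-n_steps],
                                               n_steps=n_steps)
            pred = rhs(cm, end_states)
            obs = td.dV[n_steps:]
            ss_res = float(np.sum((obs - pred) ** 2))
            ss_tot = float(np.sum((obs - obs.mean(axis=0)) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
            errs.append(float(np.clip(1.0 - r2, 0.0, 1.0)))
        error = float(np.mean(errs))
        sparsity = mask.density()
        fitness = (1 - sparsity_weight) * error + sparsity_weight * sparsity
        if details:
            return ObjectiveResult(fitness, error, sparsity)
        return fitness

    return objective


def train_ensemble(
    elites: list[Individual],
    data: list[TrajectoryData],
    labels,
    library: LibrarySpec,
    rng: np.random.Generator,
    final_trees: int = 51,
    task: str = "classify",
) -> EnsembleModel:
    """One forest per elite mask, trained on that mask's Xi features."""
    y = np.asarray(labels)
    members = []
    for ind in elites:
        X = _features(data, ind.mask, library)
        if task == "regress":
            est = RandomForestRegressor(
                n_estimators=final_trees, max_features=1 / 3,
                random_state=int(rng.integers(2**31)), n_jobs=1,
            )
        else:
            est = RandomForestClassifier(
                n_estimators=final_trees,
                random_state=int(rng.integers(2**31)), n_jobs=1,
            )
        est.fit(X, y)
        members.append((ind, est))
    return EnsembleModel(members=members, task=task)


def ensemble_predict(
    model: EnsembleModel,
    data: list[TrajectoryData],
    library: LibrarySpec,
) -> np.ndarray:
    """Mode of the member votes (ties -> highest-ranked member's vote) for
    classification; member median for regression."""
    votes = []
    ranks = []
    for ind, est in model.members:
        X = _features(data, ind.mask, library)
        votes.append(est.predict(X))
        ranks.append(ind.rank if ind.rank is not None else 0)
    votes = np.stack(votes)  # (n_members, n_trials)
    if model.task == "regress":
        return np.median(votes, axis=0)
    best_member = int(np.argmax(ranks))
    out = []
    for j in range(votes.shape[1]):
        counts = Counter(votes[:, j])
        top = max(counts.values())
        tied = {k for k, v in counts.items() if v == top}
        if len(tied) == 1:
            out.append(next(iter(tied)))
        else:
            bv = votes[best_member, j]
            out.append(bv if bv in tied else sorted(tied)[0])
    return np.array(out)


# ---------------------------------------------------------------------------
# Full pipeline on embedded trajectories
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    elites: list[Individual]
    model: EnsembleModel
    history: object
    library: LibrarySpec


def fit_pipeline(
    train_points: list[np.ndarray],
    train_labels,
    rng: np.random.Generator,
    config: RunConfig | None = None,
    task: str = "classify",
) -> PipelineResult:
    """Seed -> evolve -> train the final ensemble, on training data only."""
    config = config or RunConfig()
    library = build_library(config.dims, config.max_degree)
    data = prepare_trajectories(train_points, library, labels=train_labels)
    objective = make_classification_objective(
        data,
        train_labels,
        library,
        rng,
        interim_trees=config.interim_trees,
        repeats=config.objective_repeats,
        holdout_fraction=config.holdout_fraction,
        sparsity_weight=config.sparsity_weight,
        regression=(task == "regress"),
    )
    schedule = MutationSchedule(
        r_init=config.seed_mutation_rate, r_gen1=config.gen1_mutation_rate
    )
    elites, history = run_evolution(
        data,
        library,
        objective,
        rng,
        population=config.population,
        n_elites=config.elites,
        total_gens=config.resolved_generations(config.dims),
        schedule=schedule,
    )
    model = train_ensemble(
        elites, data, train_labels, library, rng,
        final_trees=config.final_trees, task=task,
    )
    return PipelineResult(elites=elites, model=model, history=history,
                          library=library)


def predict_pipeline(result: PipelineResult,
                     points: list[np.ndarray]) -> np.ndarray:
    data = prepare_trajectories(points, result.library)
    return ensemble_predict(result.model, data, result.library)


def outer_holdout(
    points: list[np.ndarray],
    labels,
    rng: np.random.Generator,
    config: RunConfig | None = None,
    repeats: int | None = None,
    surrogate: bool = False,
    task: str = "classify",
) -> F1Summary:
    """The outer hold-one-out protocol on embedded trajectories.

    Each repetition holds out one randomly chosen example of every stimulus,
    runs the whole pipeline (seeding, evolution, ensemble training) on the
    remainder, and predicts the held-out trials.  ``surrogate=True`` scrambles
    the labels first, which turns the run into an overfitting control.
    """
    config = config or RunConfig()
    if repeats is None:
        repeats = config.outer_repeats
    y = np.asarray(labels)
    if surrogate:
        y = rng.permutation(y)
    uniq, counts = np.unique(y, return_counts=True)
    if counts.min() < 3:
        raise ValueError("need >=3 examples per stimulus for the outer holdout")
    y_true_all, y_pred_all = [], []
    for _ in range(repeats):
        hold = np.zeros(len(y), dtype=bool)
        for lab in uniq:
            idx = np.where(y == lab)[0]
            hold[rng.choice(idx)] = True
        train_pts = [p for p, h in zip(points, hold) if not h]
        test_pts = [p for p, h in zip(points, hold) if h]
        result = fit_pipeline(train_pts, y[~hold], rng, config, task=task)
        pred = predict_pipeline(result, test_pts)
        y_true_all.extend(y[hold])
        y_pred_all.extend(pred)
    return summarize_predictions(y_true_all, y_pred_all)


# ---------------------------------------------------------------------------
# Deflection baseline decoder
# ---------------------------------------------------------------------------

def deflection_decoder(
    deflections,
    labels,
    rng: np.random.Generator,
    repeats: int = 20,
    n_trees: int = 51,
) -> F1Summary:
    """Random forest on the single deflection feature under the same outer
    hold-one-out protocol."""
    X = np.asarray(deflections, dtype=float).reshape(-1, 1)
    y = np.asarray(labels)
    uniq, counts = np.unique(y, return_counts=True)
    if counts.min() < 3:
        raise ValueError("need >=3 examples per stimulus")
    y_true_all, y_pred_all = [], []
    for _ in range(repeats):
        hold = np.zeros(len(y), dtype=bool)
        for lab in uniq:
            hold[rng.choice(np.where(y == lab)[0])] = True
        est = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        est.fit(X[~hold], y[~hold])
        y_true_all.extend(y[hold])
        y_pred_all.extend(est.predict(X[hold]))
    return summarize_predictions(y_true_all, y_pred_all)


# ---------------------------------------------------------------------------
# Occupancy-map maximum-likelihood decoder
# ---------------------------------------------------------------------------

@dataclass
class OccupancyMap:
    """Axial (z) x radial (r) occupancy densities over a fixed grid."""

    z_edges: np.ndarray
    r_edges: np.ndarray
    axis: np.ndarray
    centers: dict = field(default_factory=dict)  # stimulus -> central point
    stimulus_maps: dict = field(default_factory=dict)

    FLOOR = 1e-12

    def histogram(self, zr: np.ndarray, smooth_bins: float = 1.0) -> np.ndarray:
        h, _, _ = np.histogram2d(zr[:, 0], zr[:, 1],
                                 bins=(self.z_edges, self.r_edges))
        h = gaussian_filter(h, sigma=smooth_bins, mode="constant")
        s = h.sum()
        return h / s if s > 0 else np.full_like(h, 1.0 / h.size)


def _cylindrical(points: np.ndarray, center: np.ndarray,
                 axis: np.ndarray) -> np.ndarray:
    """(z, r) coordinates of points about an axis through ``center``; the
    angular coordinate is computed implicitly and discarded."""
    c = points - center
    z = c @ axis
    r = np.linalg.norm(c - np.outer(z, axis), axis=1)
    return np.column_stack([z, r])


def mle_occupancy_decoder(
    points: list[np.ndarray],
    labels,
    rng: np.random.Generator,
    z_bins: int = 20,
    r_bins: int = 10,
    reps: int = 510,
    train_fraction: float = 0.75,
    smooth_bins: float = 1.0,
) -> F1Summary:
    """Classify held-out 3-D trajectories by phase-space occupancy.

    Per repetition: per stimulus, take 75% of its trajectories, subtract the
    set's central point, pool the centered training points to define a common
    principal axis and a (z, r) grid, and kernel-smooth each stimulus's
    histogram into a density map.  Each held-out trajectory is then placed in
    every candidate stimulus's frame (centered by that stimulus's central
    point — the subtraction that makes the joint probabilities comparable),
    histogrammed the same way, and assigned to the stimulus maximizing the
    occupancy-weighted log likelihood.
    """
    y = np.asarray(labels)
    uniq, counts = np.unique(y, return_counts=True)
    if counts.min() < 4:
        raise ValueError("need >=4 examples per stimulus")
    pts = [np.asarray(p, dtype=float) for p in points]
    if pts[0].shape[1] != 3:
        raise ValueError("occupancy decoder expects 3-D trajectories")
    y_true_all, y_pred_all = [], []
    floor = OccupancyMap.FLOOR
    for _ in range(reps):
        hold = _holdout_split(y, 1.0 - train_fraction, rng)
        centers = {}
        centered_by_stim = {}
        for lab in uniq:
            idx = np.where((y == lab) & ~hold)[0]
            cloud = np.concatenate([pts[i] for i in idx])
            centers[lab] = cloud.mean(axis=0)
            centered_by_stim[lab] = cloud - centers[lab]
        pooled = np.concatenate(list(centered_by_stim.values()))
        # first principal axis of the pooled centered training cloud
        _, _, Vt = np.linalg.svd(pooled - pooled.mean(axis=0),
                                 full_matrices=False)
        axis = Vt[0]
        zr_by_stim = {
            lab: _cylindrical(cloud + centers[lab], centers[lab], axis)
            for lab, cloud in centered_by_stim.items()
        }
        zr_pool = np.concatenate(list(zr_by_stim.values()))
        omap = OccupancyMap(
            z_edges=np.linspace(zr_pool[:, 0].min(), zr_pool[:, 0].max(),
                                z_bins + 1),
            r_edges=np.linspace(0.0, zr_pool[:, 1].max(), r_bins + 1),
            axis=axis,
            centers=centers,
        )
        for lab in uniq:
            omap.stimulus_maps[lab] = omap.histogram(zr_by_stim[lab],
                                                     smooth_bins)
        for i in np.where(hold)[0]:
            scores = {}
            for lab, ms in omap.stimulus_maps.items():
                zr = _cylindrical(pts[i], centers[lab], axis)
                mt = omap.histogram(zr, smooth_bins)
                log_mt = np.log(np.maximum(mt, floor))
                scores[lab] = float(np.sum(
                    mt * (np.log(np.maximum(ms, floor)) + log_mt)
                ))
            pred = max(sorted(scores), key=lambda lab: scores[lab])
            y_true_all.append(y[i])
            y_pred_all.append(pred)
    return summarize_predictions(y_true_all, y_pred_all)


# ---------------------------------------------------------------------------
# State-variable decoder (reliability + deflection regressed from Xi)
# ---------------------------------------------------------------------------

def state_variable_decoder(
    points: list[np.ndarray],
    labels,
    reliabilities: dict,
    mean_deflections: dict,
    rng: np.random.Generator,
    config: RunConfig | None = None,
    repeats: int | None = None,
) -> F1Summary:
    """Decode the stimulus through two predicted latent state variables.

    Ensemble regressors (median vote) map each trial's Xi features to its
    stimulus's reliability and mean deflection; a third random forest
    classifies the stimulus from the two predictions.  Evaluated under the
    outer hold-one-out protocol.
    """
    config = config or RunConfig()
    if repeats is None:
        repeats = config.outer_repeats
    y = np.asarray(labels)
    uniq, counts = np.unique(y, return_counts=True)
    if counts.min() < 3:
        raise ValueError("need >=3 examples per stimulus")
    rel = np.array([reliabilities[lab] for lab in y], dtype=float)
    defl = np.array([mean_deflections[lab] for lab in y], dtype=float)
    y_true_all, y_pred_all = [], []
    for _ in range(repeats):
        hold = np.zeros(len(y), dtype=bool)
        for lab in uniq:
            hold[rng.choice(np.where(y == lab)[0])] = True
        tr = ~hold
        train_pts = [p for p, t in zip(points, tr) if t]
        res = fit_pipeline(train_pts, y[tr], rng, config, task="classify")
        data_tr = prepare_trajectories(train_pts, res.library)
        data_te = prepare_trajectories(
            [p for p, h in zip(points, hold) if h], res.library
        )
        rel_model = train_ensemble(res.elites, data_tr, rel[tr], res.library,
                                   rng, final_trees=config.final_trees,
                                   task="regress")
        defl_model = train_ensemble(res.elites, data_tr, defl[tr],
                                    res.library, rng,
                                    final_trees=config.final_trees,
                                    task="regress")
        Z_tr = np.column_stack([
            ensemble_predict(rel_model, data_tr, res.library),
            ensemble_predict(defl_model, data_tr, res.library),
        ])
        Z_te = np.column_stack([
            ensemble_predict(rel_model, data_te, res.library),
            ensemble_predict(defl_model, data_te, res.library),
        ])
        clf = RandomForestClassifier(
            n_estimators=config.final_trees,
            random_state=int(rng.integers(2**31)), n_jobs=1,
        )
        clf.fit(Z_tr, y[tr])
        y_true_all.extend(y[hold])
        y_pred_all.extend(clf.predict(Z_te))
    return summarize_predictions(y_true_all, y_pred_all)
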