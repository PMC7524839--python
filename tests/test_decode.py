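import numpy as np
import pytest
from scipy import stats

from dyndisc import decode
from dyndisc.evolve import Individual, Mask, prepare_trajectories
from dyndisc.io import RunConfig
from dyndisc.sindy import build_library


def _damped_osc_trajs(freqs_hz, n_per, rng, noise=0.02, n=400):
    """3-D trajectories whose rotation frequency codes the label."""
    pts, labels = [], []
    t = np.arange(n)
    for lab, f in enumerate(freqs_hz, start=1):
        for _ in range(n_per):
            ph = rng.uniform(0, 2 * np.pi)
            w = 2 * np.pi * f / 1000
            x = np.cos(w * t + ph) * np.exp(-t / 2000)
            y = np.sin(w * t + ph) * np.exp(-t / 2000)
            z = 0.3 * np.cos(2 * w * t + ph)
            arr = np.column_stack([x, y, z])
            arr += rng.normal(0, noise, arr.shape)
            pts.append(arr)
            labels.append(lab)
    return pts, np.array(labels)


@pytest.fixture(scope="module")
def osc_dataset():
    rng = np.random.default_rng(11)
    return _damped_osc_trajs([5, 11, 23], 8, rng)


class TestObjectiveArithmetic:
    def test_separable_features_fitness_is_sparsity_share(self, osc_dataset):
        # if classification is perfect the fitness is 0.2 * density
        pts, labels = osc_dataset
        lib = build_library(3)
        data = prepare_trajectories(pts, lib, labels=labels)
        rng = np.random.default_rng(0)
        obj = decode.make_classification_objective(
            data, labels, lib, rng, interim_trees=15, repeats=5
        )
        bits = np.zeros((20, 3), dtype=np.uint8)
        bits[:4] = 1  # 12/60 nonzero
        mask = Mask.repair(bits)
        res = obj(mask, details=True)
        assert res.sparsity_term == pytest.approx(0.2)
        if res.error_term < 1e-9:  # perfectly separable case
            assert res.fitness == pytest.approx(0.04)
        assert res.fitness == pytest.approx(
            0.8 * res.error_term + 0.2 * res.sparsity_term
        )

    def test_shuffled_labels_near_chance(self, osc_dataset):
        pts, labels = osc_dataset
        lib = build_library(3)
        rng = np.random.default_rng(1)
        shuffled = rng.permutation(labels)
        data = prepare_trajectories(pts, lib, labels=shuffled)
        obj = decode.make_classification_objective(
            data, shuffled, lib, rng, interim_trees=5, repeats=10
        )
        res = obj(Mask.repair(np.ones((20, 3), np.uint8)), details=True)
        # mean macro-F1 should sit near chance (1/3); well below perfect
        assert res.error_term > 0.4

    def test_gof_perfect_model_limit(self):
        # a linear system the library represents exactly: error ~ 0
        lib = build_library(1)
        t = np.arange(500.0)
        v = np.exp(-0.005 * t)[:, None]
        data = prepare_trajectories([v], lib)
        obj = decode.make_gof_objective(data, lib)
        bits = np.array([[1], [1], [0], [0]], dtype=np.uint8)
        res = obj(Mask.repair(bits), details=True)
        assert res.error_term < 1e-3
        assert res.fitness == pytest.approx(0.2 * res.sparsity_term,
                                            abs=1e-3)

    def test_gof_constant_only_on_oscillation_is_poor(self):
        lib = build_library(1)
        t = np.arange(500.0)
        v = np.sin(2 * np.pi * 30 * t / 1000)[:, None]
        data = prepare_trajectories([v], lib)
        obj = decode.make_gof_objective(data, lib)
        bits = np.array([[1], [0], [0], [0]], dtype=np.uint8)
        res = obj(Mask.repair(bits), details=True)
        assert res.error_term > 0.9


class TestEnsemble:
    def _model(self, votes_fn, ranks):
        class Stub:
            def __init__(self, v):
                self.v = v

            def predict(self, X):
                return np.array([self.v] * len(X))

        members = [
            (Individual(Mask.repair(np.ones((4, 1), np.uint8)), 0.0,
                        rank=r), Stub(v))
            for r, v in zip(ranks, votes_fn)
        ]
        return decode.EnsembleModel(members=members, task="classify")

    def test_majority_vote(self):
        model = self._model(["A"] * 23 + ["B"] * 22, range(1, 46))
        model.task = "classify"
        lib = build_library(1)
        data = prepare_trajectories([np.sin(np.arange(100.0) / 5)[:, None]],
                                    lib)
        assert decode.ensemble_predict(model, data, lib)[0] == "A"

    def test_tie_broken_by_best_ranked_member(self):
        votes = ["A"] * 15 + ["B"] * 15 + ["C"] * 15
        ranks = list(range(1, 46))
        # highest rank (45) is the last member, voting C
        model = self._model(votes, ranks)
        lib = build_library(1)
        data = prepare_trajectories([np.sin(np.arange(100.0) / 5)[:, None]],
                                    lib)
        assert decode.ensemble_predict(model, data, lib)[0] == "C"

    def test_regression_median(self):
        model = self._model(list(range(1, 46)), range(1, 46))
        model.task = "regress"
        lib = build_library(1)
        data = prepare_trajectories([np.sin(np.arange(100.0) / 5)[:, None]],
                                    lib)
        assert decode.ensemble_predict(model, data, lib)[0] == 23

    def test_train_ensemble_cardinality(self, osc_dataset):
        pts, labels = osc_dataset
        lib = build_library(3)
        data = prepare_trajectories(pts, lib, labels=labels)
        rng = np.random.default_rng(2)
        elites = [
            Individual(Mask.repair(
                rng.integers(0, 2, (20, 3)).astype(np.uint8)), 0.1 * i,
                rank=i + 1)
            for i in range(7)
        ]
        model = decode.train_ensemble(elites, data, labels, lib, rng,
                                      final_trees=5)
        assert len(model.members) == 7


class TestSummaries:
    def test_f1_and_ccr_ranges(self):
        s = decode.summarize_predictions([1, 1, 2, 2, 3, 3],
                                         [1, 2, 2, 2, 3, 1])
        assert 0 <= s.ccr <= 1 and 0 <= s.macro <= 1
        assert set(s.per_label) == {1, 2, 3}

    def test_constant_classifier_balanced_ccr_is_chance(self):
        y = [1, 2, 3, 4] * 5
        s = decode.summarize_predictions(y, [1] * 20)
        assert s.ccr == pytest.approx(0.25)


class TestDeflectionDecoder:
    def test_disjoint_distributions_ccr_near_one(self):
        rng = np.random.default_rng(3)
        labels = np.repeat([1, 2, 3], 10)
        defl = labels * 10.0 + rng.normal(0, 0.1, 30)
        s = decode.deflection_decoder(defl, labels, rng, repeats=10)
        assert s.ccr > 0.95

    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([1, 2, 3], 12)
        defl = rng.normal(0, 1, 36)
        s = decode.deflection_decoder(defl, labels, rng, repeats=20)
        lo, hi = stats.binom.interval(0.99, s.n_predictions, 1 / 3)
        assert lo <= s.ccr * s.n_predictions <= hi


class TestMLEDecoder:
    def _cigar(self, rng, center_z, n, spread=0.3):
        z = rng.normal(center_z, 1.0, n)
        x = rng.normal(0, spread, n)
        y = rng.normal(0, spread, n)
        return np.column_stack([z, x, y])

    def test_disjoint_axial_ranges_perfect(self):
        rng = np.random.default_rng(5)
        pts = [self._cigar(rng, z, 300) for z in [-6] * 6 + [6] * 6]
        labels = np.array([1] * 6 + [2] * 6)
        s = decode.mle_occupancy_decoder(pts, labels, rng, reps=20)
        assert s.ccr == 1.0

    def test_identical_occupancy_near_chance(self):
        rng = np.random.default_rng(6)
        pts = [self._cigar(rng, 0, 300) for _ in range(16)]
        labels = np.array([1, 2] * 8)
        s = decode.mle_occupancy_decoder(pts, labels, rng, reps=40)
        lo, hi = stats.binom.interval(0.999, s.n_predictions, 0.5)
        assert lo <= s.ccr * s.n_predictions <= hi

    def test_too_few_examples_rejected(self):
        rng = np.random.default_rng(7)
        pts = [self._cigar(rng, 0, 50) for _ in range(5)]
        with pytest.raises(ValueError):
            decode.mle_occupancy_decoder(pts, [1, 1, 1, 2, 2], rng, reps=2)


@pytest.fixture(scope="module")
def fast_config():
    return RunConfig(population=50, elites=10, generations=4,
                     objective_repeats=3, interim_trees=5,
                     final_trees=15)


class TestOuterHoldout:

    def test_separable_dynamics_high_ccr(self, osc_dataset, fast_config):
        pts, labels = osc_dataset
        rng = np.random.default_rng(8)
        s = decode.outer_holdout(pts, labels, rng, config=fast_config,
                                 repeats=3)
        assert s.ccr > 0.8

    def test_surrogate_labels_within_chance_band(self, osc_dataset,
                                                 fast_config):
        pts, labels = osc_dataset
        rng = np.random.default_rng(9)
        s = decode.outer_holdout(pts, labels, rng, config=fast_config,
                                 repeats=4, surrogate=True)
        lo, hi = stats.binom.interval(0.999, s.n_predictions, 1 / 3)
        assert lo <= s.ccr * s.n_predictions <= hi


class TestStateVariableDecoder:
    def test_injective_state_map_decodes(self, osc_dataset):
        pts, labels = osc_dataset
        rng = np.random.default_rng(10)
        rel = {1: 1.0, 2: 5.0, 3: 9.0}
        defl = {1: 2.0, 2: 20.0, 3: 50.0}
        cfg = RunConfig(population=50, elites=10, generations=3,
                        objective_repeats=3, final_trees=15)
        s = decode.state_variable_decoder(pts, labels, rel, defl, rng,
                                          config=cfg, repeats=2)
        assert s.ccr > 0.6
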