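"""Under-sampling contracts and AdaBoost team selection vs a step-by-step oracle."""

import math

import numpy as np
import pytest

from eiodetect import (
    BaseClassifierSpec,
    ConfigError,
    EnsembleModel,
    LabeledDataset,
    TrainingError,
    ValidationError,
    adaboost_select,
    fit_single,
    train_pool,
    undersample_subsets,
)
from eiodetect.ensemble import ClassifierPool


def make_dataset(n_neg, n_pos, rng, d=3):
    X = np.vstack([
        rng.normal(0.0, 1.0, size=(n_neg, d)),
        rng.normal(1.5, 1.0, size=(n_pos, d)),
    ])
    y = np.concatenate([np.zeros(n_neg, int), np.ones(n_pos, int)])
    sids = np.array([f"s{i % 5}" for i in range(n_neg + n_pos)], dtype=object)
    return LabeledDataset(X, y, sids)


class FixedScorer:
    """A 'trained' member that returns canned probabilities per row index."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, float)

    def score(self, X):
        X = np.atleast_2d(X)
        # rows carry their index in column 0
        idx = X[:, 0].astype(int)
        return self.probs[idx]


def index_dataset(labels):
    """Dataset whose single feature is the row index (for FixedScorer pools)."""
    labels = np.asarray(labels, int)
    X = np.arange(len(labels), dtype=float)[:, None]
    sids = np.array(["s"] * len(labels), dtype=object)
    return LabeledDataset(X, labels, sids)


def oracle_adaboost(member_probs, labels, max_rounds):
    """Independent replay of the update equations (selection, alphas, K)."""
    labels = np.asarray(labels, int)
    y = np.where(labels == 1, 1.0, -1.0)
    votes = [np.where(np.asarray(p) >= 0.5, 1.0, -1.0) for p in member_probs]
    n = len(labels)
    w = [1.0 / n] * n
    remaining = list(range(len(member_probs)))
    order, alphas = [], []
    for _ in range(max_rounds):
        if not remaining:
            break
        best_j, best_eps = None, None
        for j in remaining:
            eps = sum(w[i] for i in range(n) if votes[j][i] != y[i])
            if best_eps is None or eps < best_eps - 1e-18:
                best_j, best_eps = j, eps
        if best_eps >= 0.5:
            break
        eps = min(max(best_eps, 1e-10), 1 - 1e-10)
        alpha = 0.5 * math.log((1 - eps) / eps)
        order.append(best_j)
        alphas.append(alpha)
        remaining.remove(best_j)
        w = [w[i] * math.exp(-alpha * y[i] * votes[best_j][i]) for i in range(n)]
        total = sum(w)
        w = [v / total for v in w]
        if best_eps == 0.0:
            break
    return order, alphas


class TestUndersampling:
    def test_subset_size_and_minority_coverage(self, rng):
        ds = make_dataset(100, 10, rng)
        subsets = undersample_subsets(ds, L=3, seed=5)
        assert len(subsets) == 3
        minority = set(np.flatnonzero(ds.labels == 1))
        for idx in subsets:
            assert len(idx) == 20
            assert minority <= set(idx.tolist())
            assert len(set(idx.tolist())) == 20  # without replacement

    def test_balanced_input_degenerates_to_full_dataset(self, rng):
        ds = make_dataset(8, 8, rng)
        for idx in undersample_subsets(ds, L=4, seed=0):
            assert sorted(idx.tolist()) == list(range(16))

    def test_same_seed_reproduces_draws(self, rng):
        ds = make_dataset(50, 7, rng)
        a = undersample_subsets(ds, L=5, seed=9)
        b = undersample_subsets(ds, L=5, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        ds = LabeledDataset(X, np.zeros(10, int), np.array(["s"] * 10, dtype=object))
        with pytest.raises(ValidationError):
            undersample_subsets(ds, L=2, seed=0)


class TestTrainPool:
    def test_pool_of_eleven_logistic_members(self, rng):
        ds = make_dataset(120, 15, rng)
        pool = train_pool(ds, BaseClassifierSpec("logistic"), L=11, seed=2)
        assert pool.L == len(pool.members) == len(pool.subset_indices) == 11
        probs = pool.members[0].score(ds.X)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_pool_of_one_degenerates_to_single_classifier(self, rng):
        ds = make_dataset(60, 12, rng)
        pool = train_pool(ds, BaseClassifierSpec("logistic"), L=1, seed=3)
        model = adaboost_select(pool, ds)
        assert model.K == 1 and model.alphas[0] > 0
        probe = rng.normal(size=(5, 3))
        np.testing.assert_allclose(model.score(probe), pool.members[0].score(probe))

    def test_same_seed_gives_identical_predictions(self, rng):
        ds = make_dataset(80, 10, rng)
        probe = rng.normal(0.5, 1.0, size=(20, 3))
        spec = BaseClassifierSpec("mlp", hyperparameters={"max_iter": 80})
        a = train_pool(ds, spec, L=3, seed=7)
        b = train_pool(ds, spec, L=3, seed=7)
        for ma, mb in zip(a.members, b.members):
            np.testing.assert_array_equal(ma.score(probe), mb.score(probe))

    def test_lstm_kind_not_available(self, rng):
        ds = make_dataset(30, 6, rng)
        with pytest.raises(ConfigError, match="lstm"):
            train_pool(ds, BaseClassifierSpec("lstm"), L=2, seed=0)

    def test_unknown_kind_rejected_at_spec(self):
        with pytest.raises(ConfigError):
            BaseClassifierSpec("forest")


class TestAdaboostSelect:
    def test_perfect_member_short_circuits(self):
        labels = [0, 0, 1, 1]
        perfect = FixedScorer([0.1, 0.2, 0.9, 0.8])
        noisy = FixedScorer([0.6, 0.4, 0.6, 0.4])
        pool = ClassifierPool(members=[noisy, perfect], subset_indices=[np.arange(4)] * 2, L=2)
        model = adaboost_select(pool, index_dataset(labels))
        assert model.K == 1
        assert model.member_indices == [1]
        assert model.alphas[0] == pytest.approx(0.5 * math.log((1 - 1e-10) / 1e-10))

    def test_coin_flip_pool_rejected(self):
        labels = [0, 0, 1, 1]
        half_wrong = FixedScorer([0.9, 0.1, 0.9, 0.1])  # errs on half the weight
        pool = ClassifierPool(members=[half_wrong], subset_indices=[np.arange(4)], L=1)
        with pytest.raises(TrainingError, match="chance"):
            adaboost_select(pool, index_dataset(labels))

    def test_selection_ties_break_by_lowest_index(self):
        labels = [0, 0, 1, 1]
        a = FixedScorer([0.1, 0.9, 0.9, 0.9])  # errs on row 1 only
        b = FixedScorer([0.9, 0.1, 0.9, 0.9])  # errs on row 0 only: same eps
        pool = ClassifierPool(members=[a, b], subset_indices=[np.arange(4)] * 2, L=2)
        model = adaboost_select(pool, index_dataset(labels), max_rounds=1)
        assert model.member_indices[0] == 0

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_step_by_step_oracle(self, trial):
        """Selection order, alpha values and K agree with an independent replay."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(20, 100))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        L = int(rng.integers(2, 6))
        # members correlate with the truth to varying degrees so some beat chance
        member_probs = []
        for _ in range(L):
            flip = rng.uniform(0.05, 0.6)
            p = np.where(rng.uniform(size=n) < flip, 1 - labels, labels).astype(float)
            member_probs.append(np.clip(p + rng.normal(0, 0.1, n), 0, 1))
        pool = ClassifierPool(
            members=[FixedScorer(p) for p in member_probs],
            subset_indices=[np.arange(n)] * L,
            L=L,
        )
        ds = index_dataset(labels)
        order, alphas = oracle_adaboost(member_probs, labels, max_rounds=L)
        if not order:
            with pytest.raises(TrainingError):
                adaboost_select(pool, ds)
            return
        model = adaboost_select(pool, ds)
        assert model.member_indices == order
        np.testing.assert_allclose(model.alphas, alphas, atol=1e-10)
        assert model.K == len(order)

    def test_round_errors_beat_chance_and_bound_decreases(self, rng):
        """Every selected eps < 0.5, alphas > 0, exponential-loss bound non-increasing."""
        ds = make_dataset(150, 20, rng)
        pool = train_pool(ds, BaseClassifierSpec("logistic"), L=7, seed=4)
        y = np.where(ds.labels == 1, 1.0, -1.0)
        model = adaboost_select(pool, ds)
        assert np.all(model.alphas > 0)
        # replay the weight path to recover each round's eps
        w = np.full(len(ds), 1.0 / len(ds))
        bound, prev = 1.0, None
        for member, alpha in zip(model.team, model.alphas):
            h = np.where(member.score(ds.X) >= 0.5, 1.0, -1.0)
            eps = float(w[h != y].sum())
            assert eps < 0.5
            term = 2 * math.sqrt(eps * (1 - eps))
            bound *= term
            assert prev is None or bound <= prev + 1e-12
            prev = bound
            w = w * np.exp(-alpha * y * h)
            w /= w.sum()


class TestEnsembleScoring:
    def test_weighted_mean_arithmetic(self):
        model = EnsembleModel(
            team=[FixedScorer([0.2]), FixedScorer([0.8])], alphas=[1.0, 3.0]
        )
        assert model.score(np.array([[0.0]]))[0] == pytest.approx(0.65)

    def test_convexity_bound_attained(self):
        model = EnsembleModel(team=[FixedScorer([1.0])] * 3, alphas=[0.5, 1.0, 2.0])
        assert model.score(np.array([[0.0]]))[0] == pytest.approx(1.0)

    def test_permutation_and_rescaling_invariance(self, rng):
        probs = [rng.uniform(size=10) for _ in range(3)]
        X = np.arange(10, dtype=float)[:, None]
        base = EnsembleModel(team=[FixedScorer(p) for p in probs], alphas=[1.0, 2.0, 0.5])
        permuted = EnsembleModel(
            team=[FixedScorer(probs[2]), FixedScorer(probs[0]), FixedScorer(probs[1])],
            alphas=[0.5, 1.0, 2.0],
        )
        scaled = EnsembleModel(team=[FixedScorer(p) for p in probs],
                               alphas=[10.0, 20.0, 5.0])
        np.testing.assert_allclose(base.score(X), permuted.score(X), atol=1e-12)
        np.testing.assert_allclose(base.score(X), scaled.score(X), atol=1e-12)

    def test_classify_threshold_is_strict(self):
        model = EnsembleModel(team=[FixedScorer([0.7, 0.5, 0.2])], alphas=[1.0])
        X = np.arange(3, dtype=float)[:, None]
        assert model.classify(X, 0.5).tolist() == [1, 0, 0]
        assert model.classify(X, 1.0).tolist() == [0, 0, 0]

    def test_dimension_mismatch_rejected(self, rng):
        ds = make_dataset(40, 8, rng, d=2)
        from eiodetect import FeatureConfig

        model = fit_single(ds, BaseClassifierSpec("logistic"),
                           feature_config=FeatureConfig(variant="simple"))
        with pytest.raises(ValidationError, match="dimension"):
            model.score(rng.normal(size=(3, 5)))

    def test_model_round_trips_through_archive(self, rng, tmp_path):
        ds = make_dataset(60, 9, rng)
        model = fit_single(ds, BaseClassifierSpec("logistic"), seed=1)
        path = model.save(tmp_path / "m.joblib")
        back = EnsembleModel.load(path)
        probe = rng.normal(size=(7, 3))
        np.testing.assert_array_equal(model.score(probe), back.score(probe))
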