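import itertools

import numpy as np
import pytest

from citscreen.errors import DegenerateInputError, ParameterError
from citscreen.evaluate import (
    _balance_folds,
    _weight_folds,
    auc_roc,
    cross_validate_strategy,
    default_balancing_specs,
    make_folds,
    n_strategies,
    results_to_frame,
    run_grid,
    sample_hyperparameters,
)
from citscreen.learners import LEARNERS, LearnerFailure, fit_and_score
from citscreen.preprocess import build_dtm
from citscreen.rebalance import BalancingSpec
from citscreen.synthetic import SyntheticSpec, generate_corpus

from conftest import make_corpus


def brute_force_auc(scores, labels):
    """All-pairs Mann-Whitney estimate; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAucRoc:
    def test_worked_example(self):
        assert auc_roc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc_roc([3.0, 2.0, 1.0, 0.0], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auc_roc([1.0] * 6, [1, 1, 0, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            auc_roc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 25))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            # coarse grid of score values makes ties frequent
            scores = rng.integers(0, 5, size=n) / 4.0
            assert auc_roc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )


class TestMakeFolds:
    def test_exact_stratification_when_divisible(self):
        labels = np.array([1] * 10 + [0] * 190)
        folds = make_folds(labels, 5, seed=0)
        for f in range(5):
            assert (labels[folds == f] == 1).sum() == 2
            assert (labels[folds == f] == 0).sum() == 38

    def test_balanced_remainder(self):
        labels = np.array([1] * 7 + [0] * 50)
        folds = make_folds(labels, 5, seed=1)
        pos_counts = sorted((labels[folds == f] == 1).sum() for f in range(5))
        assert pos_counts == [1, 1, 1, 2, 2]

    def test_reproducible(self):
        labels = np.array([1] * 8 + [0] * 40)
        assert (make_folds(labels, 5, seed=3) == make_folds(labels, 5, seed=3)).all()

    def test_small_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            make_folds(np.array([1, 1, 0, 0, 0, 0, 0]), 5)


class TestSampleHyperparameters:
    def test_ranges(self):
        draws = sample_hyperparameters("SVM", 20, seed=0)
        assert all(1e-2 <= d.params["C"] <= 1e2 for d in draws)
        draws = sample_hyperparameters("GLMNet", 20, seed=0)
        assert all(
            1e-4 <= d.params["lambda"] <= 1 and 0 <= d.params["alpha"] <= 1
            for d in draws
        )
        draws = sample_hyperparameters("RF", 20, feature_count=100, seed=0)
        assert all(1 <= d.params["mtry"] <= 20 for d in draws)

    def test_knn_bound_by_train_size(self):
        draws = sample_hyperparameters("kNN", 50, train_size=6, seed=0)
        ks = {d.params["k"] for d in draws}
        assert ks <= set(range(1, 6))

    def test_deterministic_given_seed(self):
        a = sample_hyperparameters("GLMNet", 10, seed=42)
        b = sample_hyperparameters("GLMNet", 10, seed=42)
        assert [d.params for d in a] == [d.params for d in b]

    def test_degenerate_train_size_rejected(self):
        with pytest.raises(DegenerateInputError):
            sample_hyperparameters("kNN", 5, train_size=1, seed=0)

    def test_unknown_learner_rejected(self):
        with pytest.raises(ParameterError):
            sample_hyperparameters("NaiveBayes", 5)


@pytest.fixture(scope="module")
def separable_corpus():
    return generate_corpus(
        SyntheticSpec("sep", n_pos=10, n_neg=100, separation=0.9, seed=21)
    )


class TestCrossValidateStrategy:
    @pytest.mark.parametrize("learner", ["SVM", "RF", "GLMNet"])
    def test_separable_corpus_reaches_auc_one(self, separable_corpus, learner):
        cv = cross_validate_strategy(
            separable_corpus,
            learner,
            BalancingSpec("none"),
            n_draws=3,
            seed=11,
        )
        assert cv.status == "ok"
        assert cv.mean_auc == pytest.approx(1.0)
        assert len(cv.fold_aucs) == 5 and cv.sd_auc == pytest.approx(0.0)

    def test_failure_is_captured_not_raised(self, separable_corpus, monkeypatch):
        def boom(*args, **kwargs):
            raise LearnerFailure("synthetic failure for testing")

        monkeypatch.setattr("citscreen.evaluate.fit_and_score", boom)
        cv = cross_validate_strategy(
            separable_corpus, "kNN", BalancingSpec("none"), n_draws=2, seed=1
        )
        assert cv.status == "failed"
        assert "synthetic failure" in cv.cause
        assert cv.mean_auc is None and cv.fold_aucs is None

    def test_chosen_draw_reported(self, separable_corpus):
        cv = cross_validate_strategy(
            separable_corpus, "GLMNet", BalancingSpec("rus", 0.5, seed=2),
            n_draws=3, seed=7,
        )
        assert cv.chosen_draw.learner == "GLMNet"
        assert set(cv.chosen_draw.params) == {"lambda", "alpha"}


class TestLeakageGuards:
    def test_validation_folds_shared_across_balancing(self, separable_corpus):
        dtm = build_dtm(separable_corpus)
        weighted = _weight_folds(dtm, 5, 0.04, fold_seed=77)
        for spec in default_balancing_specs(seed=5)[1:]:
            balanced = _balance_folds(weighted, spec, balance_seed=13)
            for base, bal in zip(weighted, balanced):
                # held-out fold bit-identical, whatever the training resample
                assert bal["X_val"] is base["X_val"]
                assert bal["y_val"] is base["y_val"]

    def test_training_resample_respects_method(self, separable_corpus):
        dtm = build_dtm(separable_corpus)
        weighted = _weight_folds(dtm, 5, 0.04, fold_seed=77)
        rus = _balance_folds(weighted, BalancingSpec("rus", 0.5), balance_seed=13)
        ros = _balance_folds(weighted, BalancingSpec("ros", 0.5), balance_seed=13)
        for base, r, o in zip(weighted, rus, ros):
            assert len(r["y_train"]) < len(base["y_train"])
            assert len(o["y_train"]) > len(base["y_train"])


class TestRunGrid:
    def test_cell_enumeration(self, separable_corpus):
        results = run_grid(
            [separable_corpus], learners=("kNN",), master_seed=0, n_draws=1
        )
        assert len(results) == 5  # one learner, five strategies

    def test_twenty_strategies_by_default(self):
        assert n_strategies() == 20
        assert n_strategies(learners=("SVM",)) == 5

    def test_grid_requires_corpora(self):
        with pytest.raises(ParameterError):
            run_grid([])

    def test_results_frame_schema(self, separable_corpus):
        results = run_grid(
            [separable_corpus], learners=("SVM",), master_seed=3, n_draws=1
        )
        frame = results_to_frame(results)
        assert list(frame.columns) == [
            "review_id", "learner", "method", "minority_share",
            "fold_aucs", "mean_auc", "sd_auc", "status",
        ]
        assert (frame["status"] == "ok").all()
        assert len(frame) == 5


def test_fit_and_score_invalid_k_fails():
    X = np.eye(6)
    y = np.array([1, 1, 1, 0, 0, 0])
    with pytest.raises(LearnerFailure):
        fit_and_score("kNN", {"k": 10}, X, y, X)


@pytest.mark.parametrize("learner", LEARNERS)
def test_fit_and_score_returns_continuous_scores(learner):
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 8))
    y = np.array([1] * 10 + [0] * 30)
    X[y == 1] += 2.0
    params = {
        "SVM": {"C": 1.0},
        "kNN": {"k": 3},
        "RF": {"mtry": 3},
        "GLMNet": {"lambda": 0.01, "alpha": 0.5},
    }[learner]
    scores = fit_and_score(learner, params, X, y, X, seed=1)
    assert scores.shape == (40,)
    assert auc_roc(scores, y) > 0.9
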