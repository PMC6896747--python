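"""Classifier families behind a uniform fit-and-score interface.

Four families are supported, each exposing a continuous positive-class score
(probability or decision value) so ROC analysis never depends on a hard
threshold:

- ``SVM``: linear support vector machine; tunable cost C.
- ``kNN``: k-nearest neighbours; tunable neighbourhood size k.
- ``RF``: random forest; tunable number of candidate features per split (mtry).
- ``GLMNet``: elastic-net regularized logistic regression; tunable penalty
  strength lambda and mixing parameter alpha (glmnet parameterisation, with
  the per-observation penalty scaling translated for the underlying solver).

Internal optimisation of each family is delegated to scikit-learn; any
exception raised while fitting or scoring is wrapped in
:class:`LearnerFailure` so the evaluation grid can record the cell as failed
instead of aborting.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC

from .errors import CitscreenError, ParameterError

LEARNER_SVM = "SVM"
LEARNER_KNN = "kNN"
LEARNER_RF = "RF"
LEARNER_GLMNET = "GLMNet"
LEARNERS = (LEARNER_SVM, LEARNER_KNN, LEARNER_RF, LEARNER_GLMNET)

# Learners whose fitted model is a deterministic function of (data, params, seed).
DETERMINISTIC_LEARNERS = frozenset(LEARNERS)


class LearnerFailure(CitscreenError, RuntimeError):
    """A classifier failed to train or score on one fold."""


def _positive_proba(clf, X) -> np.ndarray:
    proba = clf.predict_proba(X)
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return proba[:, pos_col]


def fit_and_score(
    learner: str,
    params: dict,
    X_train,
    y_train: np.ndarray,
    X_test,
    seed: int = 0,
) -> np.ndarray:
    """Train one classifier and return continuous positive-class scores on X_test."""
    if learner not in LEARNERS:
        raise ParameterError(f"unknown learner {learner!r}")
    try:
        if learner == LEARNER_SVM:
            clf = LinearSVC(C=float(params["C"]), random_state=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X_train, y_train)
            return np.asarray(clf.decision_function(X_test), dtype=float)
        if learner == LEARNER_KNN:
            k = int(params["k"])
            if k < 1 or k >= len(y_train):
                raise ValueError(
                    f"neighbourhood size k={k} invalid for {len(y_train)} training rows"
                )
            clf = KNeighborsClassifier(n_neighbors=k)
            clf.fit(X_train, y_train)
            return _positive_proba(clf, X_test)
        if learner == LEARNER_RF:
            mtry = int(min(params["mtry"], X_train.shape[1]))
            clf = RandomForestClassifier(
                n_estimators=100,
                max_features=max(1, mtry),
                random_state=seed,
                n_jobs=1,
            )
            clf.fit(X_train, y_train)
            return _positive_proba(clf, X_test)
        if learner == LEARNER_GLMNET:
            lam = float(params["lambda"])
            alpha = float(params["alpha"])
            # glmnet penalises lambda * (mean loss); sklearn's C is the inverse
            # of the penalty on the summed loss, hence the 1/(n * lambda) map.
            C = 1.0 / max(len(y_train) * lam, 1e-12)
            clf = LogisticRegression(
                solver="saga",
                l1_ratio=alpha,
                C=C,
                max_iter=100,
                tol=1e-3,
                random_state=seed,
            )
            with warnings.catch_warnings():
                # random draws legitimately include weak penalties that stop
                # at max_iter; the ranking scores are still usable
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X_train, y_train)
            return _positive_proba(clf, X_test)
        raise AssertionError("unreachable")
    except LearnerFailure:
        raise
    except Exception as exc:
        raise LearnerFailure(f"{learner} failed: {exc}") from exc
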