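"""Cross-validated evaluation of the (review x learner x balancing) grid.

For each systematic-review corpus, each classifier family, and each of five
imbalance-handling strategies (none, RUS-50:50, RUS-35:65, ROS-50:50,
ROS-35:65 — 20 learner-strategy combinations in all), a stratified k-fold
cross-validation is run.  Inside every fold, TF-IDF weighting and token
selection are fitted on the training rows only; the held-out fold is aligned
to the fitted vocabulary and rescaled with the training IDFs; resampling is
applied to the (already weighted) training rows only.  Ten random
hyperparameter draws per learner are scored by mean fold AUC-ROC and the
best draw's fold AUCs are reported.

A learner failure on any fold marks the whole cell ``status="failed"`` with
the cause recorded; the surrounding grid always completes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .corpus import Corpus
from .errors import DegenerateInputError, ParameterError
from .learners import LEARNERS, LearnerFailure, fit_and_score
from .preprocess import DocumentTermMatrix, build_dtm
from .rebalance import (
    METHOD_NONE,
    METHOD_ROS,
    METHOD_RUS,
    BalancingSpec,
    apply_balancing,
)
from .seeding import derive_seed
from .tfidf import apply_tfidf, fit_tfidf


@dataclass
class HyperDraw:
    """One random draw of a learner's tunable parameters."""

    learner: str
    params: dict


@dataclass
class CVResult:
    """Cross-validation outcome for one grid cell (or a recorded failure)."""

    fold_aucs: list[float] | None
    mean_auc: float | None
    sd_auc: float | None
    n_folds: int
    chosen_draw: HyperDraw | None
    status: str  # "ok" | "failed"
    cause: str | None = None


@dataclass
class StrategyResult:
    """One (review, learner, balancing) cell of the evaluation grid."""

    review_id: str
    learner: str
    balancing: BalancingSpec
    cv: CVResult


def default_balancing_specs(seed: int = 0) -> list[BalancingSpec]:
    """The five imbalance strategies evaluated per learner."""
    return [
        BalancingSpec(METHOD_NONE, seed=seed),
        BalancingSpec(METHOD_RUS, 0.50, seed=seed),
        BalancingSpec(METHOD_RUS, 0.35, seed=seed),
        BalancingSpec(METHOD_ROS, 0.50, seed=seed),
        BalancingSpec(METHOD_ROS, 0.35, seed=seed),
    ]


def n_strategies(
    learners: Sequence[str] = LEARNERS, balancing_specs: Sequence | None = None
) -> int:
    """Number of learner-strategy combinations in the grid (20 by default)."""
    specs = balancing_specs if balancing_specs is not None else default_balancing_specs()
    return len(learners) * len(specs)


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC-ROC as the Mann-Whitney probability that a positive outscores a negative.

    Computed from midranks, which is algebraically identical to averaging
    over all positive-negative pairs with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("auc_roc needs both classes present")
    ranks = rankdata(scores, method="average")
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def make_folds(labels: np.ndarray, k_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment: per-fold class counts differ by at most one.

    Stratification matters here because positives can be as few as five; an
    unstratified split could leave a fold with no positive, making fold AUC
    undefined.
    """
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k_folds:
        raise DegenerateInputError(
            f"each class needs >= {k_folds} members (got {counts.tolist()})"
        )
    splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, val_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        assignment[val_idx] = fold
    return assignment


def sample_hyperparameters(
    learner: str,
    n_draws: int = 10,
    feature_count: int = 100,
    train_size: int = 100,
    seed: int = 0,
) -> list[HyperDraw]:
    """Draw random hyperparameter combinations for one learner family.

    Ranges: C log-uniform on [1e-2, 1e2]; k uniform integer on
    [1, min(30, train_size - 1)]; mtry uniform integer on
    [1, max(2, round(2*sqrt(feature_count)))]; lambda log-uniform on
    [1e-4, 1]; alpha uniform on [0, 1].
    """
    if n_draws < 1:
        raise ParameterError("n_draws must be >= 1")
    if learner not in LEARNERS:
        raise ParameterError(f"unknown learner {learner!r}")
    rng = np.random.default_rng(seed)
    draws: list[HyperDraw] = []
    for _ in range(n_draws):
        if learner == "SVM":
            params = {"C": float(10 ** rng.uniform(-2, 2))}
        elif learner == "kNN":
            k_max = min(30, train_size - 1)
            if k_max < 1:
                raise DegenerateInputError(
                    f"train_size={train_size} too small to pick any k"
                )
            params = {"k": int(rng.integers(1, k_max + 1))}
        elif learner == "RF":
            mtry_max = max(2, round(2 * math.sqrt(max(feature_count, 1))))
            mtry_max = min(mtry_max, max(feature_count, 1))
            params = {"mtry": int(rng.integers(1, mtry_max + 1))}
        else:  # GLMNet
            params = {
                "lambda": float(10 ** rng.uniform(-4, 0)),
                "alpha": float(rng.uniform(0, 1)),
            }
        draws.append(HyperDraw(learner=learner, params=params))
    return draws


def _weight_folds(
    dtm: DocumentTermMatrix,
    k_folds: int,
    retain_fraction: float,
    fold_seed: int,
):
    """Split into folds and fit/apply TF-IDF weighting leakage-safely.

    Balancing-independent: the same weighted folds serve every balancing
    strategy of one review (they share the fold seed), so the grid runner
    computes them once per corpus.
    """
    assignment = make_folds(dtm.labels, k_folds=k_folds, seed=fold_seed)
    folds = []
    for fold in range(k_folds):
        train_idx = np.flatnonzero(assignment != fold)
        val_idx = np.flatnonzero(assignment == fold)
        train_tf = dtm.take_rows(train_idx)
        model = fit_tfidf(train_tf, retain_fraction=retain_fraction)
        val = apply_tfidf(model, dtm.take_rows(val_idx))
        folds.append(
            {
                "X_train": apply_tfidf(model, train_tf).weights,
                "y_train": train_tf.labels,
                "X_val": val.weights,
                "y_val": val.labels,
                "n_features": len(model.vocabulary),
            }
        )
    return folds


def _balance_folds(weighted_folds, balancing: BalancingSpec, balance_seed: int):
    """Resample the (already weighted) training rows of each fold."""
    folds = []
    for fold, f in enumerate(weighted_folds):
        spec = BalancingSpec(
            balancing.method,
            balancing.minority_share,
            seed=derive_seed(balance_seed, "fold", fold),
        )
        X_bal, y_bal = apply_balancing(f["X_train"], f["y_train"], spec)
        folds.append({**f, "X_train": X_bal, "y_train": y_bal})
    return folds


def cross_validate_strategy(
    corpus_or_dtm: Corpus | DocumentTermMatrix,
    learner: str,
    balancing: BalancingSpec,
    k_folds: int = 5,
    n_draws: int = 10,
    retain_fraction: float = 0.04,
    seed: int = 0,
    fold_seed: int | None = None,
) -> CVResult:
    """Evaluate one (corpus, learner, balancing) cell.

    ``fold_seed`` defaults to a derivation of ``seed`` but can be pinned
    externally so that all balancing strategies of one review share identical
    folds (the grid runner does this).
    """
    dtm = (
        corpus_or_dtm
        if isinstance(corpus_or_dtm, DocumentTermMatrix)
        else build_dtm(corpus_or_dtm)
    )
    if fold_seed is None:
        fold_seed = derive_seed(seed, "folds")
    try:
        weighted = _weight_folds(dtm, k_folds, retain_fraction, fold_seed=fold_seed)
        return _evaluate_cell(weighted, learner, balancing, n_draws, seed)
    except DegenerateInputError as exc:
        return CVResult(
            fold_aucs=None,
            mean_auc=None,
            sd_auc=None,
            n_folds=k_folds,
            chosen_draw=None,
            status="failed",
            cause=str(exc),
        )


def _evaluate_cell(
    weighted_folds,
    learner: str,
    balancing: BalancingSpec,
    n_draws: int,
    seed: int,
) -> CVResult:
    """Score one (learner, balancing) cell on pre-weighted folds."""
    k_folds = len(weighted_folds)
    try:
        folds = _balance_folds(
            weighted_folds, balancing, balance_seed=derive_seed(seed, "balance")
        )
        train_size = min(len(f["y_train"]) for f in folds)
        feature_count = min(f["n_features"] for f in folds)
        draws = sample_hyperparameters(
            learner,
            n_draws=n_draws,
            feature_count=feature_count,
            train_size=train_size,
            seed=derive_seed(seed, "draws"),
        )
        per_draw_aucs: list[list[float]] = []
        for d, draw in enumerate(draws):
            aucs = []
            for f, fold in enumerate(folds):
                scores = fit_and_score(
                    learner,
                    draw.params,
                    fold["X_train"],
                    fold["y_train"],
                    fold["X_val"],
                    seed=derive_seed(seed, "fit", d, f),
                )
                aucs.append(auc_roc(scores, fold["y_val"]))
            per_draw_aucs.append(aucs)
    except (LearnerFailure, DegenerateInputError) as exc:
        return CVResult(
            fold_aucs=None,
            mean_auc=None,
            sd_auc=None,
            n_folds=k_folds,
            chosen_draw=None,
            status="failed",
            cause=str(exc),
        )
    means = [float(np.mean(a)) for a in per_draw_aucs]
    best = int(np.argmax(means))  # first draw wins ties
    fold_aucs = per_draw_aucs[best]
    return CVResult(
        fold_aucs=[float(a) for a in fold_aucs],
        mean_auc=means[best],
        sd_auc=float(np.std(fold_aucs, ddof=1)),
        n_folds=k_folds,
        chosen_draw=draws[best],
        status="ok",
    )


def run_grid(
    corpora: Iterable[Corpus],
    learners: Sequence[str] = LEARNERS,
    balancing_specs: Sequence[BalancingSpec] | None = None,
    master_seed: int = 0,
    k_folds: int = 5,
    n_draws: int = 10,
    retain_fraction: float = 0.04,
) -> list[StrategyResult]:
    """Run every (review x learner x balancing) cell of the evaluation grid.

    Fold assignment depends only on (master_seed, review), so every strategy
    of one review is scored on identical held-out folds; all other seeds are
    derived per cell, making each cell independently reproducible.  Failed
    cells are recorded, never dropped.
    """
    corpora = list(corpora)
    if not corpora:
        raise ParameterError("run_grid needs at least one corpus")
    if balancing_specs is None:
        balancing_specs = default_balancing_specs()
    results: list[StrategyResult] = []
    for corpus in corpora:
        dtm = build_dtm(corpus)
        fold_seed = derive_seed(master_seed, corpus.review_id, "folds")
        weighted = _weight_folds(
            dtm, k_folds, retain_fraction, fold_seed=fold_seed
        )
        for learner in learners:
            for spec in balancing_specs:
                cell_seed = derive_seed(
                    master_seed,
                    corpus.review_id,
                    learner,
                    spec.method,
                    round(spec.minority_share, 4),
                )
                balancing = BalancingSpec(
                    spec.method, spec.minority_share, seed=cell_seed
                )
                cv = _evaluate_cell(
                    weighted, learner, balancing, n_draws=n_draws, seed=cell_seed
                )
                results.append(
                    StrategyResult(
                        review_id=corpus.review_id,
                        learner=learner,
                        balancing=balancing,
                        cv=cv,
                    )
                )
    return results


def results_to_frame(results: Iterable[StrategyResult]) -> pd.DataFrame:
    """Tabular view of grid results (the machine-readable strategy table)."""
    rows = []
    for r in results:
        rows.append(
            {
                "review_id": r.review_id,
                "learner": r.learner,
                "method": r.balancing.method,
                "minority_share": (
                    r.balancing.minority_share
                    if r.balancing.method != METHOD_NONE
                    else np.nan
                ),
                "fold_aucs": (
                    ";".join(f"{a:.6f}" for a in r.cv.fold_aucs)
                    if r.cv.fold_aucs
                    else ""
                ),
                "mean_auc": r.cv.mean_auc,
                "sd_auc": r.cv.sd_auc,
                "status": r.cv.status,
            }
        )
    return pd.DataFrame(rows)


def write_results(results: Iterable[StrategyResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)
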