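"""Random under- and oversampling of training rows to a target class ratio.

Both methods act on the minority:majority ratio ``s : (1 - s)`` where ``s``
is the requested minority share (0.50 for a 50:50 split, 0.35 for 35:65).
Rounding is chosen so the achieved minority share never falls below the
request: the undersampler keeps ``floor(n_min * (1-s)/s)`` majority rows and
the oversampler grows the minority to ``ceil(n_maj * s/(1-s))`` rows.
Resampling is only ever applied to training folds; held-out folds must pass
through untouched (the evaluation harness asserts this).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ParameterError

METHOD_NONE = "none"
METHOD_RUS = "rus"
METHOD_ROS = "ros"
METHODS = (METHOD_NONE, METHOD_RUS, METHOD_ROS)


@dataclass(frozen=True)
class BalancingSpec:
    """Imbalance-handling method plus target minority share and seed."""

    method: str
    minority_share: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"unknown balancing method {self.method!r}")
        if self.method != METHOD_NONE and not (0.0 < self.minority_share <= 0.5):
            raise ParameterError("minority_share must lie in (0, 0.5]")

    def label(self) -> str:
        """Human-readable strategy label, e.g. ``RUS-35:65``."""
        if self.method == METHOD_NONE:
            return "none"
        minority = round(100 * self.minority_share)
        return f"{self.method.upper()}-{minority}:{100 - minority}"


def _split_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (minority indices, majority indices); positives win ties."""
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateInputError("both classes must be present for resampling")
    return (pos, neg) if pos.size <= neg.size else (neg, pos)


def undersample_indices(labels: np.ndarray, spec: BalancingSpec) -> np.ndarray:
    """Row indices kept by random undersampling, in original order."""
    minority, majority = _split_classes(labels)
    s = spec.minority_share
    target = min(majority.size, math.floor(minority.size * (1 - s) / s))
    rng = np.random.default_rng(spec.seed)
    kept_majority = rng.choice(majority, size=target, replace=False)
    return np.sort(np.concatenate([minority, kept_majority]))


def oversample_indices(labels: np.ndarray, spec: BalancingSpec) -> np.ndarray:
    """Original row indices followed by minority duplicates drawn with replacement."""
    minority, majority = _split_classes(labels)
    s = spec.minority_share
    target = math.ceil(majority.size * s / (1 - s))
    n_extra = max(0, target - minority.size)
    rng = np.random.default_rng(spec.seed)
    extras = rng.choice(minority, size=n_extra, replace=True)
    return np.concatenate([np.arange(len(labels)), extras])


def random_undersample(rows, labels: np.ndarray, spec: BalancingSpec):
    """Randomly drop majority training rows down to the target ratio."""
    if spec.method != METHOD_RUS:
        raise ParameterError("spec.method must be 'rus'")
    idx = undersample_indices(labels, spec)
    return rows[idx], np.asarray(labels)[idx]


def random_oversample(rows, labels: np.ndarray, spec: BalancingSpec):
    """Randomly duplicate minority training rows up to the target ratio."""
    if spec.method != METHOD_ROS:
        raise ParameterError("spec.method must be 'ros'")
    idx = oversample_indices(labels, spec)
    return rows[idx], np.asarray(labels)[idx]


def apply_balancing(rows, labels: np.ndarray, spec: BalancingSpec):
    """Dispatch on the spec's method; ``none`` passes data through unchanged."""
    if spec.method == METHOD_NONE:
        return rows, np.asarray(labels)
    if spec.method == METHOD_RUS:
        return random_undersample(rows, labels, spec)
    return random_oversample(rows, labels, spec)
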