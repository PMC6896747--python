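"""Delta-AUC computation and fixed-effect meta-analytic pooling.

For each review and learner, the gain of a balancing strategy is the
difference between its cross-validated mean AUC and the mean AUC of the same
learner with no balancing (``delta``).  Its sampling variance is taken as
``(sd_b^2 + sd_0^2) / k`` from the two CV standard deviations over ``k``
folds, treating the two means as independent, and is floored (default 1e-6)
because cells with every fold at AUC 1.0 have zero observed dispersion and
would otherwise receive infinite weight.  Per-review deltas are pooled per
(learner, balancing) panel with the classic inverse-variance fixed-effect
model; 95% intervals use the normal 1.96 quantile throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError
from .evaluate import CVResult, StrategyResult
from .rebalance import METHOD_NONE, BalancingSpec

Z95 = 1.96
DEFAULT_VARIANCE_FLOOR = 1e-6


@dataclass
class DeltaAUC:
    """Per-review AUC difference (balanced minus none) with variance and CI."""

    review_id: str
    learner: str
    balancing: BalancingSpec
    delta: float
    variance: float
    ci_low: float
    ci_high: float


@dataclass
class PooledEstimate:
    """Inverse-variance pooled delta for one (learner, balancing) panel."""

    learner: str
    balancing: BalancingSpec
    pooled_delta: float
    pooled_se: float
    ci_low: float
    ci_high: float
    n_reviews: int
    weights: np.ndarray  # normalized, sum to 1


class MissingResult(DegenerateInputError):
    """Raised when a delta is requested from a failed CV cell."""


def delta_auc(
    balanced: StrategyResult,
    none: StrategyResult,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> DeltaAUC:
    """Within-review delta AUC of a balancing strategy against no balancing."""
    if balanced.review_id != none.review_id or balanced.learner != none.learner:
        raise ParameterError("delta_auc pairs must share review and learner")
    b, n = balanced.cv, none.cv
    if b.status != "ok" or n.status != "ok":
        raise MissingResult(
            f"cell ({balanced.review_id}, {balanced.learner}) has a failed CV result"
        )
    if b.n_folds != n.n_folds:
        raise ParameterError("delta_auc requires equal fold counts")
    delta = b.mean_auc - n.mean_auc
    variance = max((b.sd_auc**2 + n.sd_auc**2) / b.n_folds, variance_floor)
    half = Z95 * math.sqrt(variance)
    return DeltaAUC(
        review_id=balanced.review_id,
        learner=balanced.learner,
        balancing=balanced.balancing,
        delta=delta,
        variance=variance,
        ci_low=delta - half,
        ci_high=delta + half,
    )


def pool_fixed_effect(deltas: Sequence[DeltaAUC]) -> PooledEstimate:
    """Classic inverse-variance fixed-effect pooling of per-review deltas."""
    deltas = list(deltas)
    if not deltas:
        raise DegenerateInputError("pool_fixed_effect needs at least one delta")
    d = np.array([x.delta for x in deltas])
    w = 1.0 / np.array([x.variance for x in deltas])
    pooled = float(np.sum(w * d) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    return PooledEstimate(
        learner=deltas[0].learner,
        balancing=deltas[0].balancing,
        pooled_delta=pooled,
        pooled_se=se,
        ci_low=pooled - Z95 * se,
        ci_high=pooled + Z95 * se,
        n_reviews=len(deltas),
        weights=w / np.sum(w),
    )


def forest_grid(
    results: Iterable[StrategyResult],
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> dict[tuple[str, str, float], dict]:
    """Assemble per-panel delta lists and pooled estimates.

    One panel per (learner, non-none balancing strategy): with 4 learners and
    4 strategies this is the 16-panel forest grid.  A review whose balanced or
    unbalanced cell failed is excluded from that panel only.
    """
    results = list(results)
    none_by_key: dict[tuple[str, str], StrategyResult] = {}
    for r in results:
        if r.balancing.method == METHOD_NONE:
            none_by_key[(r.review_id, r.learner)] = r
    panels: dict[tuple[str, str, float], dict] = {}
    for r in results:
        if r.balancing.method == METHOD_NONE:
            continue
        key = (r.learner, r.balancing.method, round(r.balancing.minority_share, 4))
        panel = panels.setdefault(
            key, {"learner": r.learner, "balancing": r.balancing, "deltas": []}
        )
        baseline = none_by_key.get((r.review_id, r.learner))
        if baseline is None:
            continue
        try:
            panel["deltas"].append(delta_auc(r, baseline, variance_floor))
        except MissingResult:
            continue
    for panel in panels.values():
        panel["pooled"] = (
            pool_fixed_effect(panel["deltas"]) if panel["deltas"] else None
        )
    return panels


def deltas_to_frame(panels: dict) -> pd.DataFrame:
    """Flatten forest panels into a tidy per-review delta table."""
    rows = []
    for (learner, method, share), panel in sorted(panels.items()):
        for d in panel["deltas"]:
            rows.append(
                {
                    "learner": learner,
                    "method": method,
                    "minority_share": share,
                    "review_id": d.review_id,
                    "delta": d.delta,
                    "variance": d.variance,
                    "ci_low": d.ci_low,
                    "ci_high": d.ci_high,
                }
            )
    return pd.DataFrame(rows)


def pooled_to_frame(panels: dict) -> pd.DataFrame:
    """One row per panel: the pooled diamond of each forest plot."""
    rows = []
    for (learner, method, share), panel in sorted(panels.items()):
        pooled = panel["pooled"]
        if pooled is None:
            continue
        rows.append(
            {
                "learner": learner,
                "method": method,
                "minority_share": share,
                "pooled_delta": pooled.pooled_delta,
                "pooled_se": pooled.pooled_se,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "n_reviews": pooled.n_reviews,
            }
        )
    return pd.DataFrame(rows)


def plot_forest_grid(panels: dict, figsize_per_panel: tuple[float, float] = (3.0, 2.6)):
    """Optional static rendering: learners by row, balancing strategies by column.

    Thin layer over the panel data; the tabular output is the tested surface.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    learners = sorted({k[0] for k in panels})
    strategies = sorted({(k[1], k[2]) for k in panels})
    fig, axes = plt.subplots(
        len(learners),
        len(strategies),
        figsize=(
            figsize_per_panel[0] * len(strategies),
            figsize_per_panel[1] * len(learners),
        ),
        squeeze=False,
    )
    for i, learner in enumerate(learners):
        for j, (method, share) in enumerate(strategies):
            ax = axes[i][j]
            panel = panels.get((learner, method, share))
            if panel is None or not panel["deltas"]:
                ax.set_axis_off()
                continue
            deltas = panel["deltas"]
            ys = np.arange(len(deltas), 0, -1)
            for y, d in zip(ys, deltas):
                ax.plot([d.ci_low, d.ci_high], [y, y], color="0.4", lw=1)
                ax.plot(d.delta, y, "s", color="0.2", ms=3)
            pooled = panel["pooled"]
            ax.plot(
                [pooled.ci_low, pooled.pooled_delta, pooled.ci_high, pooled.pooled_delta,
                 pooled.ci_low],
                [0, 0.35, 0, -0.35, 0],
                color="crimson",
                lw=1,
            )
            ax.axvline(0.0, color="0.7", lw=0.8, ls="--")
            ax.set_yticks([])
            if i == 0:
                ax.set_title(f"{method.upper()} {share:.2f}", fontsize=9)
            if j == 0:
                ax.set_ylabel(learner, fontsize=9)
            ax.set_xlabel("delta AUC", fontsize=8)
    fig.tight_layout()
    return fig
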