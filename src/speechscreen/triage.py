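"""Traffic-light risk stratification for screening triage.

Predicted ADRD probabilities are split into three zones — Green
``[0, t_low]`` (low risk, predicted negative), Amber ``(t_low, t_high]``
(uncertain, abstain) and Red ``(t_high, 1]`` (high risk, predicted
positive). Following a selective-classification approach, the Amber zone is
excluded and performance is reported on the retained Green/Red cases only;
``coverage`` is the retained fraction. Thresholds are chosen by exhaustive
grid search on validation scores, ranking feasible pairs lexicographically
by retained-set Youden's J, then retained ROC-AUC, then coverage, with ties
broken toward smaller thresholds to limit overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import classification_metrics

__all__ = [
    "RiskThresholds",
    "SelectiveReport",
    "assign_risk",
    "youden_j",
    "selective_metrics",
    "grid_search_thresholds",
]

ZONES = ("Green", "Amber", "Red")


@dataclass(frozen=True)
class RiskThresholds:
    """Zone boundaries; Green [0, t_low], Amber (t_low, t_high], Red (t_high, 1]."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_low <= self.t_high <= 1.0:
            raise ValueError(
                f"require 0 <= t_low <= t_high <= 1, got ({self.t_low}, {self.t_high})"
            )


@dataclass
class SelectiveReport:
    """Retained-set (non-Amber) performance under a threshold pair."""

    thresholds: RiskThresholds
    coverage: float
    metrics: dict[str, tuple[float, float]]
    youden_j: float
    undefined: list[str] = field(default_factory=list)
    n_retained: int = 0


def assign_risk(score: float, thresholds: RiskThresholds) -> str:
    """Zone for one probability; boundaries are right-closed
    ([0, t_low] -> Green, (t_low, t_high] -> Amber, (t_high, 1] -> Red)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if score <= thresholds.t_low:
        return "Green"
    if score <= thresholds.t_high:
        return "Amber"
    return "Red"


def assign_risk_many(scores: np.ndarray, thresholds: RiskThresholds) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    zones = np.where(
        scores <= thresholds.t_low,
        "Green",
        np.where(scores <= thresholds.t_high, "Amber", "Red"),
    )
    return zones.astype(object)


def youden_j(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity - 1 (inputs as fractions in [0, 1])."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return sensitivity + specificity - 1.0


def selective_metrics(
    scores: np.ndarray, labels: np.ndarray, thresholds: RiskThresholds
) -> SelectiveReport:
    """Performance after excluding the Amber zone.

    Retained Green cases count as predicted negative, Red as predicted
    positive; metrics are computed on the retained set only. J uses 0 for a
    retained sensitivity/specificity that is undefined (single-class
    retained set), with the metric flagged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    zones = assign_risk_many(scores, thresholds)
    retained = zones != "Amber"
    if not retained.any():
        raise ValueError("all scores fall in the Amber zone; nothing retained")
    pred = zones[retained] == "Red"
    report = classification_metrics(labels[retained], pred, scores[retained])
    sens = report.metrics.get("sensitivity", (np.nan,))[0]
    spec = report.metrics.get("specificity", (np.nan,))[0]
    j = youden_j(
        0.0 if np.isnan(sens) else sens / 100.0,
        0.0 if np.isnan(spec) else spec / 100.0,
    )
    return SelectiveReport(
        thresholds=thresholds,
        coverage=float(retained.mean()),
        metrics=report.metrics,
        youden_j=j,
        undefined=report.undefined,
        n_retained=int(retained.sum()),
    )


def grid_search_thresholds(
    val_scores: np.ndarray,
    val_labels: np.ndarray,
    resolution: float = 0.05,
    min_coverage: float = 0.5,
) -> tuple[RiskThresholds, pd.DataFrame]:
    """Exhaustive grid search for the traffic-light thresholds.

    Enumerates every grid pair with ``t_low <= t_high``; drops pairs whose
    retained coverage falls below ``min_coverage`` or whose retained-set
    metrics are undefined; ranks the rest lexicographically by
    (Youden's J, retained ROC-AUC, coverage), breaking exact objective ties
    toward the smaller ``(t_low, t_high)`` pair. Returns the winner and the
    full trace table of feasible pairs.
    """
    val_scores = np.asarray(val_scores, dtype=float)
    val_labels = np.asarray(val_labels, dtype=bool)
    if not (val_labels.any() and not val_labels.all()):
        raise ValueError("validation labels must contain both classes")
    n_steps = int(round(1.0 / resolution))
    grid = np.round(np.linspace(0.0, 1.0, n_steps + 1), 10)

    rows = []
    for i, t_low in enumerate(grid):
        for t_high in grid[i:]:
            thresholds = RiskThresholds(float(t_low), float(t_high))
            try:
                rep = selective_metrics(val_scores, val_labels, thresholds)
            except ValueError:
                continue
            if rep.coverage < min_coverage or rep.undefined:
                continue
            rows.append(
                {
                    "t_low": float(t_low),
                    "t_high": float(t_high),
                    "coverage": rep.coverage,
                    "youden_j": rep.youden_j,
                    "roc_auc": rep.metrics["roc_auc"][0],
                    "sensitivity": rep.metrics["sensitivity"][0],
                    "specificity": rep.metrics["specificity"][0],
                    "accuracy": rep.metrics["accuracy"][0],
                    "n_retained": rep.n_retained,
                }
            )
    if not rows:
        raise ValueError(
            f"no feasible threshold pair at resolution {resolution} with "
            f"min_coverage {min_coverage}"
        )
    trace = pd.DataFrame(rows)
    order = trace.sort_values(
        by=["youden_j", "roc_auc", "coverage", "t_low", "t_high"],
        ascending=[False, False, False, True, True],
        kind="mergesort",
    )
    best = order.iloc[0]
    return RiskThresholds(float(best.t_low), float(best.t_high)), trace
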