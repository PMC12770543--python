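"""Attribution, subgroup-fairness and severity-profile reporting.

Feature attributions come in two modes. ``tree`` mode decomposes each
random-forest prediction along the decision paths of its trees: at every
split on a sample's path, the change in the node mean (class-1 fraction for
the classifier, mean target for the regressor) is credited to the split
feature, and the root mean is the base value. Summed over a path and
averaged over trees, the base value plus a sample's contributions equals the
forest's output exactly (local accuracy). ``permutation`` mode returns
global permutation importances only.

Fairness reporting covers per-subgroup performance (sex, median-split age,
MMSE severity group), the demographic-parity gap (largest pairwise
difference in positive-prediction rates), and equalized-odds-style
sensitivity/specificity gaps. Rank associations use Spearman's correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .pipeline import MetricsReport, classification_metrics, mmse_to_group

__all__ = [
    "AttributionReport",
    "SubgroupReport",
    "SpearmanResult",
    "feature_attributions",
    "subgroup_performance",
    "demographic_parity_gap",
    "spearman_rank",
    "probability_severity_profile",
]


@dataclass
class AttributionReport:
    """Per-sample feature contributions with a global ranking."""

    base_value: float
    contributions: np.ndarray | None  # (n_samples, n_features); None in permutation mode
    feature_names: list[str]
    global_importance: pd.Series  # mean |contribution| (or permutation importance)
    mode: str

    @property
    def ranking(self) -> list[str]:
        return list(self.global_importance.index)


@dataclass
class SubgroupReport:
    """Per-group classification performance and fairness gaps."""

    grouping: str
    per_group: dict[str, MetricsReport]
    group_sizes: dict[str, int]
    parity_gap: float
    sensitivity_gap: float | None
    specificity_gap: float | None
    flagged_small: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class SpearmanResult:
    r: float
    p: float
    defined: bool = True


def _tree_path_contributions(model, X: np.ndarray) -> tuple[float, np.ndarray]:
    """Decision-path decomposition of forest predictions.

    Returns (base_value, contributions) such that
    ``base + contributions.sum(axis=1)`` equals ``predict_proba[:, 1]``
    (classifier) or ``predict`` (regressor) up to float accumulation.
    """
    n_samples, n_features = X.shape
    contributions = np.zeros((n_samples, n_features))
    base = 0.0
    estimators = model.estimators_
    is_clf = isinstance(model, RandomForestClassifier)
    for est in estimators:
        tree = est.tree_
        values = tree.value[:, 0, :]
        if is_clf:
            totals = values.sum(axis=1, keepdims=True)
            node_value = (values / np.where(totals == 0, 1.0, totals))[:, -1]
        else:
            node_value = values[:, 0]
        base += node_value[0]
        path = tree.decision_path(X.astype(np.float32))
        indptr, indices = path.indptr, path.indices
        feature = tree.feature
        for i in range(n_samples):
            nodes = indices[indptr[i] : indptr[i + 1]]
            for parent, child in zip(nodes[:-1], nodes[1:]):
                contributions[i, feature[parent]] += node_value[child] - node_value[parent]
    n_trees = len(estimators)
    return base / n_trees, contributions / n_trees


def feature_attributions(
    model,
    feature_matrix: pd.DataFrame | np.ndarray,
    mode: str = "tree",
    labels: np.ndarray | None = None,
    seed: int = 0,
) -> AttributionReport:
    """Explain forest predictions feature by feature.

    ``tree`` mode gives local per-sample contributions satisfying local
    accuracy; ``permutation`` mode (requires ``labels``) gives global
    importances only. Column names must match the order the model was
    trained with.
    """
    if isinstance(feature_matrix, pd.DataFrame):
        names = list(feature_matrix.columns)
        X = feature_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(feature_matrix, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    trained = getattr(model, "feature_names_in_", None)
    if trained is not None and isinstance(feature_matrix, pd.DataFrame):
        if list(trained) != names:
            raise ValueError("feature columns do not match the training order")

    if mode == "tree":
        base, contributions = _tree_path_contributions(model, X)
        importance = pd.Series(
            np.abs(contributions).mean(axis=0), index=names
        ).sort_values(ascending=False, kind="mergesort")
        return AttributionReport(
            base_value=base,
            contributions=contributions,
            feature_names=names,
            global_importance=importance,
            mode="tree",
        )
    if mode == "permutation":
        if labels is None:
            raise ValueError("permutation mode requires labels")
        result = permutation_importance(
            model, X, labels, n_repeats=5, random_state=seed
        )
        importance = pd.Series(result.importances_mean, index=names).sort_values(
            ascending=False, kind="mergesort"
        )
        return AttributionReport(
            base_value=float("nan"),
            contributions=None,
            feature_names=names,
            global_importance=importance,
            mode="permutation",
        )
    raise ValueError(f"unknown attribution mode {mode!r}")


def demographic_parity_gap(
    predicted_labels: np.ndarray, groups: Sequence[str]
) -> float:
    """Largest pairwise absolute difference in positive-prediction rates."""
    predicted_labels = np.asarray(predicted_labels, dtype=bool)
    groups = np.asarray(groups)
    names = np.unique(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups for a parity gap")
    rates = []
    for g in names:
        mask = groups == g
        if not mask.any():
            raise ValueError(f"group {g!r} is empty")
        rates.append(predicted_labels[mask].mean())
    rates = np.array(rates)
    return float(rates.max() - rates.min())


def subgroup_performance(
    labels: np.ndarray,
    scores: np.ndarray,
    groups: Sequence[str],
    grouping: str = "group",
    threshold: float = 0.5,
    min_group_size: int = 10,
) -> SubgroupReport:
    """Classification performance per subgroup, with fairness gaps.

    Groups smaller than ``min_group_size`` are reported and flagged, never
    silently dropped. Gaps are max-minus-min across groups where the metric
    is defined.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    names = list(np.unique(groups))
    if not names:
        raise ValueError("no groups supplied")
    predicted = scores >= threshold
    per_group: dict[str, MetricsReport] = {}
    sizes: dict[str, int] = {}
    flagged: list[str] = []
    sens, spec = [], []
    for g in names:
        mask = groups == g
        sizes[str(g)] = int(mask.sum())
        if mask.sum() < min_group_size:
            flagged.append(str(g))
        rep = classification_metrics(labels[mask], predicted[mask], scores[mask])
        per_group[str(g)] = rep
        if "sensitivity" in rep.metrics:
            sens.append(rep.metrics["sensitivity"][0])
        if "specificity" in rep.metrics:
            spec.append(rep.metrics["specificity"][0])
    parity = demographic_parity_gap(predicted, groups) if len(names) >= 2 else 0.0
    return SubgroupReport(
        grouping=grouping,
        per_group=per_group,
        group_sizes=sizes,
        parity_gap=parity,
        sensitivity_gap=(max(sens) - min(sens)) / 100.0 if len(sens) >= 2 else None,
        specificity_gap=(max(spec) - min(spec)) / 100.0 if len(spec) >= 2 else None,
        flagged_small=flagged,
    )


def spearman_rank(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman's rank correlation with two-sided t-approximation p-value.

    Zero variance in either input leaves the correlation undefined
    (flagged), not NaN-propagated into downstream arithmetic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(r=float("nan"), p=float("nan"), defined=False)
    res = stats.spearmanr(x, y)
    return SpearmanResult(r=float(res.statistic), p=float(res.pvalue), defined=True)


def probability_severity_profile(
    scores: np.ndarray, mmse: Sequence[int]
) -> tuple[pd.DataFrame, SpearmanResult]:
    """Mean predicted probability per MMSE severity group, plus the
    score-MMSE Spearman correlation.

    In a well-calibrated screening model the group means decrease from
    severe to CN and the correlation is negative (worse cognition, higher
    predicted risk).
    """
    scores = np.asarray(scores, dtype=float)
    mmse = np.asarray(mmse)
    if scores.size == 0 or scores.size != mmse.size:
        raise ValueError("scores and mmse must be same nonzero length")
    group = np.array([mmse_to_group(m) for m in mmse])
    rows = []
    for g in ("severe", "moderate", "MCI", "CN"):
        mask = group == g
        if not mask.any():
            continue
        rows.append(
            {
                "group": g,
                "mean_score": float(scores[mask].mean()),
                "sd_score": float(scores[mask].std(ddof=0)),
                "n": int(mask.sum()),
            }
        )
    profile = pd.DataFrame(rows).set_index("group")
    corr = spearman_rank(scores, mmse.astype(float))
    return profile, corr
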