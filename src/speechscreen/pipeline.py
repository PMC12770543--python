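"""Random-forest screening models with cross-validated and bootstrapped
evaluation.

Two tasks share one interface: ``detect`` (binary ADRD classification from
the 100-feature linguistic vector; random forest of 50 trees, depth 16) and
``severity`` (MMSE regression; random forest with a minimum of two samples
per leaf). Evaluation follows the screening-study protocol: 10-fold
stratified cross-validation for validation metrics and out-of-fold scores,
and a 10-repeat bootstrap for the test set — each repeat refits on a
bootstrap resample of the training set and evaluates on the fixed,
never-resampled test set, with the 95% CI taken as mean ± 1.96 SD across
repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "ModelSpec",
    "MetricsReport",
    "build_model",
    "classification_metrics",
    "regression_metrics",
    "cross_validate",
    "bootstrap_test_evaluation",
    "calibration_curve",
    "mmse_to_group",
    "MMSE_GROUPS",
]

MMSE_GROUPS = ("CN", "MCI", "moderate", "severe")


@dataclass(frozen=True)
class ModelSpec:
    """Model family and hyperparameters for one task.

    Defaults pin the hyperparameters selected in the screening study:
    detection uses 50 trees of depth 16; severity regression uses a minimum
    of two samples per leaf.
    """

    task: Literal["detect", "severity"] = "detect"
    n_trees: int = 50
    max_depth: int | None = 16
    min_samples_leaf: int = 1
    seed: int = 0

    @classmethod
    def detect(cls, seed: int = 0) -> "ModelSpec":
        return cls(task="detect", n_trees=50, max_depth=16, min_samples_leaf=1, seed=seed)

    @classmethod
    def severity(cls, seed: int = 0) -> "ModelSpec":
        return cls(task="severity", n_trees=50, max_depth=None, min_samples_leaf=2, seed=seed)


@dataclass
class MetricsReport:
    """Point estimates with dispersion for one evaluation protocol.

    ``metrics`` maps metric name -> (estimate, dispersion); classification
    metrics are percentages. ``ci`` carries (lower, upper) bounds when the
    provenance is bootstrap. ``undefined`` lists metrics that could not be
    computed (e.g. AUC on a single-class sample).
    """

    metrics: dict[str, tuple[float, float]]
    provenance: Literal["cv", "bootstrap", "point"]
    n_repeats: int = 1
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    undefined: list[str] = field(default_factory=list)


def build_model(spec: ModelSpec):
    """Instantiate the sklearn forest for a model spec (host-library
    defaults for anything the spec does not pin)."""
    if spec.task == "detect":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_depth=spec.max_depth,
            min_samples_leaf=spec.min_samples_leaf,
            random_state=spec.seed,
        )
    return RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_depth=spec.max_depth,
        min_samples_leaf=spec.min_samples_leaf,
        random_state=spec.seed,
    )


def classification_metrics(
    labels: np.ndarray,
    predicted_labels: np.ndarray,
    scores: np.ndarray | None = None,
) -> MetricsReport:
    """Sensitivity, specificity, accuracy and ROC-AUC, as percentages.

    ROC-AUC is the probability that a random positive outscores a random
    negative, ties counting one half. Single-class inputs leave the
    class-conditional metrics and AUC flagged undefined rather than NaN.
    """
    labels = np.asarray(labels, dtype=bool)
    predicted_labels = np.asarray(predicted_labels, dtype=bool)
    if labels.size == 0 or labels.size != predicted_labels.size:
        raise ValueError("labels and predictions must be same nonzero length")
    tp = int(np.sum(labels & predicted_labels))
    fn = int(np.sum(labels & ~predicted_labels))
    tn = int(np.sum(~labels & ~predicted_labels))
    fp = int(np.sum(~labels & predicted_labels))
    metrics: dict[str, tuple[float, float]] = {
        "accuracy": (100.0 * (tp + tn) / labels.size, 0.0)
    }
    undefined: list[str] = []
    if tp + fn > 0:
        metrics["sensitivity"] = (100.0 * tp / (tp + fn), 0.0)
    else:
        undefined.append("sensitivity")
    if tn + fp > 0:
        metrics["specificity"] = (100.0 * tn / (tn + fp), 0.0)
    else:
        undefined.append("specificity")
    if scores is not None:
        if labels.any() and not labels.all():
            metrics["roc_auc"] = (100.0 * float(roc_auc_score(labels, scores)), 0.0)
        else:
            undefined.append("roc_auc")
    return MetricsReport(metrics=metrics, provenance="point", undefined=undefined)


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> MetricsReport:
    """MAE and RMSE (same units as the target; RMSE >= MAE always)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0 or y.size != yhat.size:
        raise ValueError("y and yhat must be same nonzero length")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    return MetricsReport(
        metrics={"mae": (mae, 0.0), "rmse": (rmse, 0.0)}, provenance="point"
    )


def cross_validate(
    features: np.ndarray,
    targets: np.ndarray,
    spec: ModelSpec,
    k: int = 10,
) -> tuple[MetricsReport, np.ndarray]:
    """K-fold cross-validation; returns fold-mean (SD) metrics and the
    out-of-fold score for every sample (each scored exactly once).

    Folds are stratified by label for the detection task. Deterministic
    given ``spec.seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets)
    if len(X) < k:
        raise ValueError(f"n={len(X)} < k={k}; use a smaller k")
    if spec.task == "detect":
        y = y.astype(bool)
        smallest = min(int(y.sum()), int((~y).sum()))
        if smallest < k:
            raise ValueError(
                f"smallest class has {smallest} members < k={k}; use a smaller k"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=spec.seed)

    oof = np.full(len(X), np.nan)
    fold_metrics: dict[str, list[float]] = {}
    for fold_i, (tr, va) in enumerate(splitter.split(X, y if spec.task == "detect" else None)):
        model = build_model(
            ModelSpec(spec.task, spec.n_trees, spec.max_depth,
                      spec.min_samples_leaf, spec.seed + fold_i)
        )
        model.fit(X[tr], y[tr])
        if spec.task == "detect":
            scores = model.predict_proba(X[va])[:, 1]
            report = classification_metrics(y[va], scores >= 0.5, scores)
        else:
            scores = model.predict(X[va])
            report = regression_metrics(y[va], scores)
        oof[va] = scores
        for name, (value, _) in report.metrics.items():
            fold_metrics.setdefault(name, []).append(value)

    summary = {
        name: (float(np.mean(vals)), float(np.std(vals, ddof=1)))
        for name, vals in fold_metrics.items()
    }
    return MetricsReport(metrics=summary, provenance="cv", n_repeats=k), oof


def bootstrap_test_evaluation(
    train_features: np.ndarray,
    train_targets: np.ndarray,
    test_features: np.ndarray,
    test_targets: np.ndarray,
    spec: ModelSpec,
    n_repeats: int = 10,
    threshold: float = 0.5,
    max_retries: int = 100,
) -> tuple[MetricsReport, np.ndarray]:
    """Bootstrap evaluation on a fixed test set.

    Each of the ``n_repeats`` repeats draws a bootstrap resample (with
    replacement, size n_train) of the training set, refits, and evaluates on
    the unchanged test set. Reports mean and 95% CI (mean ± 1.96 SD across
    repeats) per metric, plus the per-repeat mean test score matrix averaged
    into one score per test sample.
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 bootstrap repeats")
    Xtr = np.asarray(train_features, dtype=float)
    ytr = np.asarray(train_targets)
    Xte = np.asarray(test_features, dtype=float)
    yte = np.asarray(test_targets)
    rng = np.random.default_rng(spec.seed)
    n_train = len(Xtr)

    repeat_metrics: dict[str, list[float]] = {}
    test_scores = np.zeros((n_repeats, len(Xte)))
    for b in range(n_repeats):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n_train, size=n_train)
            if spec.task != "detect":
                break
            lab = ytr[idx].astype(bool)
            if lab.any() and not lab.all():
                break
        else:
            raise RuntimeError(
                f"bootstrap repeat {b}: could not draw a two-class resample "
                f"in {max_retries} retries"
            )
        model = build_model(
            ModelSpec(spec.task, spec.n_trees, spec.max_depth,
                      spec.min_samples_leaf, spec.seed + 1000 + b)
        )
        model.fit(Xtr[idx], ytr[idx])
        if spec.task == "detect":
            scores = model.predict_proba(Xte)[:, 1]
            report = classification_metrics(
                yte.astype(bool), scores >= threshold, scores
            )
        else:
            scores = model.predict(Xte)
            report = regression_metrics(yte, scores)
        test_scores[b] = scores
        for name, (value, _) in report.metrics.items():
            repeat_metrics.setdefault(name, []).append(value)

    summary: dict[str, tuple[float, float]] = {}
    ci: dict[str, tuple[float, float]] = {}
    for name, vals in repeat_metrics.items():
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        summary[name] = (mean, sd)
        ci[name] = (mean - 1.96 * sd, mean + 1.96 * sd)
    report = MetricsReport(
        metrics=summary, provenance="bootstrap", n_repeats=n_repeats, ci=ci
    )
    return report, test_scores.mean(axis=0)


def calibration_curve(
    scores: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> list[tuple[float, float, int]]:
    """Reliability curve: per equal-width bin on [0, 1], the mean score,
    observed event rate and count. Empty bins are omitted; counts sum to n.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        mask = bin_idx == b
        if not mask.any():
            continue
        out.append(
            (float(scores[mask].mean()), float(labels[mask].mean()), int(mask.sum()))
        )
    return out


def mmse_to_group(mmse: int | float) -> str:
    """Severity group from MMSE: CN (26, 30], MCI (20, 26],
    moderate [10, 20], severe [0, 10)."""
    if not 0 <= mmse <= 30:
        raise ValueError(f"MMSE {mmse} outside [0, 30]")
    if mmse > 26:
        return "CN"
    if mmse > 20:
        return "MCI"
    if mmse >= 10:
        return "moderate"
    return "severe"
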