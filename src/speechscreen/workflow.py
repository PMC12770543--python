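"""End-to-end orchestration: simulate/load -> features -> models -> triage -> reports.

A single :class:`RunConfig` drives the whole analysis; every source of
randomness derives from its ``seed``. :func:`run_all` returns a results
bundle (plain dicts/DataFrames) and optionally writes the full report set —
metrics JSON, out-of-fold scores, threshold trace, zone assignments,
attribution matrix, subgroup tables and a run manifest — under one output
directory.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

import sklearn

from . import __version__
from .corpus import ParticipantRecord, Transcript, load_dictionary, read_cohort, write_cohort
from .features import default_dictionary, extract_feature_table, write_feature_table
from .pipeline import (
    ModelSpec,
    bootstrap_test_evaluation,
    build_model,
    calibration_curve,
    cross_validate,
)
from .reporting import (
    feature_attributions,
    probability_severity_profile,
    subgroup_performance,
)
from .synthetic import CohortConfig, generate_cohort, label_from_mmse
from .triage import assign_risk_many, grid_search_thresholds, selective_metrics

__all__ = ["RunConfig", "simulate_to_dir", "run_all"]


class RunConfig(BaseModel):
    """Declarative configuration for one analysis run; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    corpus_dir: str | None = None
    metadata_path: str | None = None
    dictionary_path: str | None = None
    output_dir: str | None = None
    seed: int = 0
    # simulation (used when corpus_dir is None)
    n_participants: int = 300
    adrd_prevalence: float = 0.5
    effect_size: str = "strong"
    # modelling
    n_trees: int = 50
    max_depth: int | None = 16
    min_samples_leaf_regressor: int = 2
    cv_folds: int = 10
    bootstrap_repeats: int = 10
    # triage
    grid_resolution: float = 0.05
    min_coverage: float = 0.5
    threshold: float = Field(0.5, description="operating point for predicted class")


def _manifest(config: RunConfig) -> dict[str, Any]:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return {
        "config": config.model_dump(),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "versions": {
            "speechscreen": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
    }


def simulate_to_dir(
    config: CohortConfig, out_dir: Path | str
) -> tuple[list[Transcript], list[ParticipantRecord], pd.DataFrame]:
    """Generate a cohort and write it in the corpus format the loader reads."""
    out_dir = Path(out_dir)
    transcripts, records, truth = generate_cohort(config)
    write_cohort(transcripts, records, out_dir / "transcripts", out_dir / "metadata.csv")
    truth.to_csv(out_dir / "truth.csv")
    return transcripts, records, truth


def _metrics_dict(report) -> dict[str, Any]:
    out: dict[str, Any] = {
        name: {"mean": mean, "dispersion": disp}
        for name, (mean, disp) in report.metrics.items()
    }
    for name, (lo, hi) in report.ci.items():
        out[name]["ci95"] = [lo, hi]
    return {
        "provenance": report.provenance,
        "n_repeats": report.n_repeats,
        "metrics": out,
        "undefined": report.undefined,
    }


def run_all(
    config: RunConfig,
    write_outputs: bool = True,
) -> dict[str, Any]:
    """Run the full screening analysis and return the results bundle.

    Stages: load or simulate the cohort; extract the 100-feature table;
    10-fold CV on the training split (detection and severity) for validation
    metrics and out-of-fold scores; 10-repeat bootstrap evaluation on the
    fixed test split; traffic-light threshold search on the validation
    scores and selective metrics on the test set; attribution, calibration,
    subgroup-fairness and probability-severity reports.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- corpus ---
    if config.corpus_dir is not None:
        if config.metadata_path is None:
            raise ValueError("metadata_path is required with corpus_dir")
        transcripts, records = read_cohort(config.corpus_dir, config.metadata_path)
    else:
        sim = CohortConfig(
            n_participants=config.n_participants,
            adrd_prevalence=config.adrd_prevalence,
            effect_size=config.effect_size,  # type: ignore[arg-type]
            seed=config.seed,
        )
        if out_dir:
            transcripts, records, _ = simulate_to_dir(sim, out_dir / "cohort")
        else:
            transcripts, records, _ = generate_cohort(sim)

    dictionary = (
        load_dictionary(config.dictionary_path)
        if config.dictionary_path
        else default_dictionary()
    )

    # --- features ---
    features = extract_feature_table(transcripts, dictionary)
    by_id = {r.participant_id: r for r in records}
    meta = pd.DataFrame(
        {
            "split": [by_id[p].split for p in features.index],
            "sex": [by_id[p].sex for p in features.index],
            "age": [by_id[p].age for p in features.index],
            "mmse": [by_id[p].mmse for p in features.index],
            "diagnosis": [by_id[p].diagnosis for p in features.index],
        },
        index=features.index,
    )
    if meta["diagnosis"].notna().all():
        labels = (meta["diagnosis"] == "ADRD").to_numpy()
    else:
        labels = label_from_mmse(records)

    train_mask = (meta["split"] == "train").to_numpy()
    test_mask = (meta["split"] == "test").to_numpy()
    X, y = features.to_numpy(dtype=float), labels
    Xtr, ytr = X[train_mask], y[train_mask]
    Xte, yte = X[test_mask], y[test_mask]

    results: dict[str, Any] = {"features": features, "meta": meta, "labels": labels}

    # --- detection ---
    detect_spec = ModelSpec.detect(seed=config.seed)
    cv_report, oof_scores = cross_validate(Xtr, ytr, detect_spec, k=config.cv_folds)
    boot_report, test_scores = bootstrap_test_evaluation(
        Xtr, ytr, Xte, yte, detect_spec,
        n_repeats=config.bootstrap_repeats, threshold=config.threshold,
    )
    results["detect"] = {
        "cv": cv_report,
        "bootstrap": boot_report,
        "oof_scores": oof_scores,
        "test_scores": test_scores,
        "calibration": calibration_curve(oof_scores, ytr.astype(float), n_bins=10),
    }

    # --- severity regression (participants with MMSE) ---
    mmse_all = meta["mmse"].to_numpy(dtype=float)
    severity_spec = ModelSpec(
        task="severity",
        n_trees=config.n_trees,
        max_depth=None,
        min_samples_leaf=config.min_samples_leaf_regressor,
        seed=config.seed,
    )
    sev_cv, sev_oof = cross_validate(
        Xtr, mmse_all[train_mask], severity_spec, k=config.cv_folds
    )
    sev_boot, mmse_pred = bootstrap_test_evaluation(
        Xtr, mmse_all[train_mask], Xte, mmse_all[test_mask], severity_spec,
        n_repeats=config.bootstrap_repeats,
    )
    results["severity"] = {
        "cv": sev_cv,
        "bootstrap": sev_boot,
        "oof_predictions": sev_oof,
        "test_predictions": mmse_pred,
    }

    # --- triage ---
    thresholds, trace = grid_search_thresholds(
        oof_scores, ytr, resolution=config.grid_resolution,
        min_coverage=config.min_coverage,
    )
    zones = assign_risk_many(test_scores, thresholds)
    selective = selective_metrics(test_scores, yte, thresholds)
    results["triage"] = {
        "thresholds": thresholds,
        "trace": trace,
        "zones": zones,
        "selective": selective,
    }

    # --- reporting ---
    final_model = build_model(detect_spec)
    final_model.fit(features.loc[train_mask], ytr)
    attribution = feature_attributions(final_model, features.loc[test_mask], mode="tree")
    profile, score_mmse_corr = probability_severity_profile(
        test_scores, mmse_all[test_mask].astype(int)
    )
    subgroup_sex = subgroup_performance(
        yte, test_scores, meta.loc[test_mask, "sex"].to_numpy(),
        grouping="sex", threshold=config.threshold,
    )
    age_test = meta.loc[test_mask, "age"].to_numpy(dtype=float)
    age_groups = np.where(age_test <= np.median(age_test), "younger", "older")
    subgroup_age = subgroup_performance(
        yte, test_scores, age_groups, grouping="age", threshold=config.threshold
    )
    results["report"] = {
        "attribution": attribution,
        "profile": profile,
        "score_mmse_spearman": score_mmse_corr,
        "subgroup_sex": subgroup_sex,
        "subgroup_age": subgroup_age,
    }

    if out_dir:
        _write_bundle(out_dir, config, features, results)
    return results


def _write_bundle(out_dir: Path, config: RunConfig, features: pd.DataFrame, results) -> None:
    manifest = _manifest(config)
    write_feature_table(features, out_dir / "feature_table.csv")
    detect, triage, report = results["detect"], results["triage"], results["report"]
    metrics = {
        "detect_cv": _metrics_dict(detect["cv"]),
        "detect_test_bootstrap": _metrics_dict(detect["bootstrap"]),
        "severity_cv": _metrics_dict(results["severity"]["cv"]),
        "severity_test_bootstrap": _metrics_dict(results["severity"]["bootstrap"]),
        "selective_test": {
            "coverage": triage["selective"].coverage,
            "youden_j": triage["selective"].youden_j,
            "metrics": {
                k: v[0] for k, v in triage["selective"].metrics.items()
            },
        },
        "thresholds": {
            "t_low": triage["thresholds"].t_low,
            "t_high": triage["thresholds"].t_high,
        },
        "fairness": {
            "sex_parity_gap": report["subgroup_sex"].parity_gap,
            "sex_sensitivity_gap": report["subgroup_sex"].sensitivity_gap,
            "age_parity_gap": report["subgroup_age"].parity_gap,
        },
        "score_mmse_spearman_r": report["score_mmse_spearman"].r,
    }
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    triage["trace"].to_csv(out_dir / "threshold_trace.csv", index=False)
    meta = results["meta"]
    test_ids = features.index[(meta["split"] == "test").to_numpy()]
    pd.DataFrame(
        {
            "participant_id": test_ids,
            "score": detect["test_scores"],
            "zone": triage["zones"],
        }
    ).to_csv(out_dir / "zones.csv", index=False)
    attribution = report["attribution"]
    pd.DataFrame(
        attribution.contributions, index=test_ids, columns=attribution.feature_names
    ).to_csv(out_dir / "attributions.csv")
    report["profile"].to_csv(out_dir / "severity_profile.csv")
    manifest["outputs"] = sorted(p.name for p in out_dir.iterdir())
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
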