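import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from speechscreen.features import default_dictionary, extract_feature_table
from speechscreen.pipeline import ModelSpec, bootstrap_test_evaluation, cross_validate
from speechscreen.synthetic import CohortConfig, generate_cohort

STRONG_SEED = 13


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture(scope="session")
def strong_run():
    """One shared strong-effect analysis run: cohort of 450 (train 300 /
    test 150, stratified), 10-fold CV validation scores, and 10-repeat
    bootstrap test evaluation for both tasks."""
    transcripts, records, truth = generate_cohort(
        CohortConfig(n_participants=450, effect_size="strong", seed=STRONG_SEED)
    )
    features = extract_feature_table(transcripts)
    labels = np.array([r.diagnosis == "ADRD" for r in records])
    mmse = np.array([r.mmse for r in records])
    sex = np.array([r.sex for r in records])
    idx_train, idx_test = train_test_split(
        np.arange(len(records)), test_size=150, stratify=labels,
        random_state=STRONG_SEED,
    )
    X = features.to_numpy(dtype=float)
    detect_spec = ModelSpec.detect(seed=STRONG_SEED)
    cv_report, oof_scores = cross_validate(X[idx_train], labels[idx_train], detect_spec)
    boot_report, test_scores = bootstrap_test_evaluation(
        X[idx_train], labels[idx_train], X[idx_test], labels[idx_test], detect_spec
    )
    severity_spec = ModelSpec.severity(seed=STRONG_SEED)
    sev_report, mmse_pred = bootstrap_test_evaluation(
        X[idx_train], mmse[idx_train].astype(float),
        X[idx_test], mmse[idx_test].astype(float), severity_spec,
    )
    return {
        "seed": STRONG_SEED,
        "features": features,
        "labels": labels,
        "mmse": mmse,
        "sex": sex,
        "truth": truth,
        "idx_train": idx_train,
        "idx_test": idx_test,
        "detect_spec": detect_spec,
        "cv_report": cv_report,
        "oof_scores": oof_scores,
        "boot_report": boot_report,
        "test_scores": test_scores,
        "severity_report": sev_report,
        "mmse_pred": mmse_pred,
    }
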