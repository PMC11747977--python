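"""Two-stage automated classification with leave-one-subject-out evaluation.

Stage one detects independent components with a clear seizure transition;
stage two classifies ISI slowing (frequency falling to zero) among the
clear components.  Both use the same recipe: fold-wise median imputation
and robust scaling (median/IQR), a random forest capped at depth three,
and class weights inverse to class frequency.  Evaluation is
leave-one-subject-out: each patient forms one test fold, per-patient
balanced accuracy and (where both classes occur) AUC are reported, and
pooled metrics are computed over the concatenated test predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import RobustScaler

from .features import FeatureMatrix


@dataclass
class ClassifierConfig:
    max_depth: int = 3
    n_trees: int = 500
    class_weight: str = "balanced"
    seed: int = 0


@dataclass
class Scaler:
    median: np.ndarray
    iqr: np.ndarray
    degenerate: np.ndarray  # IQR == 0 flags (divisor forced to 1)
    columns: list[str]


def robust_scale(train_rows: pd.DataFrame) -> Scaler:
    """Fit a median/IQR scaler on training rows only (NaN-tolerant)."""
    med = train_rows.median().to_numpy()
    q1 = train_rows.quantile(0.25).to_numpy()
    q3 = train_rows.quantile(0.75).to_numpy()
    iqr = q3 - q1
    degenerate = ~(iqr > 0)
    iqr = np.where(degenerate, 1.0, iqr)
    return Scaler(median=med, iqr=iqr, degenerate=degenerate, columns=list(train_rows.columns))


def apply_scale(scaler: Scaler, rows: pd.DataFrame) -> pd.DataFrame:
    if list(rows.columns) != scaler.columns:
        raise ValueError("column mismatch between scaler and rows")
    return (rows - scaler.median) / scaler.iqr


def _impute_median(train: pd.DataFrame):
    med = train.median()
    med = med.fillna(0.0)  # all-NaN training column: neutral fill
    return med


def train_classifier(
    matrix: pd.DataFrame, labels: np.ndarray, config: ClassifierConfig | None = None
) -> RandomForestClassifier:
    """Depth-limited, class-weighted random forest on a scaled matrix."""
    config = config or ClassifierConfig()
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training labels contain a single class")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        class_weight=config.class_weight,
        random_state=config.seed,
        n_jobs=1,
    )
    clf.fit(matrix, labels)
    return clf


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of per-class recalls; undefined for single-class truth."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("balanced accuracy undefined: y_true has a single class")
    recalls = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(recalls))


def shap_feature_attribution(model, X: pd.DataFrame):
    """Optional hook: per-feature SHAP attributions for a fitted forest.

    Requires the optional ``shap`` package; not part of the tested
    contract.
    """
    try:
        import shap
    except ImportError as exc:
        raise ImportError(
            "SHAP attribution requires the optional 'shap' package"
        ) from exc
    return shap.TreeExplainer(model).shap_values(X)


@dataclass
class CvReport:
    per_patient: pd.DataFrame  # patient, n, ba, ba_is_balanced, auc
    predictions: pd.DataFrame  # patient, y_true, y_pred, proba
    pooled_ba: float
    pooled_auc: float
    task: str = ""
    config: ClassifierConfig = field(default_factory=ClassifierConfig)


def loocv_evaluate(
    matrix: FeatureMatrix | pd.DataFrame,
    labels,
    patient_ids,
    config: ClassifierConfig | None = None,
    task: str = "",
) -> CvReport:
    """Leave-one-subject-out cross-validation of the two-stage classifier.

    Imputation and scaling are fitted inside each training fold; the held
    patient's rows never inform them.  Per-patient balanced accuracy is
    reported for every patient — for a patient with a single class it
    degrades to the recall of the present class and is flagged
    ``ba_is_balanced=False``.  AUC is reported only where both classes
    occur.  Pooled metrics are computed over all concatenated predictions.
    """
    config = config or ClassifierConfig()
    X = matrix.X if isinstance(matrix, FeatureMatrix) else matrix
    y = np.asarray(labels)
    pids = np.asarray(patient_ids)
    if X.shape[0] != y.size or y.size != pids.size:
        raise ValueError("matrix, labels and patient_ids must align")
    patients = pd.unique(pids)
    if patients.size < 2:
        raise ValueError("need at least 2 patients for leave-one-subject-out")
    master = np.random.SeedSequence(config.seed)
    fold_seeds = master.generate_state(patients.size) % (2**31 - 1)
    rows, preds = [], []
    for patient, fold_seed in zip(patients, fold_seeds):
        test_mask = pids == patient
        if not test_mask.any():
            continue
        train_mask = ~test_mask
        Xtr, ytr = X[train_mask], y[train_mask]
        Xte, yte = X[test_mask], y[test_mask]
        med = _impute_median(Xtr)
        Xtr = Xtr.fillna(med)
        Xte = Xte.fillna(med)
        scaler = robust_scale(Xtr)
        Xtr = apply_scale(scaler, Xtr)
        Xte = apply_scale(scaler, Xte)
        clf = train_classifier(
            Xtr, ytr,
            ClassifierConfig(config.max_depth, config.n_trees, config.class_weight,
                             int(fold_seed)),
        )
        pos = clf.classes_[-1]  # positive class: last in sort order
        proba = clf.predict_proba(Xte)[:, list(clf.classes_).index(pos)]
        y_pred = clf.predict(Xte)
        classes_here = np.unique(yte)
        if classes_here.size >= 2:
            ba = balanced_accuracy(yte, y_pred)
            balanced = True
            auc = float(roc_auc_score(yte == pos, proba))
        else:
            c = classes_here[0]
            ba = float(np.mean(y_pred == c))
            balanced = False
            auc = np.nan
        rows.append(
            {"patient": patient, "n": int(test_mask.sum()), "ba": ba,
             "ba_is_balanced": balanced, "auc": auc}
        )
        for yt, yp, pr in zip(yte, y_pred, proba):
            preds.append({"patient": patient, "y_true": yt, "y_pred": yp,
                          "proba": float(pr)})
    per_patient = pd.DataFrame(rows)
    predictions = pd.DataFrame(preds)
    pooled_ba = balanced_accuracy(predictions["y_true"], predictions["y_pred"])
    pos_global = np.unique(y)[-1]
    pooled_auc = float(
        roc_auc_score(predictions["y_true"] == pos_global, predictions["proba"])
    )
    return CvReport(
        per_patient=per_patient,
        predictions=predictions,
        pooled_ba=pooled_ba,
        pooled_auc=pooled_auc,
        task=task,
        config=config,
    )
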