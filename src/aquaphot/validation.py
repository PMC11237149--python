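"""Internal (leave-one-out) and external (75/25) validation.

All splitting and hold-out happens at the *subject* level by default: the
three replicate spectra of one subject always travel together, so a model
is never judged on a replicate of a subject it has already seen (replicate
leakage would otherwise inflate accuracy).  Spectrum-level units remain
available for comparison.

Quality metrics follow the diagnostic-screening conventions:
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), and a total-accuracy
variant that weights each class's count by its own rate,
(TN*(TN/(TN+FP)) + TP*(TP/(TP+FN))) / n — which never exceeds the plain
accuracy (TP+TN)/n, reported alongside.  Metrics with an empty denominator
are missing (NA), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd

from . import models as _models
from . import preprocess as _pre
from .spectra_io import SpectraSet


# ---------------------------------------------------------------------------
# Confusion matrices and metrics


@dataclass
class ConfusionMatrix:
    """One-vs-rest counts per class; TP+FP+TN+FN = n for every class."""

    classes: list[str]
    counts: dict[str, dict[str, int]]
    n_evaluated: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=object)
        y_pred = np.asarray(y_pred, dtype=object)
        if y_true.shape != y_pred.shape:
            raise ValueError("prediction/label length mismatch")
        classes = sorted({str(v) for v in y_true} | {str(v) for v in y_pred})
        counts = {}
        for c in classes:
            tp = int(np.sum((y_true == c) & (y_pred == c)))
            fn = int(np.sum((y_true == c) & (y_pred != c)))
            fp = int(np.sum((y_true != c) & (y_pred == c)))
            tn = int(np.sum((y_true != c) & (y_pred != c)))
            counts[c] = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
        return cls(classes, counts, int(y_true.size))

    def to_dict(self) -> dict:
        return {"classes": self.classes, "counts": self.counts, "n": self.n_evaluated}


def sensitivity(cm: ConfusionMatrix, cls: str) -> float | None:
    """100 * TP / (TP + FN); None (missing) when no positives were evaluated."""
    c = cm.counts[cls]
    denom = c["TP"] + c["FN"]
    return 100.0 * c["TP"] / denom if denom > 0 else None


def specificity(cm: ConfusionMatrix, cls: str) -> float | None:
    """100 * TN / (TN + FP); None when no negatives were evaluated."""
    c = cm.counts[cls]
    denom = c["TN"] + c["FP"]
    return 100.0 * c["TN"] / denom if denom > 0 else None


def total_accuracy(cm: ConfusionMatrix, cls: str) -> float | None:
    """Rate-weighted total accuracy for one target class.

    (TN*(TN/(TN+FP)) + TP*(TP/(TP+FN))) / (TN+FP+TP+FN) * 100.  Each
    correct count is discounted by its own class rate, so the value is
    bounded above by the plain accuracy.
    """
    c = cm.counts[cls]
    pos, neg = c["TP"] + c["FN"], c["TN"] + c["FP"]
    n = pos + neg
    if n == 0 or pos == 0 or neg == 0:
        return None
    return 100.0 * (c["TN"] * (c["TN"] / neg) + c["TP"] * (c["TP"] / pos)) / n


def standard_accuracy(cm: ConfusionMatrix, cls: str | None = None) -> float | None:
    """Plain accuracy: one-vs-rest 100*(TP+TN)/n for a class, or multiclass."""
    if cm.n_evaluated == 0:
        return None
    if cls is None:
        correct = sum(cm.counts[c]["TP"] for c in cm.classes)
        return 100.0 * correct / cm.n_evaluated
    c = cm.counts[cls]
    return 100.0 * (c["TP"] + c["TN"]) / cm.n_evaluated


# ---------------------------------------------------------------------------
# Splitting


def split_calibration_test(s: SpectraSet, frac: float = 0.75, seed: int = 0,
                           label_field: str = "label2") -> tuple[SpectraSet, SpectraSet]:
    """Stratified subject-level split: round(frac * n_subjects) per class.

    All replicates of a subject land on the same side; every class keeps at
    least one subject on each side (classes with a single subject are
    rejected).  Deterministic given the seed.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    per_subject = s.meta.drop_duplicates("subject_id")[["subject_id", label_field]]
    cal_subjects: list[str] = []
    test_subjects: list[str] = []
    for cls, group in per_subject.groupby(label_field, sort=True):
        subjects = group["subject_id"].tolist()
        if len(subjects) < 2:
            raise ValueError(
                f"class {cls!r} has {len(subjects)} subject(s); need >= 2 to "
                "place one on each side of the split"
            )
        order = rng.permutation(len(subjects))
        n_cal = int(np.floor(frac * len(subjects) + 0.5))
        n_cal = min(max(n_cal, 1), len(subjects) - 1)
        shuffled = [subjects[i] for i in order]
        cal_subjects += shuffled[:n_cal]
        test_subjects += shuffled[n_cal:]
    return s.select_subjects(cal_subjects), s.select_subjects(test_subjects)


# ---------------------------------------------------------------------------
# Model plumbing shared by LOO and external validation


@dataclass
class ModelSpec:
    """Classifier recipe: kind in {LDA, QDA, SVM} plus keyword params."""

    kind: str = "LDA"
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = self.kind.upper()
        if self.kind not in ("LDA", "QDA", "SVM"):
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class FittedCell:
    """Pretreatment + PCA + classifier, all fitted on calibration data only."""

    pipeline: _pre.FittedPipeline
    pca: _models.PCAModel
    k: int
    classifier: Any
    model_spec: ModelSpec
    step: float

    def predict_spectra(self, s: SpectraSet) -> np.ndarray:
        a = self.pipeline.transform_matrix(s.absorbance, self.step)
        scores = self.pca.transform(a)[:, : self.k]
        return self.classifier.predict(scores)

    def calibration_scores(self) -> np.ndarray:
        return self.pca.scores[:, : self.k]


def fit_cell(train: SpectraSet, pipeline_spec: _pre.PreprocessSpec,
             model_spec: ModelSpec, label_field: str = "label2",
             pc_threshold: float = 99.0) -> FittedCell:
    """Fit the full pretreatment -> PCA -> classifier chain on one training set."""
    step = train.step or 1.0
    pipeline = _pre.fit_pipeline(train, pipeline_spec)
    a = pipeline.transform_matrix(train.absorbance, step)
    pca = _models.pca_fit(a)
    k = _models.select_components(pca, pc_threshold)
    scores = pca.scores[:, :k]
    labels = train.labels(label_field)
    if model_spec.kind == "LDA":
        clf = _models.lda_fit(scores, labels, **model_spec.params)
    elif model_spec.kind == "QDA":
        clf = _models.qda_fit(scores, labels, **model_spec.params)
    else:
        clf = _models.svm_fit(scores, labels, **model_spec.params)
    return FittedCell(pipeline, pca, k, clf, model_spec, step)


def _aggregate_subjects(meta: pd.DataFrame, y_pred: np.ndarray, label_field: str,
                        positive_first: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Majority vote over each subject's replicate predictions.

    Ties break toward the disease-positive class (screening favors
    sensitivity): any non-healthy candidate wins over healthy; among
    diseases, sorted order decides.
    """
    subjects, y_true_s, y_pred_s = [], [], []
    for sid, group in meta.groupby("subject_id", sort=True):
        idx = group.index.to_numpy()
        preds = pd.Series(y_pred[idx])
        counts = preds.value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) > 1 and positive_first:
            disease = sorted(c for c in top if c != "healthy")
            choice = disease[0] if disease else sorted(top)[0]
        else:
            choice = sorted(top)[0] if len(top) > 1 else top[0]
        subjects.append(sid)
        y_true_s.append(group[label_field].iloc[0])
        y_pred_s.append(choice)
    return np.array(subjects), np.array(y_true_s, dtype=object), np.array(y_pred_s, dtype=object)


def leave_one_out(s: SpectraSet, pipeline_spec: _pre.PreprocessSpec,
                  model_spec: ModelSpec, unit: str = "subject",
                  label_field: str = "label2",
                  pc_threshold: float = 99.0) -> ConfusionMatrix:
    """Leave-one-unit-out cross-validation with fit-on-train pretreatment.

    Each fold refits pretreatment statistics, PCA and the classifier on the
    retained spectra and predicts the held-out unit; a held-out subject's
    replicate predictions are reduced by majority vote (ties toward the
    disease class).  A fold that would lose an entire class is an error.
    """
    if unit not in ("subject", "spectrum"):
        raise ValueError("unit must be 'subject' or 'spectrum'")
    meta = s.meta
    units = sorted(meta["subject_id"].unique()) if unit == "subject" else list(meta["id"])
    if len(units) < 3:
        raise ValueError(f"need at least 3 {unit}s for leave-one-out, got {len(units)}")
    y_true, y_pred = [], []
    all_classes = set(meta[label_field])
    for u in units:
        mask_out = (meta["subject_id"] == u if unit == "subject" else meta["id"] == u).to_numpy()
        train = s.select_rows(np.flatnonzero(~mask_out))
        held = s.select_rows(np.flatnonzero(mask_out))
        if set(train.meta[label_field]) != all_classes:
            raise ValueError(f"fold holding out {u!r} loses an entire class")
        cell = fit_cell(train, pipeline_spec, model_spec, label_field, pc_threshold)
        preds = cell.predict_spectra(held)
        if unit == "subject":
            _, yt, yp = _aggregate_subjects(held.meta.reset_index(drop=True), preds, label_field)
            y_true += list(yt)
            y_pred += list(yp)
        else:
            y_true.append(held.meta[label_field].iloc[0])
            y_pred.append(preds[0])
    return ConfusionMatrix.from_predictions(y_true, y_pred)


def external_validation(calibration: SpectraSet, test: SpectraSet,
                        pipeline_spec: _pre.PreprocessSpec, model_spec: ModelSpec,
                        unit: str = "subject", label_field: str = "label2",
                        pc_threshold: float = 99.0) -> tuple[ConfusionMatrix, FittedCell]:
    """Fit once on the calibration subset, evaluate on the untouched test subset."""
    cell = fit_cell(calibration, pipeline_spec, model_spec, label_field, pc_threshold)
    preds = cell.predict_spectra(test)
    if unit == "subject":
        _, y_true, y_pred = _aggregate_subjects(test.meta.reset_index(drop=True), preds, label_field)
    else:
        y_true, y_pred = test.labels(label_field), preds
    return ConfusionMatrix.from_predictions(y_true, y_pred), cell


# ---------------------------------------------------------------------------
# Report


@dataclass
class ValidationReport:
    """Rows of per-cell, per-class metrics mirroring a results table."""

    rows: list[dict[str, Any]] = field(default_factory=list)

    def add_cell(self, model: str, range_tag: str, pretreatment: str, validation: str,
                 cm: ConfusionMatrix, k_pcs: int | None = None,
                 r2: float | None = None, rmsec: float | None = None,
                 status: str = "ok") -> None:
        for cls in cm.classes:
            self.rows.append({
                "model": model, "range": range_tag, "pretreatment": pretreatment,
                "validation": validation, "class": cls,
                "sensitivity": sensitivity(cm, cls),
                "specificity": specificity(cm, cls),
                "total_accuracy": total_accuracy(cm, cls),
                "standard_accuracy": standard_accuracy(cm, cls),
                "PCs": k_pcs, "r2": r2, "rmsec": rmsec, "status": status,
            })

    def add_failure(self, model: str, range_tag: str, pretreatment: str,
                    validation: str, message: str) -> None:
        self.rows.append({
            "model": model, "range": range_tag, "pretreatment": pretreatment,
            "validation": validation, "class": None, "sensitivity": None,
            "specificity": None, "total_accuracy": None, "standard_accuracy": None,
            "PCs": None, "r2": None, "rmsec": None, "status": f"error: {message}",
        })

    def to_frame(self) -> pd.DataFrame:
        from .spectra_io import REPORT_COLUMNS
        if not self.rows:
            return pd.DataFrame(columns=REPORT_COLUMNS)
        return pd.DataFrame(self.rows)
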