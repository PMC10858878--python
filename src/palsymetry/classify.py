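"""Patient-versus-healthy classification on the two indices.

An unregularized (maximum-likelihood) logistic regression on the raw
(SMM, DMS) feature pair is deliberately the whole model: the indices are
meant to carry the clinical signal, the classifier only draws the line.
Evaluation follows the small-sample protocol: leave-one-out cross-validation
produces one held-out probability per subject, the ROC over those pooled
probabilities gives the AUC, and the operating point is the Youden-optimal
cutoff (maximizing TPR - FPR, ties broken toward the larger threshold, i.e.
higher specificity), at which the confusion matrix and derived rates are
reported.  The rule "probability >= cutoff => patient" is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .cohort import SubjectRecord
from .errors import ValidationError

__all__ = [
    "LogisticModel",
    "CvPrediction",
    "RocReport",
    "fit_logistic",
    "loocv_probabilities",
    "roc_and_auc",
    "youden_optimal",
    "evaluate_records",
]


@dataclass(frozen=True)
class LogisticModel:
    intercept: float
    coef_smm: float
    coef_dms: float
    converged: bool
    n_iter: int
    separated: bool = False  # perfect separation handled by a small fixed ridge

    def predict_proba(self, smm, dms) -> np.ndarray:
        """Patient probability for index pairs (vectorized)."""
        z = self.intercept + self.coef_smm * np.asarray(smm) + self.coef_dms * np.asarray(dms)
        return expit(z)


@dataclass(frozen=True)
class CvPrediction:
    subject_id: str
    true_label: int  # patient=1, healthy=0
    probability: float


@dataclass(frozen=True)
class RocReport:
    """ROC points and AUC; cutoff/confusion fields are filled in by
    :func:`youden_optimal`."""

    points: np.ndarray  # (k, 3) columns fpr, tpr, threshold
    auc: float
    youden_cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    confusion: tuple[int, int, int, int] | None = None  # (tp, fn, fp, tn)


_FEATURES = ("smm", "dms")
_RIDGE_FALLBACK_C = 100.0  # fixed small ridge used only under perfect separation


def _design(records: Sequence[SubjectRecord]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[r.smm, r.dms] for r in records], dtype=float)
    y = np.array([1 if r.is_patient else 0 for r in records], dtype=int)
    return X, y


def _fit(X: np.ndarray, y: np.ndarray) -> LogisticModel:
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present to fit the classifier")
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10_000)
    clf.fit(X, y)
    # perfect ranking by a linear score <=> linearly separable <=> MLE diverges
    z = clf.decision_function(X)
    separated = bool(z[y == 1].min() > z[y == 0].max())
    if separated:
        clf = LogisticRegression(C=_RIDGE_FALLBACK_C, solver="lbfgs", max_iter=10_000)
        clf.fit(X, y)
    n_iter = int(np.max(clf.n_iter_))
    return LogisticModel(
        intercept=float(clf.intercept_[0]),
        coef_smm=float(clf.coef_[0, 0]),
        coef_dms=float(clf.coef_[0, 1]),
        converged=n_iter < 10_000,
        n_iter=n_iter,
        separated=separated,
    )


def fit_logistic(records: Sequence[SubjectRecord]) -> LogisticModel:
    """Maximum-likelihood logistic fit of patient-vs-healthy on (SMM, DMS).

    Perfectly separable data (where the MLE diverges) are refit with a small
    fixed ridge and flagged via ``separated``.
    """
    X, y = _design(records)
    return _fit(X, y)


def loocv_probabilities(records: Sequence[SubjectRecord]) -> list[CvPrediction]:
    """Leave-one-out held-out patient probabilities, one per subject, in
    input order.  Deterministic given the input."""
    records = list(records)
    if len(records) < 3:
        raise ValidationError(f"need at least 3 records for LOOCV, got {len(records)}")
    X, y = _design(records)
    preds: list[CvPrediction] = []
    for i, rec in enumerate(records):
        mask = np.ones(len(records), dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValidationError(
                f"holding out {rec.subject_id!r} leaves a single-class training fold"
            )
        model = _fit(X[mask], y[mask])
        preds.append(
            CvPrediction(
                subject_id=rec.subject_id,
                true_label=int(y[i]),
                probability=float(model.predict_proba(rec.smm, rec.dms)),
            )
        )
    return preds


def roc_and_auc(preds: Iterable[CvPrediction]) -> RocReport:
    """ROC over the pooled predictions (thresholds at each unique
    probability plus a sentinel) and trapezoidal AUC."""
    preds = list(preds)
    y = np.array([p.true_label for p in preds])
    prob = np.array([p.probability for p in preds])
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC needs both labels present")
    fpr, tpr, thr = roc_curve(y, prob, drop_intermediate=False)
    return RocReport(points=np.column_stack([fpr, tpr, thr]), auc=float(_trapezoid_auc(fpr, tpr)))


def youden_optimal(report: RocReport, preds: Iterable[CvPrediction]) -> RocReport:
    """Complete *report* with the Youden-optimal cutoff, confusion matrix
    and sensitivity/specificity/accuracy.

    The cutoff maximizes J = TPR - FPR; ties in J are broken toward the
    larger threshold (higher specificity).  Classification rule:
    probability >= cutoff => patient.
    """
    preds = list(preds)
    fpr, tpr, thr = report.points.T
    j = tpr - fpr
    finite = np.isfinite(thr)  # candidate cutoffs are observed probabilities
    j = np.where(finite, j, -np.inf)
    best = int(np.argmax(j))  # thresholds descend, so first max = largest cutoff
    cutoff = float(thr[best])
    y = np.array([p.true_label for p in preds])
    prob = np.array([p.probability for p in preds])
    called = prob >= cutoff
    tp = int(np.sum(called & (y == 1)))
    fn = int(np.sum(~called & (y == 1)))
    fp = int(np.sum(called & (y == 0)))
    tn = int(np.sum(~called & (y == 0)))
    return replace(
        report,
        youden_cutoff=cutoff,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / len(y),
        confusion=(tp, fn, fp, tn),
    )


def evaluate_records(records: Sequence[SubjectRecord]) -> tuple[list[CvPrediction], RocReport]:
    """LOOCV -> ROC/AUC -> Youden operating point, in one call."""
    preds = loocv_probabilities(records)
    report = youden_optimal(roc_and_auc(preds), preds)
    return preds, report
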