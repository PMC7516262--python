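"""Threshold screening and its evaluation battery.

Airflow limitation is suspected when FEV1% (100*FEV1/FVC) is strictly below
70%.  The evaluation compares leave-one-out predictions against reference
spirometry: sensitivity/specificity at the 70% rule, ROC/AUC with lower
FEV1% meaning more positive, Pearson correlations per index, and
Bland–Altman limits of agreement for repeated measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _auc, roc_curve as _sk_roc_curve

from .depth_io import SubjectRecord
from .errors import EvaluationError

__all__ = [
    "ScreeningResult",
    "RocCurve",
    "EvalReport",
    "AFL_THRESHOLD_PERCENT",
    "classify",
    "confusion_stats",
    "roc_curve",
    "pearson",
    "bland_altman",
    "evaluate_cohort",
]

AFL_THRESHOLD_PERCENT = 70.0


@dataclass(frozen=True)
class ScreeningResult:
    """Per-subject screening outcome against the spirometric reference."""

    subject_id: str
    fev1_percent_pred: float
    predicted_afl: bool
    reference_afl: bool


@dataclass(frozen=True)
class RocCurve:
    """ROC points (FPR, TPR) and the trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class EvalReport:
    """Aggregate screening evaluation."""

    sensitivity: float            # percent
    specificity: float            # percent
    roc: RocCurve | None = None
    pearson: list[dict] = field(default_factory=list)
    bland_altman: list[dict] = field(default_factory=list)
    results: list[ScreeningResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "pearson": self.pearson,
            "bland_altman": self.bland_altman,
            "results": [asdict(r) for r in self.results],
        }
        if self.roc is not None:
            d["roc"] = {
                "fpr": self.roc.fpr.tolist(),
                "tpr": self.roc.tpr.tolist(),
                "auc": self.roc.auc,
            }
        return d

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        return path


def classify(fev1_percent: float, threshold: float = AFL_THRESHOLD_PERCENT) -> bool:
    """True (airflow limitation suspected) iff FEV1% is strictly below the
    threshold; exactly 70.0 classifies negative."""
    if not np.isfinite(fev1_percent):
        raise ValueError("FEV1% must be finite")
    return bool(fev1_percent < threshold)


def confusion_stats(results: Sequence[ScreeningResult]) -> tuple[float, float]:
    """(sensitivity %, specificity %) of the screening decisions."""
    ref = np.array([r.reference_afl for r in results], dtype=bool)
    pred = np.array([r.predicted_afl for r in results], dtype=bool)
    if not ref.any() or ref.all():
        raise EvaluationError("need at least one positive and one negative reference")
    tp = int((pred & ref).sum())
    fn = int((~pred & ref).sum())
    tn = int((~pred & ~ref).sum())
    fp = int((pred & ~ref).sum())
    return 100.0 * tp / (tp + fn), 100.0 * tn / (tn + fp)


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC over FEV1% scores with "lower score = more positive" orientation.

    AUC is the trapezoidal area, equivalent to the Mann–Whitney statistic
    with tied score pairs contributing 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise EvaluationError("ROC needs both classes present")
    # negate scores so that low FEV1% ranks as most positive
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), -scores)
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(_auc(fpr, tpr)))


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p-value on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise EvaluationError("need matched samples of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise EvaluationError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(
    first: Sequence[float], second: Sequence[float]
) -> tuple[float, float, float]:
    """(mean difference, lower, upper 95% limits of agreement).

    Differences are first − second; limits are mean ± 1.96 * sample SD
    (n−1 denominator).
    """
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if first.shape != second.shape or first.ndim != 1 or first.size < 2:
        raise EvaluationError("need two equal-length vectors of length >= 2")
    diff = first - second
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def evaluate_cohort(
    predictions: pd.DataFrame,
    cohort: Sequence[SubjectRecord],
    threshold: float = AFL_THRESHOLD_PERCENT,
    repeat_predictions: pd.DataFrame | None = None,
) -> EvalReport:
    """Full evaluation of LOOCV predictions against reference spirometry.

    The reference label is the spirometric rule (spirometer FEV1% < 70),
    not the clinical group.  Computes sensitivity/specificity at the
    threshold, ROC/AUC over predicted FEV1%, Pearson correlations for FEV1,
    FVC and FEV1%, and (when a second run is supplied) Bland–Altman limits
    of agreement per index.
    """
    by_id = {r.subject_id: r for r in cohort}
    missing = set(predictions["subject_id"]) - set(by_id)
    if missing or len(predictions) != len(by_id):
        raise EvaluationError(f"subject id mismatch between predictions and cohort")

    results = []
    for _, row in predictions.iterrows():
        rec = by_id[row["subject_id"]]
        results.append(ScreeningResult(
            subject_id=rec.subject_id,
            fev1_percent_pred=float(row["fev1_percent_pred"]),
            predicted_afl=classify(float(row["fev1_percent_pred"]), threshold),
            reference_afl=classify(rec.fev1_percent_spirometer, threshold),
        ))
    sens, spec = confusion_stats(results)
    roc = roc_curve(
        [r.fev1_percent_pred for r in results],
        [r.reference_afl for r in results],
    )

    spiro = {
        "fev1": np.array([by_id[s].fev1_spirometer for s in predictions["subject_id"]]),
        "fvc": np.array([by_id[s].fvc_spirometer for s in predictions["subject_id"]]),
        "fev1_percent": np.array(
            [by_id[s].fev1_percent_spirometer for s in predictions["subject_id"]]
        ),
    }
    pred_cols = {"fev1": "fev1_pred", "fvc": "fvc_pred",
                 "fev1_percent": "fev1_percent_pred"}
    pearson_rows = []
    for name, col in pred_cols.items():
        r, p = pearson(predictions[col].to_numpy(), spiro[name])
        pearson_rows.append({"index": name, "r": r, "p": p})

    ba_rows = []
    if repeat_predictions is not None:
        merged = predictions.merge(
            repeat_predictions, on="subject_id", suffixes=("_1", "_2")
        )
        if len(merged) != len(predictions):
            raise EvaluationError("repeat run does not cover the same subjects")
        for name, col in pred_cols.items():
            m, lo, hi = bland_altman(
                merged[f"{col}_1"].to_numpy(), merged[f"{col}_2"].to_numpy()
            )
            ba_rows.append({
                "index": name, "mean_diff": m, "loa_low": lo, "loa_high": hi,
            })

    return EvalReport(
        sensitivity=sens,
        specificity=spec,
        roc=roc,
        pearson=pearson_rows,
        bland_altman=ba_rows,
        results=results,
    )
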