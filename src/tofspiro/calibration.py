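"""Calibration-free FVC regression and leave-one-out prediction.

The spirometer-grade FVC is predicted from the depth-camera anterior-thorax
FVC plus two anthropometric covariates by ordinary least squares:

    FVC_pred = a*FVC_anterior + b*Height + c*BMI + d

with volumes in mL, height in cm and BMI in kg/m².  The published fit on
the 53-subject study population is a = 0.55, b = 46.41, c = 0.29,
d = -5690.56.  Leave-one-out cross-validation predicts every subject from a
model fitted on the others, so no subject's own spirometry enters their
prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import LeaveOneOut
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .depth_io import SubjectRecord
from .errors import CalibrationError

__all__ = [
    "CalibrationModel",
    "FvcCalibrator",
    "published_model",
    "fit_model",
    "predict_fvc",
    "loocv_predict",
]

_MIN_FIT_ROWS = 5  # p + 2 observations for a 3-covariate + intercept model


@dataclass(frozen=True)
class CalibrationModel:
    """Coefficients of the FVC regression.

    ``a`` (mL per anterior mL), ``b`` (mL/cm), ``c`` (mL per kg/m²),
    ``d`` (mL intercept); ``n_fit`` counts the training subjects.
    """

    a: float
    b: float
    c: float
    d: float
    n_fit: int = 0

    def __post_init__(self) -> None:
        for name in "abcd":
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"coefficient {name} is not finite")

    def predict(self, fvc_anterior: float, height: float, bmi: float) -> float:
        return (
            self.a * fvc_anterior + self.b * height + self.c * bmi + self.d
        )


def published_model() -> CalibrationModel:
    """The regression fitted on the original 53-subject population."""
    return CalibrationModel(a=0.55, b=46.41, c=0.29, d=-5690.56, n_fit=53)


class FvcCalibrator(RegressorMixin, BaseEstimator):
    """Ordinary-least-squares FVC calibration, scikit-learn style.

    Feature matrix columns: ``[fvc_anterior_ml, height_cm, bmi]``; target:
    spirometer FVC in mL.  After ``fit`` the coefficients are exposed as
    ``coef_`` / ``intercept_`` and bundled in ``model_``.

    Parameters
    ----------
    fit_intercept : bool, default True
        Kept for API completeness; the calibration equation always has an
        intercept in practice.
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y) -> "FvcCalibrator":
        X, y = check_X_y(X, y, ensure_min_samples=_MIN_FIT_ROWS)
        if X.shape[1] != 3:
            raise ValueError(
                f"expected 3 features (fvc_anterior, height, bmi), got {X.shape[1]}"
            )
        if X.shape[0] < _MIN_FIT_ROWS:
            raise CalibrationError(
                f"need at least {_MIN_FIT_ROWS} subjects, got {X.shape[0]}"
            )
        design = np.column_stack([X, np.ones(len(X))]) if self.fit_intercept else X
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise CalibrationError(
                "design matrix is rank deficient (a constant covariate?)"
            )
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        if self.fit_intercept:
            self.coef_, self.intercept_ = beta[:3], float(beta[3])
        else:
            self.coef_, self.intercept_ = beta, 0.0
        self.n_features_in_ = 3
        self.model_ = CalibrationModel(
            a=float(self.coef_[0]), b=float(self.coef_[1]),
            c=float(self.coef_[2]), d=self.intercept_, n_fit=len(X),
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_ + self.intercept_


def fit_model(
    table: Sequence[tuple[float, float, float, float]]
) -> CalibrationModel:
    """OLS fit from rows of ``(fvc_anterior, height, bmi, fvc_spirometer)``."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("expected rows of (fvc_anterior, height, bmi, fvc_spirometer)")
    if arr.shape[0] < _MIN_FIT_ROWS:
        raise CalibrationError(f"need at least {_MIN_FIT_ROWS} rows")
    return FvcCalibrator().fit(arr[:, :3], arr[:, 3]).model_


def predict_fvc(
    model: CalibrationModel, fvc_anterior: float, height: float, bmi: float
) -> float:
    """Predicted spirometer-grade FVC (mL); warns when non-positive."""
    if not np.all(np.isfinite([fvc_anterior, height, bmi])):
        raise ValueError("inputs must be finite")
    if fvc_anterior < 0:
        raise ValueError("anterior FVC cannot be negative")
    pred = model.predict(fvc_anterior, height, bmi)
    if pred <= 0:
        warnings.warn(
            f"predicted FVC {pred:.1f} mL is non-positive; inputs are outside "
            "the calibration's physiologic range",
            stacklevel=2,
        )
    return float(pred)


def loocv_predict(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Leave-one-out predictions of FVC, FEV1 and FEV1% for every subject.

    For each held-out subject the regression is refitted on the rest; the
    held-out FVC prediction rescales that subject's anterior volume curve,
    so FEV1_pred = fev1_anterior * fvc_pred / fvc_anterior and the predicted
    FEV1% equals the anterior-thorax FEV1%.

    Returns a DataFrame with columns ``subject_id, fvc_pred, fev1_pred,
    fev1_percent_pred, fvc_spirometer, fev1_spirometer, group``.
    """
    cohort = list(cohort)
    if len(cohort) < _MIN_FIT_ROWS + 1:
        raise CalibrationError(
            f"LOOCV needs at least {_MIN_FIT_ROWS + 1} subjects, got {len(cohort)}"
        )
    for r in cohort:
        if r.fvc_anterior is None or r.fev1_anterior is None:
            raise CalibrationError(
                f"subject {r.subject_id} lacks anterior-thorax indices"
            )
    X = np.array([[r.fvc_anterior, r.height, r.bmi] for r in cohort])
    y = np.array([r.fvc_spirometer for r in cohort])

    rows = []
    for train_idx, test_idx in LeaveOneOut().split(X):
        k = int(test_idx[0])
        est = FvcCalibrator().fit(X[train_idx], y[train_idx])
        fvc_pred = float(est.predict(X[test_idx])[0])
        r = cohort[k]
        fev1_pred = r.fev1_anterior * fvc_pred / r.fvc_anterior
        rows.append({
            "subject_id": r.subject_id,
            "fvc_pred": fvc_pred,
            "fev1_pred": fev1_pred,
            "fev1_percent_pred": 100.0 * fev1_pred / fvc_pred,
            "fvc_spirometer": r.fvc_spirometer,
            "fev1_spirometer": r.fev1_spirometer,
            "group": r.group,
        })
    return pd.DataFrame(rows)
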