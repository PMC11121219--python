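"""Linear SVM calibration and breed discrimination with calibration diagnostics.

Quantification uses an epsilon-insensitive linear support vector regressor
(SVR) fitted on feature-standardised spectra; discrimination uses a linear
maximum-margin classifier (SVC).  Model quality is judged the way NIR
calibrations conventionally are: regress the predictions on the observed
values and require RMSE near 0, slope and R^2 near 1 and an intercept not
significantly different from 0.  Model selection filters candidates on the
calibration group (R^2 >= 0.95 and slope >= 0.95) and then picks the lowest
prediction-group RMSE among those with prediction R^2 above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.svm import SVC, SVR

from .spectra import ParameterError

__all__ = [
    "RegressionReport",
    "ClassificationReport",
    "ModelSelectionCriteria",
    "LinearSVRModel",
    "LinearSVCModel",
    "fit_linear_svr",
    "tune_C",
    "evaluate_regression",
    "fit_linear_svc",
    "evaluate_classification",
    "select_best_model",
]


@dataclass
class RegressionReport:
    """Calibration diagnostics in the dependent variable's units.

    ``slope``/``intercept`` (with standard deviations and two-sided p-values
    against 0) come from the OLS regression of predictions on observations;
    ``rse`` is that regression's residual standard error divided by the
    observation mean.  ``slope_vs1_p`` additionally tests slope = 1.
    """

    group: str
    rmse: float
    r2: float
    slope: float
    slope_sd: float
    slope_p: float
    intercept: float
    intercept_sd: float
    intercept_p: float
    rse: float
    slope_vs1_p: float = float("nan")
    n: int = 0
    treatment: str = ""
    best_C: float = float("nan")
    parameter: str = ""

    @property
    def intercept_label(self) -> str:
        """Rendered intercept: "ns" when not significantly different from 0."""
        if self.intercept_p > 0.05:
            return "ns"
        return f"{self.intercept:.3f} ± {self.intercept_sd:.3f}"

    def to_row(self) -> dict:
        """One report row shaped like the calibration-performance tables."""
        return {
            "Parameters": self.parameter,
            "Data Treatment": self.treatment,
            "Group": self.group,
            "Best C": self.best_C,
            "RMSE": round(self.rmse, 3),
            "R2": round(self.r2, 4),
            "Slope ± s": f"{self.slope:.3f} ± {self.slope_sd:.3f}",
            "Intercept ± s": self.intercept_label,
        }


@dataclass
class ClassificationReport:
    """Replicate-level accuracy with per-class sensitivity/specificity (%)."""

    group: str
    classes: tuple
    confusion: np.ndarray  # rows true, cols predicted
    accuracy: float
    sensitivity: dict
    specificity: dict

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    def to_row(self) -> dict:
        row = {"Group": self.group, "Accuracy (%)": round(self.accuracy, 1)}
        for c in self.classes:
            row[f"Sensitivity {c} (%)"] = round(self.sensitivity[c], 1)
            row[f"Specificity {c} (%)"] = round(self.specificity[c], 1)
        return row


@dataclass(frozen=True)
class ModelSelectionCriteria:
    r2_train_min: float = 0.95
    slope_train_min: float = 0.95
    r2_test_min: float = 0.90

    def __post_init__(self) -> None:
        for v in (self.r2_train_min, self.slope_train_min, self.r2_test_min):
            if not 0 < v <= 1:
                raise ParameterError("selection thresholds must lie in (0, 1]")


class _Standardizer:
    """Column z-scoring frozen on the fitting data (sd floor avoids 0/0)."""

    def fit(self, x: np.ndarray) -> "_Standardizer":
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean_) / self.sd_


@dataclass
class LinearSVRModel:
    """Linear epsilon-SVR wrapped with train-statistics standardisation.

    Features are z-scored and the target is standardised with calibration
    statistics before fitting, so ``epsilon`` is expressed in target-sd
    units; predictions are returned on the original scale.
    """

    C: float
    epsilon: float = 0.1
    _xs: _Standardizer = field(default_factory=_Standardizer, repr=False)
    _y_mean: float = 0.0
    _y_sd: float = 1.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearSVRModel":
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float)
        if X.shape[0] < 2:
            raise ParameterError("need at least 2 training rows")
        if self.C <= 0:
            raise ParameterError("C must be positive")
        if self.epsilon < 0:
            raise ParameterError("epsilon must be non-negative")
        self._xs.fit(X)
        self._y_mean = float(y.mean())
        sd = float(y.std())
        self._y_sd = sd if sd > 0 else 1.0
        self._svr = SVR(kernel="linear", C=self.C, epsilon=self.epsilon)
        self._svr.fit(self._xs.transform(X), (y - self._y_mean) / self._y_sd)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        z = self._svr.predict(self._xs.transform(X))
        return z * self._y_sd + self._y_mean

    @property
    def coef_(self) -> np.ndarray:
        """Affine coefficients on the original feature scale."""
        w = self._svr.coef_.ravel() / self._xs.sd_ * self._y_sd
        return w


def fit_linear_svr(X: np.ndarray, y: np.ndarray, C: float,
                   epsilon: float = 0.1) -> LinearSVRModel:
    """Fit a linear epsilon-insensitive SVR (standardised internally)."""
    return LinearSVRModel(C=C, epsilon=epsilon).fit(X, y)


def tune_C(X: np.ndarray, y: np.ndarray, C_grid, epsilon: float = 0.1) -> float:
    """Pick the grid member minimising calibration-group RMSE (ties -> smallest C)."""
    grid = sorted(float(c) for c in C_grid)
    if not grid:
        raise ParameterError("C grid must be non-empty")
    best_C, best_rmse = None, np.inf
    for C in grid:
        model = fit_linear_svr(X, y, C=C, epsilon=epsilon)
        rmse = float(np.sqrt(np.mean((y - model.predict(X)) ** 2)))
        if rmse < best_rmse - 1e-12:  # strict improvement; earlier (smaller) C wins ties
            best_C, best_rmse = C, rmse
    return best_C


def evaluate_regression(y_true: np.ndarray, y_pred: np.ndarray,
                        group: str = "train") -> RegressionReport:
    """Diagnostics from regressing predictions on observations.

    RMSE is sqrt(mean squared prediction error).  Slope, intercept, their
    standard deviations, p-values and R^2 come from the OLS fit
    ``y_pred ~ y_true``; RSE is the OLS residual standard error divided by
    the observation mean.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape:
        raise ParameterError("y_true and y_pred lengths differ")
    n = y_true.size
    if n < 3:
        raise ParameterError("need at least 3 observation pairs")
    if np.var(y_true) == 0:
        raise ParameterError("zero variance in observations: R^2 undefined")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    ols = sm.OLS(y_pred, sm.add_constant(y_true)).fit()
    intercept, slope = ols.params
    intercept_sd, slope_sd = ols.bse
    intercept_p, slope_p = ols.pvalues
    # additional test of slope against the ideal value 1
    slope_vs1_p = float(ols.t_test("x1 = 1").pvalue)
    resid_se = float(np.sqrt(ols.scale))
    mean_obs = float(y_true.mean())
    rse = resid_se / abs(mean_obs) if mean_obs != 0 else float("inf")
    return RegressionReport(
        group=group, rmse=rmse, r2=float(ols.rsquared),
        slope=float(slope), slope_sd=float(slope_sd), slope_p=float(slope_p),
        intercept=float(intercept), intercept_sd=float(intercept_sd),
        intercept_p=float(intercept_p), rse=rse, slope_vs1_p=slope_vs1_p, n=n,
    )


@dataclass
class LinearSVCModel:
    """Linear maximum-margin classifier over standardised features."""

    C: float = 1.0
    _xs: _Standardizer = field(default_factory=_Standardizer, repr=False)

    def fit(self, X: np.ndarray, labels: np.ndarray) -> "LinearSVCModel":
        X = np.atleast_2d(np.asarray(X, float))
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if classes.size != 2:
            raise ParameterError(f"exactly 2 classes required, got {classes.size}")
        self._xs.fit(X)
        self._svc = SVC(kernel="linear", C=self.C, coef0=0.0)
        self._svc.fit(self._xs.transform(X), labels)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self._svc.predict(self._xs.transform(X))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self._svc.decision_function(self._xs.transform(X))


def fit_linear_svc(X: np.ndarray, labels: np.ndarray, C: float = 1.0) -> LinearSVCModel:
    """Fit a two-class linear SVC (cost C, coef0 fixed at 0)."""
    return LinearSVCModel(C=C).fit(X, labels)


def evaluate_classification(labels_true, labels_pred,
                            group: str = "train") -> ClassificationReport:
    """Accuracy (%) plus per-class sensitivity/specificity from the confusion table."""
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    if t.shape != p.shape:
        raise ParameterError("label vectors have different lengths")
    classes = tuple(np.unique(np.concatenate([t, p])))
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=int)
    for ti, pi in zip(t, p):
        confusion[index[ti], index[pi]] += 1
    total = confusion.sum()
    accuracy = 100.0 * np.trace(confusion) / total
    sensitivity, specificity = {}, {}
    for c in classes:
        i = index[c]
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = total - tp - fn - fp
        sensitivity[c] = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        specificity[c] = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return ClassificationReport(
        group=group, classes=classes, confusion=confusion,
        accuracy=float(accuracy), sensitivity=sensitivity, specificity=specificity,
    )


def select_best_model(reports: list[tuple[RegressionReport, RegressionReport]],
                      criteria: ModelSelectionCriteria = ModelSelectionCriteria(),
                      ) -> tuple[RegressionReport, RegressionReport] | None:
    """Choose the best (train, test) report pair for one dependent variable.

    Candidates must meet the calibration thresholds (R^2 and slope); among
    those, the pair with R^2_test above threshold and the lowest test RMSE
    wins, ties resolved by higher test R^2.  Returns ``None`` when no
    candidate qualifies.
    """
    if not reports:
        raise ParameterError("no candidate reports")
    eligible = [
        (tr, te) for tr, te in reports
        if tr.r2 >= criteria.r2_train_min and tr.slope >= criteria.slope_train_min
        and te.r2 >= criteria.r2_test_min
    ]
    if not eligible:
        return None
    return min(eligible, key=lambda pair: (pair[1].rmse, -pair[1].r2))
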