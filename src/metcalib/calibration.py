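"""MET calibration equations and the two-regression prediction engine.

The calibration maps per-epoch filtered synthetic acceleration (mG) to
physical-activity intensity in METs, with separate equations for ambulatory
and non-ambulatory epochs (the "two-regression" scheme). Non-ambulatory
equations may pin the intercept at 0.9 METs — the assumed intensity of
motionless wakefulness — which turns the fit into least squares of
``y - 0.9`` through the origin; a quadratic term in filtered acceleration is
supported for the non-ambulatory branch, where the intensity/acceleration
relationship is non-linear.

The model-fitting surface follows the statsmodels idiom: build a
:class:`METRegression` from data (optionally via :meth:`~METRegression.from_dataframe`),
call :meth:`~METRegression.fit`, and read estimates, standard errors, SEE and
R-squared off the returned :class:`METRegressionResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ActivityClass, CutoffSpec, classify_epoch
from .signal import EpochFeatures

__all__ = [
    "CalibrationEquation",
    "SubjectCovariates",
    "METRegression",
    "METRegressionResults",
    "TwoRegressionPrediction",
    "fit_ols",
    "fit_fixed_intercept",
    "goodness_of_fit",
    "predict_met",
    "two_regression_predict",
]

#: Assumed MET value of motionless wakefulness; the pinned intercept.
FIXED_INTERCEPT_MET = 0.9

#: Ambulatory activities excluded from equation development: their METs sit
#: far off the ambulatory regression line.
DEFAULT_EXCLUDED_LABELS = ("ascending stairs", "descending stairs")

_FORMS = (
    "linear",
    "linear_covariate",
    "linear_fixed_intercept",
    "linear_fixed_intercept_covariate",
    "quadratic_fixed_intercept",
)
_FIXED_FORMS = {
    "linear_fixed_intercept",
    "linear_fixed_intercept_covariate",
    "quadratic_fixed_intercept",
}
_COVARIATE_FORMS = {"linear_covariate", "linear_fixed_intercept_covariate"}


@dataclass(frozen=True)
class SubjectCovariates:
    """Subject-level covariates entering some equations.

    ``sex`` is a 0/1 indicator; the published equations do not state the
    mapping, so it is configurable — the shipped fixtures code 1 = boy.
    """

    sex: Optional[int] = None
    age: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in (0, 1):
            raise ValueError(f"sex must be coded 0 or 1, got {self.sex}")
        if self.age is not None and self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")

    def get(self, name: str) -> float:
        value = getattr(self, name, None)
        if value is None:
            raise ValueError(f"equation requires covariate '{name}' but it was not provided")
        return float(value)


@dataclass(frozen=True)
class CalibrationEquation:
    """One parametric MET equation.

    ``predict`` evaluates
    ``intercept + slope_counts*x + quad_counts*x**2 + covariate_coeff*cov``
    with x the filtered synthetic acceleration in mG. The raw polynomial is
    returned even past a quadratic's vertex or below zero — no silent
    clamping.
    """

    form: str
    intercept: float
    slope_counts: float
    quad_counts: float = 0.0
    covariate_name: Optional[str] = None
    covariate_coeff: float = 0.0
    target_class: ActivityClass = ActivityClass.NON_AMBULATORY
    population_tag: str = ""

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown equation form {self.form!r}; expected one of {_FORMS}")
        if self.form in _FIXED_FORMS and self.intercept != FIXED_INTERCEPT_MET:
            raise ValueError(
                f"fixed-intercept forms must have intercept {FIXED_INTERCEPT_MET}, "
                f"got {self.intercept}"
            )
        if self.quad_counts != 0.0 and self.form != "quadratic_fixed_intercept":
            raise ValueError("quadratic coefficient is only allowed in the quadratic form")
        if (self.covariate_name is not None) != (self.form in _COVARIATE_FORMS):
            raise ValueError(f"covariate_name must be set iff the form uses one ({self.form})")
        if self.target_class not in (ActivityClass.AMBULATORY, ActivityClass.NON_AMBULATORY):
            raise ValueError("target_class must be ambulatory or non_ambulatory")

    @property
    def requires_covariates(self) -> bool:
        return self.covariate_name is not None

    def predict(
        self,
        filtered_mg: float | np.ndarray,
        covariates: Optional[SubjectCovariates] = None,
    ) -> float | np.ndarray:
        x = np.asarray(filtered_mg, dtype=float)
        if np.any(x < 0):
            raise ValueError("filtered synthetic acceleration must be non-negative")
        y = self.intercept + self.slope_counts * x + self.quad_counts * x**2
        if self.requires_covariates:
            if covariates is None:
                raise ValueError(
                    f"equation requires covariate '{self.covariate_name}' "
                    "but no covariates were provided"
                )
            y = y + self.covariate_coeff * covariates.get(self.covariate_name)
        return float(y) if np.isscalar(filtered_mg) else y

    def to_dict(self) -> dict:
        d = {"form": self.form, "intercept": self.intercept, "slope": self.slope_counts}
        if self.form == "quadratic_fixed_intercept":
            d["quad"] = self.quad_counts
        if self.requires_covariates:
            d["covariate"] = self.covariate_name
            d["covariate_coeff"] = self.covariate_coeff
        return d

    @classmethod
    def from_dict(
        cls, d: dict, target_class: ActivityClass, population_tag: str = ""
    ) -> "CalibrationEquation":
        return cls(
            form=d["form"],
            intercept=float(d.get("intercept", FIXED_INTERCEPT_MET)),
            slope_counts=float(d["slope"]),
            quad_counts=float(d.get("quad", 0.0)),
            covariate_name=d.get("covariate"),
            covariate_coeff=float(d.get("covariate_coeff", 0.0)),
            target_class=target_class,
            population_tag=population_tag,
        )


def _design_matrix(
    form: str, x: np.ndarray, covariate: Optional[np.ndarray]
) -> tuple[np.ndarray, list[str], bool]:
    """Return (design, column names, has_free_intercept) for one form."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    free_intercept = form in ("linear", "linear_covariate")
    if free_intercept:
        cols.append(np.ones_like(x))
        names.append("intercept")
    cols.append(x)
    names.append("filtered_mg")
    if form == "quadratic_fixed_intercept":
        cols.append(x**2)
        names.append("filtered_mg_sq")
    if form in _COVARIATE_FORMS:
        if covariate is None:
            raise ValueError(f"form {form!r} requires a covariate column")
        cols.append(covariate)
        names.append("covariate")
    return np.column_stack(cols), names, free_intercept


class METRegression:
    """Least-squares MET calibration model.

    Parameters
    ----------
    met : array-like
        Measured MET values (dependent variable).
    filtered_mg : array-like
        Filtered synthetic acceleration, mG.
    form : str
        One of ``linear``, ``linear_covariate``, ``linear_fixed_intercept``,
        ``linear_fixed_intercept_covariate``, ``quadratic_fixed_intercept``.
        Fixed forms pin the intercept (default 0.9 METs) and regress
        ``met - intercept`` through the origin.
    covariate : array-like, optional
        Covariate column (sex indicator or age) for the covariate forms.
    covariate_name : str, optional
        ``"sex"`` or ``"age"``; informational, stored on the fitted equation.
    fixed_intercept : float
        Pinned intercept for the fixed forms.
    labels : sequence of str, optional
        Per-observation activity labels; observations whose label is in
        ``exclude_labels`` (default: both stair activities) are dropped
        before fitting.
    target_class : ActivityClass
        Class the fitted equation will serve in the two-regression scheme.

    Examples
    --------
    >>> model = METRegression(mets, filtered, form="quadratic_fixed_intercept")
    >>> res = model.fit()
    >>> res.params, res.see, res.rsquared  # doctest: +SKIP
    """

    def __init__(
        self,
        met: Sequence[float],
        filtered_mg: Sequence[float],
        form: str = "linear",
        covariate: Optional[Sequence[float]] = None,
        covariate_name: Optional[str] = None,
        fixed_intercept: float = FIXED_INTERCEPT_MET,
        labels: Optional[Sequence[str]] = None,
        exclude_labels: Sequence[str] = DEFAULT_EXCLUDED_LABELS,
        target_class: ActivityClass = ActivityClass.NON_AMBULATORY,
        population_tag: str = "",
    ) -> None:
        if form not in _FORMS:
            raise ValueError(f"unknown form {form!r}; expected one of {_FORMS}")
        y = np.asarray(met, dtype=float)
        x = np.asarray(filtered_mg, dtype=float)
        cov = None if covariate is None else np.asarray(covariate, dtype=float)
        if len(x) != len(y) or (cov is not None and len(cov) != len(y)):
            raise ValueError("met, filtered_mg and covariate must have equal length")

        excluded: list[str] = []
        if labels is not None:
            labels = np.asarray(labels, dtype=object)
            if len(labels) != len(y):
                raise ValueError("labels must align with observations")
            drop = np.isin(labels, list(exclude_labels))
            excluded = sorted(set(labels[drop]))
            y, x = y[~drop], x[~drop]
            if cov is not None:
                cov = cov[~drop]

        self.endog = y
        self.exog_x = x
        self.exog_covariate = cov
        self.form = form
        self.covariate_name = covariate_name
        self.fixed_intercept = fixed_intercept
        self.target_class = target_class
        self.population_tag = population_tag
        self.excluded_labels = excluded

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        form: str = "linear",
        met_col: str = "measured_met",
        x_col: str = "filtered_mg",
        covariate_col: Optional[str] = None,
        label_col: Optional[str] = "activity_label",
        **kwargs,
    ) -> "METRegression":
        """Build the model from a labeled epoch table."""
        labels = None
        if label_col is not None and label_col in data.columns:
            labels = data[label_col].to_numpy()
        covariate = data[covariate_col].to_numpy() if covariate_col else None
        return cls(
            data[met_col].to_numpy(),
            data[x_col].to_numpy(),
            form=form,
            covariate=covariate,
            covariate_name=covariate_col,
            labels=labels,
            **kwargs,
        )

    def fit(self) -> "METRegressionResults":
        y, x = self.endog, self.exog_x
        X, names, free_intercept = _design_matrix(self.form, x, self.exog_covariate)
        n, p = X.shape
        if n <= p:
            raise ValueError(f"need more than {p} observations to fit {self.form}; got {n}")
        work = y if free_intercept else y - self.fixed_intercept
        beta, _, rank, _ = np.linalg.lstsq(X, work, rcond=None)
        if rank < p:
            raise np.linalg.LinAlgError(
                f"design matrix is rank deficient (rank {rank} < {p} columns); "
                "regressors are collinear or constant"
            )
        fitted = X @ beta
        resid = work - fitted
        sse = float(resid @ resid)
        see = float(np.sqrt(sse / (n - p)))
        sst_centered = float(np.sum((y - y.mean()) ** 2))
        sst_uncentered = float(work @ work)
        xtx_inv = np.linalg.inv(X.T @ X)
        bse = np.sqrt(np.diag(xtx_inv)) * see
        return METRegressionResults(
            model=self,
            params=beta,
            param_names=names,
            bse=bse,
            see=see,
            sse=sse,
            rsquared=1.0 - sse / sst_centered if sst_centered > 0 else np.nan,
            rsquared_uncentered=1.0 - sse / sst_uncentered if sst_uncentered > 0 else np.nan,
            nobs=n,
            df_resid=n - p,
        )


@dataclass
class METRegressionResults:
    """Fitted calibration equation plus fit diagnostics.

    ``see`` is the standard error of estimate sqrt(SSE / (n - p)) with p the
    number of fitted coefficients (a pinned intercept is not counted).
    ``rsquared`` uses the centered convention (1 - SSE/SST about the mean of
    the measured METs); ``rsquared_uncentered`` normalises by the raw sum of
    squares of the working response (``met - 0.9`` for fixed forms), the
    convention some packages report for through-origin fits.
    """

    model: METRegression
    params: np.ndarray
    param_names: list[str]
    bse: np.ndarray
    see: float
    sse: float
    rsquared: float
    rsquared_uncentered: float
    nobs: int
    df_resid: int

    @property
    def excluded_labels(self) -> list[str]:
        return self.model.excluded_labels

    @property
    def equation(self) -> CalibrationEquation:
        coeffs = dict(zip(self.param_names, self.params))
        free = "intercept" in coeffs
        return CalibrationEquation(
            form=self.model.form,
            intercept=float(coeffs["intercept"]) if free else self.model.fixed_intercept,
            slope_counts=float(coeffs["filtered_mg"]),
            quad_counts=float(coeffs.get("filtered_mg_sq", 0.0)),
            covariate_name=self.model.covariate_name if "covariate" in coeffs else None,
            covariate_coeff=float(coeffs.get("covariate", 0.0)),
            target_class=self.model.target_class,
            population_tag=self.model.population_tag,
        )

    def predict(self, filtered_mg, covariates: Optional[SubjectCovariates] = None):
        return self.equation.predict(filtered_mg, covariates)

    def summary(self) -> str:
        lines = [
            "MET calibration fit",
            "=" * 46,
            f"form:            {self.model.form}",
            f"observations:    {self.nobs}",
            f"excluded labels: {', '.join(self.excluded_labels) or 'none'}",
            f"SEE (METs):      {self.see:.4f}",
            f"R2 (centered):   {self.rsquared:.4f}",
            f"R2 (uncentered): {self.rsquared_uncentered:.4f}",
            "-" * 46,
            f"{'term':<18}{'coef':>14}{'std err':>14}",
        ]
        if self.model.form in _FIXED_FORMS:
            lines.append(f"{'intercept':<18}{self.model.fixed_intercept:>14.4f}{'(fixed)':>14}")
        for name, b, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"{name:<18}{b:>14.6g}{se:>14.3g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional surface


def fit_ols(x: Sequence[float], y: Sequence[float], **kwargs) -> METRegressionResults:
    """Ordinary least squares METs ~ filtered acceleration with free intercept."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("regressor x is constant; slope is unidentified")
    return METRegression(y, x, form="linear", **kwargs).fit()


def fit_fixed_intercept(
    design: Sequence[Sequence[float]] | np.ndarray,
    y: Sequence[float],
    intercept: float = FIXED_INTERCEPT_MET,
    covariate_name: Optional[str] = None,
    **kwargs,
) -> METRegressionResults:
    """Least squares of ``y - intercept`` through the origin.

    ``design`` holds one tuple per observation: ``(filtered_mg,)``,
    ``(filtered_mg, filtered_mg**2)`` for the quadratic form, or
    ``(filtered_mg, covariate)`` when ``covariate_name`` is given.
    """
    D = np.atleast_2d(np.asarray(design, dtype=float))
    if D.shape[1] == 1:
        form, cov = "linear_fixed_intercept", None
    elif D.shape[1] == 2 and covariate_name is None:
        if not np.allclose(D[:, 1], D[:, 0] ** 2):
            raise ValueError(
                "two-column design without covariate_name must be (x, x**2); "
                "pass covariate_name for a covariate model"
            )
        form, cov = "quadratic_fixed_intercept", None
    elif D.shape[1] == 2:
        form, cov = "linear_fixed_intercept_covariate", D[:, 1]
    else:
        raise ValueError(f"design must have 1 or 2 columns, got {D.shape[1]}")
    return METRegression(
        y,
        D[:, 0],
        form=form,
        covariate=cov,
        covariate_name=covariate_name,
        fixed_intercept=intercept,
        **kwargs,
    ).fit()


def goodness_of_fit(
    y_pred: Sequence[float], y_obs: Sequence[float], n_params: int
) -> dict[str, float]:
    """SEE and centered R-squared of predictions against observations."""
    yp = np.asarray(y_pred, dtype=float)
    yo = np.asarray(y_obs, dtype=float)
    if yp.shape != yo.shape:
        raise ValueError(f"length mismatch: {yp.shape} vs {yo.shape}")
    n = len(yo)
    if n <= n_params:
        raise ValueError(f"need n > n_params, got n={n}, n_params={n_params}")
    sse = float(np.sum((yo - yp) ** 2))
    sst = float(np.sum((yo - yo.mean()) ** 2))
    return {
        "see": float(np.sqrt(sse / (n - n_params))),
        "r_squared": 1.0 - sse / sst if sst > 0 else np.nan,
    }


def predict_met(
    equation: CalibrationEquation,
    filtered_mg: float | np.ndarray,
    covariates: Optional[SubjectCovariates] = None,
) -> float | np.ndarray:
    """Evaluate a calibration equation at the given filtered acceleration."""
    return equation.predict(filtered_mg, covariates)


@dataclass
class TwoRegressionPrediction:
    """Per-epoch output of the two-regression scheme."""

    mets: np.ndarray
    classes: list[ActivityClass]
    negative: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __iter__(self):
        return iter(self.mets)


def two_regression_predict(
    epochs: Iterable[EpochFeatures],
    nonamb_eq: CalibrationEquation,
    amb_eq: CalibrationEquation,
    spec: CutoffSpec = CutoffSpec(),
    covariates: Optional[SubjectCovariates] = None,
) -> TwoRegressionPrediction:
    """Classify each epoch by its ratio, then predict METs with the matched equation.

    Still epochs (ratio unset) use the non-ambulatory equation — at a near-zero
    filtered acceleration a fixed-intercept equation returns ~0.9 METs. Epochs
    whose raw polynomial prediction falls below zero are flagged in
    ``negative`` (and a warning is emitted) rather than clamped.
    """
    if nonamb_eq.target_class is not ActivityClass.NON_AMBULATORY:
        raise ValueError("nonamb_eq must target the non-ambulatory class")
    if amb_eq.target_class is not ActivityClass.AMBULATORY:
        raise ValueError("amb_eq must target the ambulatory class")
    mets: list[float] = []
    classes: list[ActivityClass] = []
    for e in epochs:
        cls = classify_epoch(e, spec)
        eq = amb_eq if cls is ActivityClass.AMBULATORY else nonamb_eq
        mets.append(eq.predict(e.filtered_synthetic_mg, covariates))
        classes.append(cls)
    mets_arr = np.asarray(mets, dtype=float)
    negative = mets_arr < 0
    if negative.any():
        warnings.warn(
            f"{int(negative.sum())} epoch(s) predicted negative METs "
            "(extrapolation beyond the calibration range); values not clamped",
            RuntimeWarning,
            stacklevel=2,
        )
    return TwoRegressionPrediction(mets=mets_arr, classes=classes, negative=negative)
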