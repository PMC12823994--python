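"""Predictive models of repertoire diversity.

Two models of D are fitted and evaluated in five-fold cross-validation:

* a gradient-boosted decision-tree regressor (XGBoost at library defaults,
  squared-error loss) used to rank feature importance; and
* the two-parameter linear model  D_hat = a*S - b*S_k  with no intercept,
  fitted on untransformed counts, with 1-sigma pairs-bootstrap standard
  errors on (a, b).

Cross-validated predictions cover every subject exactly once, each
predicted by a model that never saw it.  Residual scatter is reported both
on the raw count scale and in dex (sd of log10 D - log10 D_hat), the
latter being the headline scale for the variance decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, cross_val_predict
from xgboost import XGBRegressor

from .errors import CollinearityError, DegenerateInputError

DEFAULT_FOLDS = 5


@dataclass
class ImportanceReport:
    """Normalised feature importances from a fit on all data."""

    importances: dict[str, float]
    model: str = "xgboost"

    def __post_init__(self) -> None:
        total = sum(self.importances.values())
        if total > 0:
            self.importances = {k: v / total for k, v in self.importances.items()}

    def grouped(self, groups: dict[str, list[str]]) -> dict[str, float]:
        """Sum importances of encoded columns back onto original features."""
        return {
            name: sum(self.importances.get(c, 0.0) for c in cols)
            for name, cols in groups.items()
        }


@dataclass
class FitResult:
    """Linear-model fit: coefficients, bootstrap SEs, CV predictions, R²."""

    a: float                      # coefficient on S
    b: float                      # coefficient on S_k, stored positive
    se_a: float
    se_b: float
    cv_predictions: np.ndarray    # D_hat per subject, held-out folds only
    fold_assignments: np.ndarray
    r2_cv: float                  # raw-scale R² of CV predictions
    r2_cv_log: float              # same on log10 scale
    residual_sd_dex: float        # sd of log10 D - log10 D_hat, full-data fit
    residual_sd_raw: float        # sd of raw residuals, full-data fit
    intercept: float = 0.0
    seed: int = 0
    n_boot: int = 0
    coefficients: dict = field(init=False)

    def __post_init__(self) -> None:
        self.coefficients = {"a": self.a, "b": self.b}

    def predict(self, S, S_k) -> np.ndarray:
        return self.a * np.asarray(S, float) - self.b * np.asarray(S_k, float) + self.intercept

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "se_a": self.se_a, "se_b": self.se_b,
            "intercept": self.intercept, "r2_cv": self.r2_cv,
            "r2_cv_log": self.r2_cv_log, "residual_sd_dex": self.residual_sd_dex,
            "residual_sd_raw": self.residual_sd_raw, "n_boot": self.n_boot,
            "seed": self.seed,
        }


def encode_features(cohort: pd.DataFrame, features: list[str]):
    """Encode a feature list into a numeric design frame.

    ``sex`` becomes an is_male indicator; ``cmv_status`` becomes
    cmv_positive and cmv_unknown indicators (unknown is its own level, not
    imputed).  Numeric columns pass through.  Returns (frame, groups) where
    groups maps each requested feature to its encoded column names.
    """
    cols = {}
    groups: dict[str, list[str]] = {}
    for feat in features:
        if feat not in cohort.columns:
            raise KeyError(f"feature {feat!r} not in cohort table")
        if feat == "sex":
            cols["is_male"] = (cohort["sex"].astype(str) == "male").astype(float)
            groups["sex"] = ["is_male"]
        elif feat == "cmv_status":
            s = cohort["cmv_status"].astype(str)
            cols["cmv_positive"] = (s == "positive").astype(float)
            groups["cmv_status"] = ["cmv_positive"]
            if (s == "unknown").any():
                cols["cmv_unknown"] = (s == "unknown").astype(float)
                groups["cmv_status"].append("cmv_unknown")
        else:
            cols[feat] = pd.to_numeric(cohort[feat])
            groups[feat] = [feat]
    return pd.DataFrame(cols), groups


def fit_gbm_cv(
    cohort: pd.DataFrame,
    features: list[str],
    target: str = "D",
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> tuple[np.ndarray, ImportanceReport]:
    """Gradient-boosted regression with out-of-fold predictions.

    Uses XGBRegressor at default hyperparameters with squared-error loss.
    Predictions come only from held-out folds over ``folds`` random splits
    covering all subjects; importances come from a fit on all data.
    """
    if len(cohort) < folds:
        raise ValueError(f"need at least {folds} subjects for {folds}-fold CV")
    X, groups = encode_features(cohort, features)
    y = pd.to_numeric(cohort[target]).to_numpy(float)
    model = XGBRegressor(objective="reg:squarederror", random_state=seed, n_jobs=1)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = cross_val_predict(model, X.to_numpy(float), y, cv=cv)
    full = XGBRegressor(objective="reg:squarederror", random_state=seed, n_jobs=1)
    full.fit(X.to_numpy(float), y)
    report = ImportanceReport(
        importances=dict(zip(X.columns, map(float, full.feature_importances_)))
    )
    report.groups = groups
    return preds, report


def _design(cohort: pd.DataFrame, s_col: str, sk_col: str, intercept: bool) -> np.ndarray:
    S = pd.to_numeric(cohort[s_col]).to_numpy(float)
    Sk = pd.to_numeric(cohort[sk_col]).to_numpy(float)
    cols = [S, Sk] + ([np.ones_like(S)] if intercept else [])
    return np.column_stack(cols)


def _check_rank(X: np.ndarray) -> None:
    # a constant regressor carries no information in this no-intercept model
    if np.any(np.ptp(X[:, :2], axis=0) == 0):
        raise CollinearityError("S or S_k is constant across subjects")
    # S_k exactly proportional to S (or any exact collinearity) is unfittable
    sv = np.linalg.svd(X / np.abs(X).max(axis=0, keepdims=True), compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise CollinearityError(
            "design matrix is rank deficient (S_k proportional to S?)"
        )


def fit_linear_model(
    cohort: pd.DataFrame,
    n_boot: int = 1000,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    s_col: str = "S",
    sk_col: str = "S_1000",
    d_col: str = "D",
    intercept: bool = False,
) -> FitResult:
    """Least-squares fit of D = a*S - b*S_k on untransformed counts.

    Coefficients come from fitting all the data; their 1-sigma standard
    errors from a nonparametric pairs bootstrap; cross-validated
    predictions and R² from ``folds``-fold CV.  No intercept by default.
    """
    for col in (s_col, sk_col, d_col):
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} not in cohort table")
    n = len(cohort)
    if n < 10:
        raise ValueError(f"need at least 10 subjects, got {n}")
    X = _design(cohort, s_col, sk_col, intercept)
    y = pd.to_numeric(cohort[d_col]).to_numpy(float)
    _check_rank(X)
    rng = np.random.default_rng(seed)

    coef = np.linalg.lstsq(X, y, rcond=None)[0]

    # pairs bootstrap through the 2x2 (or 3x3) normal equations
    boot = np.empty((n_boot, X.shape[1]))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        Xi, yi = X[idx], y[idx]
        boot[i] = np.linalg.lstsq(Xi, yi, rcond=None)[0]
    se = boot.std(axis=0, ddof=1) if n_boot > 1 else np.zeros(X.shape[1])

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty(n)
    fold_id = np.empty(n, int)
    for f, (tr, te) in enumerate(cv.split(X)):
        c = np.linalg.lstsq(X[tr], y[tr], rcond=None)[0]
        preds[te] = X[te] @ c
        fold_id[te] = f

    fitted = X @ coef
    log_obs = np.log10(np.maximum(y, 1.0))
    log_fit = np.log10(np.maximum(fitted, 1.0))
    log_pred = np.log10(np.maximum(preds, 1.0))
    return FitResult(
        a=float(coef[0]),
        b=float(-coef[1]),
        se_a=float(se[0]),
        se_b=float(se[1]),
        cv_predictions=preds,
        fold_assignments=fold_id,
        r2_cv=evaluate_r2(y, preds),
        r2_cv_log=evaluate_r2(log_obs, log_pred),
        residual_sd_dex=float(np.std(log_obs - log_fit, ddof=1)),
        residual_sd_raw=float(np.std(y - fitted, ddof=1)),
        intercept=float(coef[2]) if intercept else 0.0,
        seed=seed,
        n_boot=n_boot,
    )


def evaluate_r2(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot about the mean."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have the same length")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("R² undefined for constant observed values")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def topk_sensitivity(
    cohort: pd.DataFrame,
    ks: tuple[int, ...] = (10, 100, 1000),
    n_boot: int = 200,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> dict[int, FitResult]:
    """Re-fit the linear model using S_k for each k; compare R² across k."""
    out = {}
    for k in ks:
        col = f"S_{k}"
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} not in cohort table")
        out[k] = fit_linear_model(
            cohort, n_boot=n_boot, folds=folds, seed=seed, sk_col=col
        )
    return out
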