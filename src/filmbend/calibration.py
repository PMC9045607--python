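"""Forward and inverse linear calibration between exposure and bending.

Forward: ordinary least squares from solution composition (acetone fraction,
ethanol fraction, optionally the trial's initial angle) to the per-trial
change in tip angle.  Inverse: one OLS model per analyte from the
triple-exponential transient parameters back to the acetone and ethanol
fractions, with a feature ablation comparing the full parameter set
(a0..a3, lambda1..3) to the reduced set (a0, lambda1..3).

R-squared convention throughout: the squared Pearson correlation between
predicted and actual values.  Fits report in-sample R-squared by default —
exploratory calibration summaries, not held-out performance claims — with an
optional seeded k-fold cross-validated variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    InvalidParamsError,
    UndefinedCorrelationError,
    UnderDeterminedError,
)

__all__ = [
    "CalibrationModel",
    "HysteresisDiagnostic",
    "r_squared",
    "fit_forward_model",
    "fit_inverse_model",
    "feature_ablation",
    "hysteresis_diagnostic",
    "FULL_FEATURES",
    "REDUCED_FEATURES",
]

FULL_FEATURES = ("a0", "a1", "a2", "a3", "lambda1", "lambda2", "lambda3")
REDUCED_FEATURES = ("a0", "lambda1", "lambda2", "lambda3")


def r_squared(predicted, actual) -> float:
    """Squared Pearson correlation between predicted and actual values.

    Note this is sign-blind: a perfectly anti-correlated prediction also
    scores 1.  Raises when either series is constant (correlation undefined).
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size < 3:
        raise InvalidParamsError("need at least 3 matched pairs")
    if np.ptp(a) == 0:
        raise UndefinedCorrelationError("actual values are constant")
    if np.ptp(p) == 0:
        raise UndefinedCorrelationError("predicted values are constant")
    r = np.corrcoef(p, a)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class CalibrationModel:
    direction: str  # "forward" | "inverse"
    feature_names: tuple[str, ...]
    coefficients: dict  # target -> {"intercept": ..., feature: ...}
    r2_per_target: dict  # target -> in-sample R^2
    n_trials: int

    def predict(self, table: pd.DataFrame, target: str) -> np.ndarray:
        coefs = self.coefficients[target]
        out = np.full(len(table), coefs["intercept"], dtype=float)
        for name in self.feature_names:
            out += coefs[name] * table[name].to_numpy(dtype=float)
        return out


def _ols(table: pd.DataFrame, features, target: str, direction: str,
         cv: int | None = None, cv_seed: int = 0):
    X = table[list(features)].to_numpy(dtype=float)
    y = table[target].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        bad = [
            name
            for i, name in enumerate(features)
            if np.linalg.matrix_rank(np.delete(Xc, i + 1, axis=1)) == np.linalg.matrix_rank(Xc)
        ]
        raise CollinearityError(
            f"rank-deficient design for {direction} model; "
            f"collinear features: {bad or list(features)}"
        )
    res = sm.OLS(y, Xc).fit()
    coefs = {"intercept": float(res.params[0])}
    coefs.update({name: float(res.params[i + 1]) for i, name in enumerate(features)})
    if cv is None:
        r2 = r_squared(np.asarray(res.fittedvalues), y)
    else:
        r2 = r_squared(_kfold_predictions(Xc, y, cv, cv_seed), y)
    return coefs, r2


def _kfold_predictions(Xc: np.ndarray, y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Out-of-fold OLS predictions from a seeded k-fold split."""
    if not 2 <= k <= len(y):
        raise InvalidParamsError(f"cv folds must be in 2..{len(y)}")
    idx = np.random.default_rng(seed).permutation(len(y))
    preds = np.empty(len(y))
    for fold in np.array_split(idx, k):
        train = np.setdiff1d(idx, fold)
        params = sm.OLS(y[train], Xc[train]).fit().params
        preds[fold] = Xc[fold] @ params
    return preds


def fit_forward_model(
    trials: pd.DataFrame, include_initial_angle: bool = True
) -> CalibrationModel:
    """OLS of the per-trial tip-angle change on the acetone and ethanol
    fractions (and, by default, the trial's initial angle)."""
    if len(trials) < 5:
        raise UnderDeterminedError("need at least 5 trials for the forward model")
    features = ["f_acetone", "f_ethanol"]
    if include_initial_angle:
        features.append("initial_angle_deg")
    coefs, r2 = _ols(trials, features, "delta_theta_deg", "forward")
    return CalibrationModel(
        direction="forward",
        feature_names=tuple(features),
        coefficients={"delta_theta_deg": coefs},
        r2_per_target={"delta_theta_deg": r2},
        n_trials=len(trials),
    )


def fit_inverse_model(
    table: pd.DataFrame, feature_subset: str | tuple = "full",
    cv: int | None = None, cv_seed: int = 0,
) -> CalibrationModel:
    """Per-analyte OLS from transient-fit parameters to solution fractions.

    ``table`` needs the transient parameters, a boolean ``converged`` column
    and the ``f_acetone``/``f_ethanol`` targets; unconverged fits are dropped.
    ``feature_subset`` is "full" (a0..a3, lambda1..3), "reduced"
    (a0, lambda1..3) or an explicit tuple of column names.  By default R^2 is
    in-sample; pass ``cv`` (number of seeded folds) to report R^2 on
    out-of-fold predictions instead — the sharper instrument when *comparing*
    predictive power between analytes.
    """
    if isinstance(feature_subset, str):
        try:
            features = {"full": FULL_FEATURES, "reduced": REDUCED_FEATURES}[feature_subset]
        except KeyError:
            raise InvalidParamsError(f"unknown feature subset {feature_subset!r}") from None
    else:
        features = tuple(feature_subset)
    used = table[table["converged"]] if "converged" in table else table
    if len(used) < max(8, len(features) + 2):
        raise UnderDeterminedError(
            f"{len(used)} converged fits for {len(features)} features; "
            f"need at least {max(8, len(features) + 2)}"
        )
    coefficients, r2s = {}, {}
    for target in ("f_acetone", "f_ethanol"):
        coefs, r2 = _ols(used, features, target, "inverse", cv=cv, cv_seed=cv_seed)
        coefficients[target] = coefs
        r2s[target] = r2
    return CalibrationModel(
        direction="inverse",
        feature_names=features,
        coefficients=coefficients,
        r2_per_target=r2s,
        n_trials=len(used),
    )


def feature_ablation(table: pd.DataFrame) -> dict:
    """Fit the full and reduced inverse models and report the per-analyte
    R-squared drop when the exponential amplitudes a1..a3 are omitted."""
    full = fit_inverse_model(table, "full")
    reduced = fit_inverse_model(table, "reduced")
    delta = {
        tgt: full.r2_per_target[tgt] - reduced.r2_per_target[tgt]
        for tgt in full.r2_per_target
    }
    return {"full": full, "reduced": reduced, "delta_r2": delta}


@dataclass(frozen=True)
class HysteresisDiagnostic:
    """Drift of per-trial initial angles: the fingerprint of slow,
    history-dependent film state."""

    initial_angles_deg: np.ndarray
    drift_slope_deg_per_trial: float
    lag1_autocorrelation: float  # NaN when undefined
    autocorrelation_defined: bool


def hysteresis_diagnostic(initial_angles) -> HysteresisDiagnostic:
    """Linear drift slope and lag-1 autocorrelation of the per-trial initial
    angles, taken in temporal order (at least 10 trials)."""
    x = np.asarray(initial_angles, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise InvalidParamsError("need at least 10 trials in temporal order")
    idx = np.arange(x.size, dtype=float)
    slope = float(np.polyfit(idx, x, 1)[0]) if np.ptp(x) > 0 else 0.0
    a, b = x[:-1], x[1:]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        lag1, defined = float("nan"), False
    else:
        lag1, defined = float(np.corrcoef(a, b)[0, 1]), True
    return HysteresisDiagnostic(
        initial_angles_deg=x,
        drift_slope_deg_per_trial=slope,
        lag1_autocorrelation=lag1,
        autocorrelation_defined=defined,
    )
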