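"""PLS1 regression and validation statistics for NIR calibration.

The calibration model is univariate partial least squares (PLS1) fitted
with NIPALS on mean-centered data.  With ``X_c`` the centered spectra
matrix and ``y_c`` the centered concentrations, each component extracts

    w = X_c' y_c / ||X_c' y_c||      (weight: covariance direction)
    t = X_c w                        (score)
    p = X_c' t / (t' t)              (X loading)
    q = y_c' t / (t' t)              (y loading)

after which X is deflated by ``t p'`` and y residualized by ``q t``.  The
compact regression vector is assembled as ``b = W (P' W)^{-1} q`` with
intercept ``y_mean - x_mean' b``; both prediction routes (sequential
scores and the coefficient vector) are cross-checked at fit time.

An independent SIMPLS implementation is provided purely as a second
route to the same predictions (the two algorithms agree for PLS1); it is
used by the tests, never by the pipeline.

Validation follows the study protocol: leave-one-out cross-validation
grouped at the sample level, so all temperature replicates of a sample
are held out together; RMSEP = sqrt(mean (yhat - y)^2) in g/L and
R^2 = 1 - SS_res/SS_tot over the held-out predictions, in percent.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLSModel",
    "CVResult",
    "MethodComparison",
    "CalibrationCurve",
    "ChemometricsError",
    "fit_pls",
    "simpls_coefficients",
    "predict",
    "loo_cv",
    "rmsep",
    "r2_percent",
    "rmsep_percent_of_range",
    "rmsecv_by_components",
    "compare_methods",
    "loq_ich",
    "save_model",
    "load_model",
]

MODEL_FORMAT = "mustspec-pls-1"


class ChemometricsError(ValueError):
    """Invalid input to a chemometric operation."""


@dataclass
class PLSModel:
    """Fitted PLS1 artifacts for one analyte."""

    analyte: str
    n_components: int
    x_mean: np.ndarray       # (p,)
    y_mean: float
    weights: np.ndarray      # W, (p, a)
    x_loadings: np.ndarray   # P, (p, a)
    y_loadings: np.ndarray   # q, (a,)
    coef: np.ndarray         # b, (p,)
    intercept: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return int(self.coef.size)


@dataclass
class CVResult:
    """Grouped leave-one-out cross-validation output for one model."""

    predictions: np.ndarray       # per spectrum, each predicted exactly once
    truths: np.ndarray
    groups: np.ndarray            # sample id per spectrum
    rmsep: float
    r2_percent: float             # 1 - SSres/SStot, percent (Q2-style)
    pearson_r2_percent: float     # squared Pearson correlation, logged not headline
    n_samples: int
    n_spectra: int

    def per_sample(self) -> pd.DataFrame:
        """Aggregate held-out predictions per sample (mean over replicates)."""
        df = pd.DataFrame(
            {"sample_id": self.groups, "y_true": self.truths, "y_pred": self.predictions}
        )
        agg = df.groupby("sample_id", sort=True).agg(
            y_true=("y_true", "first"), y_pred_mean=("y_pred", "mean")
        )
        return agg.reset_index()


@dataclass
class MethodComparison:
    """OLS agreement between two reference methods for one analyte."""

    analyte: str
    values_a: np.ndarray
    values_b: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    n: int


@dataclass
class CalibrationCurve:
    """Linear calibration line with its residual-sd based LOQ."""

    analyte: str
    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    residual_sd: float
    loq: float


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ChemometricsError(f"X must be 2-D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ChemometricsError("non-finite values in X")
    return X


def fit_pls(
    X,
    y,
    n_components: int = 6,
    *,
    analyte: str = "",
    metadata: Mapping | None = None,
) -> PLSModel:
    """Fit PLS1 by NIPALS with X-deflation and y-residualization.

    ``n_components`` defaults to the 6 latent variables the calibration
    protocol fixed; it must not exceed min(n_rows - 1, n_features).
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ChemometricsError(f"X has {n} rows but y has {y.size} entries")
    if not np.all(np.isfinite(y)):
        raise ChemometricsError("non-finite values in y")
    if np.ptp(y) == 0:
        raise ChemometricsError("y has zero variance; nothing to calibrate")
    a_max = min(n - 1, p)
    if not 1 <= n_components <= a_max:
        raise ChemometricsError(
            f"n_components={n_components} outside [1, {a_max}] for X of shape {X.shape}"
        )

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))

    cov_scale = float(np.linalg.norm(Xd.T @ yd))
    for a in range(n_components):
        w = Xd.T @ yd
        nw = float(np.linalg.norm(w))
        if nw <= 1e-14 * max(cov_scale, 1e-300):
            raise ChemometricsError(
                f"covariance exhausted after {a} components; "
                f"reduce n_components below {n_components}"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            raise ChemometricsError(f"degenerate score at component {a + 1}")
        pk = Xd.T @ t / tt
        qk = float(yd @ t / tt)
        Xd = Xd - np.outer(t, pk)
        yd = yd - qk * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pk, qk, t

    # compact coefficients: b = W (P'W)^-1 q
    b = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ b)

    # internal consistency: sequential-score and coefficient predictions
    yhat_seq = y_mean + T @ q
    yhat_coef = X @ b + intercept
    tol = 1e-8 * max(1.0, float(np.max(np.abs(y))))
    worst = float(np.max(np.abs(yhat_seq - yhat_coef)))
    if worst > tol:
        raise ChemometricsError(
            f"NIPALS prediction routes disagree by {worst:.3e} (> {tol:.1e}); "
            "the problem is numerically degenerate at this component count"
        )

    return PLSModel(
        analyte=analyte,
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=b,
        intercept=intercept,
        metadata=dict(metadata or {}),
    )


def simpls_coefficients(X, y, n_components: int) -> tuple[np.ndarray, float]:
    """SIMPLS (de Jong) coefficients for PLS1: an independent route.

    Works on the covariance vector directly, deflating it against an
    orthonormal loading basis instead of deflating X.  For a univariate
    response its predictions coincide with NIPALS PLS1.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    s = Xc.T @ yc
    V = np.zeros((p, n_components))
    R = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        r = s.copy()
        t = Xc @ r
        norm_t = float(np.linalg.norm(t))
        if norm_t <= 0:
            raise ChemometricsError(f"SIMPLS degenerate at component {a + 1}")
        t /= norm_t
        r /= norm_t
        pk = Xc.T @ t
        q[a] = float(yc @ t)
        v = pk.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pk)
        v /= float(np.linalg.norm(v))
        s = s - v * float(v @ s)
        V[:, a], R[:, a] = v, r

    b = R @ q
    intercept = y_mean - float(x_mean @ b)
    return b, intercept


def predict(model: PLSModel, X) -> np.ndarray:
    """Predict concentrations (g/L); negative predictions are reported as-is."""
    X = _as_matrix(X)
    if X.shape[1] != model.n_features:
        raise ChemometricsError(
            f"X has {X.shape[1]} features, model expects {model.n_features}"
        )
    return X @ model.coef + model.intercept


def rmsep(predictions, truths) -> float:
    """Root mean square error of prediction, same units as y."""
    yhat = np.asarray(predictions, dtype=float).ravel()
    y = np.asarray(truths, dtype=float).ravel()
    if yhat.size == 0 or yhat.size != y.size:
        raise ChemometricsError("predictions and truths must be equal-length, non-empty")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def r2_percent(predictions, truths) -> float:
    """Validation R^2 = 1 - SS_res/SS_tot over held-out predictions, percent."""
    yhat = np.asarray(predictions, dtype=float).ravel()
    y = np.asarray(truths, dtype=float).ravel()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ChemometricsError("truths have zero variance; R^2 undefined")
    ss_res = float(np.sum((yhat - y) ** 2))
    return 100.0 * (1.0 - ss_res / ss_tot)


def rmsep_percent_of_range(rmsep_value: float, value_min: float, value_max: float) -> float:
    """RMSEP as percent of the analyte's value range (the span-normalized
    figure used to compare models across analytes and varieties)."""
    if not value_max > value_min:
        raise ChemometricsError(
            f"degenerate value range [{value_min}, {value_max}]"
        )
    return 100.0 * rmsep_value / (value_max - value_min)


def loo_cv(X, y, groups, n_components: int = 6, *, analyte: str = "") -> CVResult:
    """Leave-one-out cross-validation grouped by sample id.

    Each distinct group (sample) is held out in turn with all of its
    replicate spectra; the model is refitted on the remaining groups and
    the held-out spectra predicted.  Every spectrum is predicted exactly
    once by a model that never saw any spectrum of its sample.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups)
    if groups.size != y.size or y.size != X.shape[0]:
        raise ChemometricsError("X, y and groups must agree in length")
    unique = np.unique(groups)
    if unique.size < 3:
        raise ChemometricsError(f"need >= 3 distinct groups, got {unique.size}")
    predictions = np.empty_like(y)
    for g in unique:
        held = groups == g
        if held.all():
            raise ChemometricsError(f"group {g!r} contains every row")
        model = fit_pls(X[~held], y[~held], n_components, analyte=analyte)
        predictions[held] = predict(model, X[held])

    pearson = float(stats.pearsonr(predictions, y).statistic ** 2) * 100.0
    return CVResult(
        predictions=predictions,
        truths=y,
        groups=groups,
        rmsep=rmsep(predictions, y),
        r2_percent=r2_percent(predictions, y),
        pearson_r2_percent=pearson,
        n_samples=int(unique.size),
        n_spectra=int(y.size),
    )


def rmsecv_by_components(X, y, groups, max_components: int = 10) -> pd.DataFrame:
    """Diagnostic: grouped-CV RMSEP as a function of component count.

    Provided for inspection only; the pipeline keeps the component count
    fixed at its configured value rather than auto-selecting.
    """
    rows = []
    for a in range(1, max_components + 1):
        cv = loo_cv(X, y, groups, n_components=a)
        rows.append({"n_components": a, "rmsep": cv.rmsep, "r2_percent": cv.r2_percent})
    return pd.DataFrame(rows)


def compare_methods(
    table_a: pd.DataFrame, table_b: pd.DataFrame, analyte: str
) -> MethodComparison:
    """OLS regression of method B on method A for one analyte.

    Both tables follow the reference schema (``sample_id`` plus
    ``<analyte>_g_l`` columns); pairing is by sample id.  Reports slope,
    intercept, squared Pearson correlation and the RMSE of the residuals
    from the fitted line.
    """
    col = f"{analyte}_g_l"
    for name, tab in (("A", table_a), ("B", table_b)):
        if col not in tab.columns:
            raise ChemometricsError(f"method {name} table is missing column {col!r}")
        if "sample_id" not in tab.columns:
            raise ChemometricsError(f"method {name} table is missing column 'sample_id'")
    merged = table_a[["sample_id", col]].merge(
        table_b[["sample_id", col]], on="sample_id", suffixes=("_a", "_b")
    )
    if len(merged) < 3:
        raise ChemometricsError(
            f"need >= 3 paired samples for {analyte}, got {len(merged)}"
        )
    a = merged[f"{col}_a"].to_numpy(dtype=float)
    b = merged[f"{col}_b"].to_numpy(dtype=float)
    if np.ptp(a) == 0:
        raise ChemometricsError(f"method A values constant for {analyte}; fit undefined")
    fit = stats.linregress(a, b)
    residuals = b - (fit.slope * a + fit.intercept)
    return MethodComparison(
        analyte=analyte,
        values_a=a,
        values_b=b,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        rmse=float(np.sqrt(np.mean(residuals**2))),
        n=int(len(merged)),
    )


def loq_ich(concentrations, responses, *, analyte: str = "") -> CalibrationCurve:
    """Limit of quantification from a calibration line: LOQ = 10 sigma / S.

    ``sigma`` is the residual standard deviation of the ordinary
    least-squares calibration line (n - 2 denominator) and ``S`` its
    slope, following the ICH validation guideline.  Requires at least 4
    concentration levels spanning a positive range and a positive slope.
    """
    c = np.asarray(concentrations, dtype=float).ravel()
    r = np.asarray(responses, dtype=float).ravel()
    if c.size != r.size or c.size < 4:
        raise ChemometricsError("calibration needs >= 4 paired points")
    if np.unique(c).size < 4:
        raise ChemometricsError("calibration needs >= 4 distinct concentration levels")
    if np.ptp(c) <= 0 or np.min(c) < 0:
        raise ChemometricsError("concentration levels must span a positive range")
    fit = stats.linregress(c, r)
    if fit.slope <= 0:
        raise ChemometricsError(
            f"nonpositive calibration slope ({fit.slope:g}); LOQ undefined"
        )
    residuals = r - (fit.slope * c + fit.intercept)
    sigma = float(np.sqrt(np.sum(residuals**2) / (c.size - 2)))
    return CalibrationCurve(
        analyte=analyte,
        concentrations=c,
        responses=r,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_sd=sigma,
        loq=10.0 * sigma / float(fit.slope),
    )


# -- model persistence ------------------------------------------------------

def save_model(model: PLSModel, path: str | Path) -> None:
    """Persist a model as versioned JSON; reload reproduces predictions
    bit-for-bit (floats survive the JSON round trip exactly)."""
    doc = {
        "format": MODEL_FORMAT,
        "analyte": model.analyte,
        "n_components": model.n_components,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coef": model.coef.tolist(),
        "intercept": model.intercept,
        "metadata": model.metadata,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True)


def load_model(path: str | Path) -> PLSModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != MODEL_FORMAT:
        raise ChemometricsError(
            f"unsupported model format {doc.get('format')!r}; expected {MODEL_FORMAT}"
        )
    return PLSModel(
        analyte=doc["analyte"],
        n_components=int(doc["n_components"]),
        x_mean=np.array(doc["x_mean"], dtype=float),
        y_mean=float(doc["y_mean"]),
        weights=np.array(doc["weights"], dtype=float),
        x_loadings=np.array(doc["x_loadings"], dtype=float),
        y_loadings=np.array(doc["y_loadings"], dtype=float),
        coef=np.array(doc["coef"], dtype=float),
        intercept=float(doc["intercept"]),
        metadata=doc.get("metadata", {}),
    )
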