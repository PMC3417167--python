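"""Mass-univariate first-level GLM with AR(1) prewhitening.

A single pooled AR(1) coefficient per subject is estimated from OLS residuals
over in-mask voxels; data and design are then exactly whitened (including the
sqrt(1 - rho^2) scaling of the first sample) and fitted voxelwise by ordinary
least squares. Prewhitened OLS is algebraically identical to generalized least
squares under the AR(1) covariance, which the tests verify against a dense GLS
oracle.

Two first-level strategies are supported: ``per_feature`` (each of the 14
regressors fitted in its own GLM together with the drift basis and intercept,
as in the beta-weight summaries) and ``combined`` (all 14 at once). The
per-feature path uses Frisch–Waugh–Lovell residualization so the nuisance
projection of the data is shared across the 14 fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import toeplitz

from .design import DesignMatrix
from .errors import (AlignmentError, CollinearityError, CompletenessError,
                     DegenerateDataError, ValidationError)


@dataclass
class StatMap:
    """A 3-D statistical image. Values are defined only within the mask;
    voxels outside are NaN (0 for integer-valued overlap/significance maps)."""

    kind: str                 # beta | t | p | significance | overlap
    values: np.ndarray        # 3-D
    feature: str              # feature name or contrast label
    level: str                # first | second
    affine: np.ndarray
    mask: np.ndarray
    df: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValidationError("values and mask shapes differ")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")

    def in_mask(self) -> np.ndarray:
        """Flat vector of in-mask values."""
        return self.values[self.mask]


@dataclass
class Ar1Model:
    rho: float
    estimation_scope: str = "global-in-mask"

    def __post_init__(self):
        if not abs(self.rho) < 1:
            raise ValidationError("|rho| must be < 1")


# ---------------------------------------------------------------------------
# AR(1) machinery

def ar1_whiten(arr: np.ndarray, rho: float) -> np.ndarray:
    """Exact AR(1) whitening along axis 0: the first sample is scaled by
    sqrt(1 - rho^2), subsequent samples become x_t - rho * x_{t-1}."""
    arr = np.asarray(arr, dtype=float)
    out = np.empty_like(arr)
    out[0] = np.sqrt(1.0 - rho ** 2) * arr[0]
    out[1:] = arr[1:] - rho * arr[:-1]
    return out


def ols_residuals(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of column-wise OLS of Y (T x V) on X (T x k)."""
    Q, _ = np.linalg.qr(X)
    return Y - Q @ (Q.T @ Y)


def estimate_ar1(residuals: np.ndarray,
                 design: np.ndarray | None = None) -> Ar1Model:
    """Pooled lag-1 autocorrelation of residuals (voxels x time).

    Projecting out k design columns (drift columns in particular, which carry
    exactly the high-autocorrelation content) biases the raw residual lag-1
    autocorrelation downward. When ``design`` is given, the raw estimate is
    inverted through the analytically expected residual autocorrelation
    E[r1 | rho] for that residual-forming matrix, removing the bias.
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim == 1:
        r = r[None, :]
    if r.shape[1] < 3:
        raise ValidationError("need at least 3 time points")
    r = r - r.mean(axis=1, keepdims=True)
    denom = float(np.sum(r * r))
    if denom == 0:
        raise DegenerateDataError("residuals have zero variance")
    num = float(np.sum(r[:, 1:] * r[:, :-1]))
    raw = num / denom
    if design is None:
        return Ar1Model(rho=raw)
    grid = np.linspace(-0.2, 0.95, 24)
    curve = expected_residual_lag1(design, grid)
    rho = float(np.interp(raw, curve, grid))
    return Ar1Model(rho=min(max(rho, -0.999), 0.999))


def expected_residual_lag1(design: np.ndarray, rho_grid: np.ndarray,
                           ) -> np.ndarray:
    """E[pooled lag-1 autocorrelation of OLS residuals] under AR(1) noise.

    With M = I - QQ' the residual-forming matrix, the pooled statistic
    concentrates on tr(S M Sigma M) / tr(M Sigma M) where S averages the two
    first off-diagonals and Sigma_ij = rho^|i-j|; both traces reduce to
    O(T k^2) inner products with the thin Q factor.
    """
    X = np.asarray(design, dtype=float)
    T = X.shape[0]
    Q, _ = np.linalg.qr(X)
    out = np.empty(len(rho_grid))
    lags = np.arange(T)
    for gi, rho in enumerate(np.asarray(rho_grid, dtype=float)):
        col = rho ** lags
        Sigma = toeplitz(col)
        B = Sigma @ Q                         # (T, k)
        C = Q.T @ B                           # (k, k)
        tr_MSM = T - np.trace(C)
        d1_Sigma = float(np.sum(col[1]) * (T - 1)) if T > 1 else 0.0
        d1_QBt = float(np.sum(Q[:-1] * B[1:]) + np.sum(Q[1:] * B[:-1])) / 2.0
        QC = Q @ C
        d1_QCQt = float(np.sum(QC[:-1] * Q[1:]) + np.sum(QC[1:] * Q[:-1])) / 2.0
        num = d1_Sigma - 2.0 * d1_QBt + d1_QCQt
        out[gi] = num / tr_MSM
    return out


# ---------------------------------------------------------------------------
# Generic fit

def glm_stats(Y: np.ndarray, X: np.ndarray, rho: float) -> dict:
    """Prewhitened voxelwise OLS on flat data: ``Y`` (T x V), ``X`` (T x k).

    Returns beta/se/t/p of shape (k, V) plus df = T - rank(X).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    T = X.shape[0]
    if Y.shape[0] != T:
        raise AlignmentError(
            f"data has {Y.shape[0]} volumes but design has {T} rows")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    Xw = ar1_whiten(X, rho)
    Yw = ar1_whiten(Y, rho)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    beta = XtX_inv @ (Xw.T @ Yw)             # (k, V)
    resid = Yw - Xw @ beta
    df = T - rank
    sigma2 = np.sum(resid * resid, axis=0) / df
    se = np.sqrt(sigma2[None, :] * np.diag(XtX_inv)[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return {"beta": beta, "se": se, "t": t, "p": p, "df": df}


def fit_glm(series, X: DesignMatrix, ar1: Ar1Model,
            columns: list[str] | None = None) -> dict[str, dict[str, StatMap]]:
    """Prewhitened voxelwise OLS on a VolumeSeries.

    Returns ``{column: {"beta": map, "t": map, "p": map}}`` for each column of
    interest (by default the feature regressors); t = beta/se with
    df = T - rank(X), two-sided p.
    """
    if columns is None:
        columns = list(X.feature_names)
    Y = series.data[series.mask].T.astype(float)
    res = glm_stats(Y, X.matrix.to_numpy(dtype=float), ar1.rho)
    col_index = {c: i for i, c in enumerate(X.matrix.columns)}
    out: dict[str, dict[str, StatMap]] = {}
    for col in columns:
        j = col_index[col]
        out[col] = {
            "beta": _to_map("beta", res["beta"][j], col, series, res["df"]),
            "t": _to_map("t", res["t"][j], col, series, res["df"]),
            "p": _to_map("p", res["p"][j], col, series, res["df"]),
        }
    return out


def fit_per_feature(series, X: DesignMatrix, ar1: Ar1Model,
                    ) -> dict[str, dict[str, StatMap]]:
    """Fit one GLM per feature (feature + drift + intercept), sharing the
    whitened nuisance projection across features (Frisch–Waugh–Lovell)."""
    data = series.data
    mask = series.mask
    T = X.n_volumes
    if data.shape[-1] != T:
        raise AlignmentError("time dimension mismatch")
    Y = data[mask].T.astype(float)
    res = per_feature_stats(
        Y, X.features().to_numpy(dtype=float),
        X.nuisance().to_numpy(dtype=float), ar1.rho)
    out: dict[str, dict[str, StatMap]] = {}
    for i, feat in enumerate(X.feature_names):
        out[feat] = {
            "beta": _to_map("beta", res["beta"][i], feat, series, res["df"]),
            "t": _to_map("t", res["t"][i], feat, series, res["df"]),
            "p": _to_map("p", res["p"][i], feat, series, res["df"]),
        }
    return out


def per_feature_stats(Y: np.ndarray, F: np.ndarray, N: np.ndarray,
                      rho: float, compute_tp: bool = True) -> dict:
    """Vectorized per-feature GLM statistics on flat data.

    Parameters: ``Y`` (T x V) data, ``F`` (T x n_features) feature regressors,
    ``N`` (T x k) nuisance (drift + intercept), pooled AR(1) ``rho``. Each
    feature's model is [feature, nuisance]; returns beta/se/t/p arrays of
    shape (n_features, V) plus df.
    """
    return per_feature_stats_whitened(ar1_whiten(Y, rho),
                                      ar1_whiten(F, rho),
                                      ar1_whiten(N, rho),
                                      compute_tp=compute_tp)


def per_feature_stats_whitened(Yw: np.ndarray, Fw: np.ndarray,
                               Nw: np.ndarray,
                               compute_tp: bool = True) -> dict:
    """Per-feature GLM on already-whitened flat data (Frisch–Waugh–Lovell:
    the nuisance projection of the data is computed once and shared across
    the per-feature models)."""
    T = Yw.shape[0]
    Q, _ = np.linalg.qr(Nw)
    Yr = Yw - Q @ (Q.T @ Yw)
    Fr = Fw - Q @ (Q.T @ Fw)
    norms2 = np.sum(Fr * Fr, axis=0)
    if np.any(norms2 <= 0):
        raise CollinearityError("a feature regressor lies in the nuisance span")
    df = T - (Nw.shape[1] + 1)
    beta = (Fr.T @ Yr) / norms2[:, None]               # (F, V)
    out = {"beta": beta, "df": df}
    if compute_tp:
        yss = np.sum(Yr * Yr, axis=0)                  # (V,)
        rss = np.maximum(yss[None, :] - beta ** 2 * norms2[:, None], 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / norms2[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
        out.update(se=se, t=t, p=2.0 * stats.t.sf(np.abs(t), df))
    return out


# ---------------------------------------------------------------------------
# Contrasts

def social_vs_nonsocial_contrast(betas: dict[str, StatMap],
                                 social_set: tuple[str, ...],
                                 nonsocial_set: tuple[str, ...]) -> StatMap:
    """Voxelwise mean(social betas) - mean(non-social betas) for one subject."""
    missing = [f for f in (*social_set, *nonsocial_set) if f not in betas]
    if missing:
        raise CompletenessError(f"missing feature betas: {missing}")
    ref = betas[social_set[0]]
    soc = np.mean([betas[f].values for f in social_set], axis=0)
    non = np.mean([betas[f].values for f in nonsocial_set], axis=0)
    values = np.where(ref.mask, soc - non, np.nan)
    return StatMap(kind="beta", values=values, feature="social_vs_nonsocial",
                   level="first", affine=ref.affine, mask=ref.mask)


def _to_map(kind: str, flat: np.ndarray, feature: str, series,
            df: float | None) -> StatMap:
    vol = np.full(series.mask.shape, np.nan)
    vol[series.mask] = flat
    return StatMap(kind=kind, values=vol, feature=feature, level="first",
                   affine=series.affine, mask=series.mask, df=df)
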