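"""First-level design matrices.

A design holds the 14 feature regressors (optionally mutually orthogonalized,
optionally convolved with the canonical double-gamma HRF), a discrete-cosine
high-pass drift basis (cutoff 128 s by default) and an intercept.

Orthogonalization is *simultaneous*: each feature is residualized against the
13 other ORIGINAL regressors (plus intercept) so that, unlike sequential
Gram-Schmidt, the result does not depend on feature order. The ledger records,
per feature, the least-squares weights on the other features and the R^2 of
that fit; positive weights are subtracted from (negative weights added to) the
original time course to form the residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .errors import (AlignmentError, CollinearityError, DegenerateDataError,
                     ValidationError)
from .ratings import FeatureTimecourse

#: relative tolerance for orthogonality assertions
ORTHO_TOL = 1e-8


@dataclass
class DesignMatrix:
    """Named design columns plus the orthogonalization ledger.

    ``matrix`` columns are ordered: feature regressors, then drift columns
    (``drift_1`` ...), then ``intercept``.
    """

    matrix: pd.DataFrame
    tr_s: float
    feature_names: list[str]
    ortho_ledger: dict[str, dict] = field(default_factory=dict)
    hrf_mode: str = "none"

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def drift_names(self) -> list[str]:
        return [c for c in self.matrix.columns if c.startswith("drift_")]

    def features(self) -> pd.DataFrame:
        return self.matrix[self.feature_names]

    def nuisance(self) -> pd.DataFrame:
        """Drift + intercept columns."""
        return self.matrix[self.drift_names + ["intercept"]]


# ---------------------------------------------------------------------------
# HRF

def canonical_hrf(tr_s: float, duration_s: float = 32.0,
                  oversample: int = 16) -> np.ndarray:
    """Canonical double-gamma HRF sampled on the TR grid.

    Difference of two gamma densities (peak ~5 s, undershoot ~15 s,
    undershoot ratio 1/6), averaged within each TR from an oversampled grid
    and normalized to unit sum so convolution preserves the scale of
    sustained input.
    """
    dt = tr_s / oversample
    t = np.arange(0, duration_s, dt)
    peak = gamma_dist.pdf(t, 6, scale=1.0)
    undershoot = gamma_dist.pdf(t, 16, scale=1.0)
    fine = peak - undershoot / 6.0
    n = t.size // oversample
    h = fine[: n * oversample].reshape(n, oversample).mean(axis=1)
    return h / h.sum()


def hrf_convolve(tc: FeatureTimecourse, mode: str = "canonical",
                 ) -> FeatureTimecourse:
    """Causal convolution with the canonical HRF, truncated to the original
    length; ``mode='none'`` is the identity (the published analysis does not
    state whether rating regressors were convolved, so both are supported)."""
    if mode == "none":
        return tc
    if mode != "canonical":
        raise ValidationError(f"unknown hrf mode {mode!r}")
    h = canonical_hrf(tc.tr_s)
    values = np.convolve(tc.values, h)[: len(tc)]
    return FeatureTimecourse(tc.feature, values, tc.tr_s, provenance="convolved")


# ---------------------------------------------------------------------------
# Drift basis

def dct_highpass_basis(n_volumes: int, tr_s: float, cutoff_s: float,
                       ) -> np.ndarray:
    """Orthonormal DCT-II drift columns with periods longer than ``cutoff_s``.

    The number of columns follows the K = floor(2 * n * tr / cutoff)
    convention; K = 0 (drift handled by the intercept alone) when the cutoff
    exceeds twice the run duration.
    """
    if n_volumes < 2:
        raise ValidationError("need at least 2 volumes for a drift basis")
    if cutoff_s <= 2 * tr_s:
        raise ValidationError("cutoff must exceed twice the TR")
    K = int(np.floor(2.0 * n_volumes * tr_s / cutoff_s))
    t = np.arange(n_volumes)
    cols = np.empty((n_volumes, K))
    for k in range(1, K + 1):
        cols[:, k - 1] = np.sqrt(2.0 / n_volumes) * np.cos(
            np.pi * k * (t + 0.5) / n_volumes)
    return cols


# ---------------------------------------------------------------------------
# Orthogonalization

def orthogonalize_feature(feature: str, X: pd.DataFrame,
                          ) -> tuple[np.ndarray, dict]:
    """Residualize one feature against all other original regressors.

    Returns the residual column and a ledger entry with the least-squares
    weights over the other features, the intercept of the fit, and the R^2
    (fraction of the feature's variance explained by the others).
    """
    others = [c for c in X.columns if c != feature]
    y = X[feature].to_numpy(dtype=float)
    A = np.column_stack([X[others].to_numpy(dtype=float),
                         np.ones(len(X))])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        dep = _dependent_columns(X[others])
        raise CollinearityError(
            f"other regressors are rank deficient: {dep}", dependent=dep)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fit = A @ coef
    residual = y - fit
    centered = y - y.mean()
    ss_tot = float(centered @ centered)
    r2 = 1.0 - float(residual @ residual) / ss_tot if ss_tot > 0 else 1.0
    ledger = {
        "weights": dict(zip(others, coef[:-1].tolist())),
        "intercept": float(coef[-1]),
        "r_squared": r2,
        "residual_variance_fraction": 1.0 - r2,
    }
    return residual, ledger


def orthogonalize_all(X: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Simultaneously orthogonalize every feature against the other originals."""
    out = {}
    ledger = {}
    for feature in X.columns:
        residual, entry = orthogonalize_feature(feature, X)
        out[feature] = residual
        ledger[feature] = entry
    return pd.DataFrame(out, index=X.index), ledger


def _dependent_columns(X: pd.DataFrame) -> list[str]:
    """Name a minimal-ish set of columns involved in a rank deficiency."""
    cols = list(X.columns)
    arr = X.to_numpy(dtype=float)
    dep = []
    kept: list[int] = []
    for j in range(arr.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(arr[:, trial]) < len(trial):
            dep.append(cols[j])
        else:
            kept.append(j)
    return dep


# ---------------------------------------------------------------------------
# Assembly

def build_design(timecourses: list[FeatureTimecourse], tr_s: float,
                 highpass_cutoff_s: float = 128.0,
                 hrf_mode: str = "canonical",
                 orthogonalize: bool = False) -> DesignMatrix:
    """Assemble the full design: (optional) mutual orthogonalization on the
    rating time courses, then (optional) HRF convolution, then the DCT drift
    basis and intercept."""
    lengths = {len(tc) for tc in timecourses}
    if len(lengths) != 1:
        raise AlignmentError("feature time courses have unequal lengths")
    n = lengths.pop()
    names = [tc.feature for tc in timecourses]
    X = pd.DataFrame({tc.feature: tc.values for tc in timecourses})

    ledger: dict[str, dict] = {}
    if orthogonalize:
        X, ledger = orthogonalize_all(X)

    if hrf_mode != "none":
        for name in names:
            tc = FeatureTimecourse(name, X[name].to_numpy(), tr_s,
                                   provenance="orthogonalized" if orthogonalize
                                   else "downsampled")
            X[name] = hrf_convolve(tc, hrf_mode).values

    drift = dct_highpass_basis(n, tr_s, highpass_cutoff_s)
    for k in range(drift.shape[1]):
        X[f"drift_{k + 1}"] = drift[:, k]
    X["intercept"] = 1.0
    return DesignMatrix(matrix=X, tr_s=tr_s, feature_names=names,
                        ortho_ledger=ledger, hrf_mode=hrf_mode)


# ---------------------------------------------------------------------------
# Diagnostics

def compare_orthogonalization(tmaps_orig: dict[str, "StatMap"],
                              tmaps_orth: dict[str, "StatMap"],
                              X: pd.DataFrame, X_orth: pd.DataFrame,
                              ) -> dict[str, dict[str, float]]:
    """Per-feature spatial correlation between original and orthogonalized
    t-maps (over in-mask voxels) and temporal correlation between the
    original and orthogonalized regressors."""
    report: dict[str, dict[str, float]] = {}
    for feature in X.columns:
        a = tmaps_orig[feature]
        b = tmaps_orth[feature]
        if a.values.shape != b.values.shape or not np.array_equal(a.mask, b.mask):
            raise AlignmentError("t-maps do not share grid/mask")
        va = a.values[a.mask]
        vb = b.values[b.mask]
        if va.std() == 0 or vb.std() == 0:
            raise DegenerateDataError(f"zero-variance t-map for {feature!r}")
        xa = X[feature].to_numpy(dtype=float)
        xb = X_orth[feature].to_numpy(dtype=float)
        report[feature] = {
            "spatial_r": float(np.corrcoef(va, vb)[0, 1]),
            "temporal_r": float(np.corrcoef(xa, xb)[0, 1]),
        }
    return report
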