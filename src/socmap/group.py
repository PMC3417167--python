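"""Second-level random-effects inference and overlap maps.

Per-feature subject maps enter a voxelwise one-sample t-test against zero
(df = n - 1, two-sided p); paired comparisons are one-sample tests on
differences. Significance is Benjamini–Hochberg FDR over all in-mask voxels
(q = 0.05 by default). Cumulative overlap maps count, per voxel, how many of
the eight social features reached positive-effect significance (t > 0 and
FDR-significant), i.e. activation rather than deactivation.

Zero between-subject variance at a voxel leaves t undefined; such voxels are
conservatively assigned t = 0, p = 1 (hence never significant) unless the
mean is also exactly zero-consistent — the convention is logged by callers.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import GeometryError, PairingError, ValidationError
from .glm import StatMap


def _stack(maps: list[StatMap]) -> tuple[np.ndarray, StatMap]:
    ref = maps[0]
    for m in maps[1:]:
        if m.values.shape != ref.values.shape or not np.array_equal(m.mask,
                                                                    ref.mask):
            raise GeometryError("subject maps do not share grid/mask")
    data = np.stack([m.values[ref.mask] for m in maps])  # (n, V)
    return data, ref


def one_sample_t_flat(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """One-sample t against zero on a (subjects, voxels) array.

    Returns (t, p, df); zero-variance voxels get t = 0, p = 1 (conservative).
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 subjects")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0) * np.sqrt(n), 0.0)
    p = np.where(sd > 0, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return t, p, df


def one_sample_t(maps: list[StatMap]) -> tuple[StatMap, StatMap]:
    """Voxelwise one-sample t-test of the subject maps against zero."""
    if len(maps) < 2:
        raise ValidationError("need at least 2 subjects")
    data, ref = _stack(maps)
    t, p, df = one_sample_t_flat(data)
    t_map = _as_map("t", t, ref, df)
    p_map = _as_map("p", p, ref, df)
    return t_map, p_map


def paired_t(maps_a: list[StatMap], maps_b: list[StatMap],
             ) -> tuple[StatMap, StatMap]:
    """Paired-samples t-test: one-sample t applied to per-subject a - b."""
    if len(maps_a) != len(maps_b):
        raise PairingError("subject sets differ in size")
    diffs = []
    for a, b in zip(maps_a, maps_b):
        if a.values.shape != b.values.shape:
            raise PairingError("subject maps cannot be paired (grid mismatch)")
        diffs.append(StatMap(kind=a.kind, values=a.values - b.values,
                             feature=f"{a.feature}_minus_{b.feature}",
                             level="first", affine=a.affine, mask=a.mask))
    return one_sample_t(diffs)


def fdr_significance(p_map: StatMap, q: float, n_comparisons: int = 1,
                     ) -> tuple[StatMap, float]:
    """Benjamini–Hochberg over all in-mask voxels.

    With sorted p-values p(1) <= ... <= p(m), the threshold is
    p* = max{ p(k) : p(k) <= k q / m } (p* = 0 when no k qualifies);
    a voxel is significant iff p <= p*. Returns the binary map and p*.

    ``n_comparisons`` Bonferroni-divides q across separately tested features
    (e.g. 14 when correcting over the modeled feature set); the default of 1
    reports per-feature maps uncorrected across features.
    """
    mask = p_map.mask
    if not mask.any():
        raise ValidationError("empty mask")
    if n_comparisons < 1:
        raise ValidationError("n_comparisons must be >= 1")
    p = p_map.values[mask]
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p values outside [0, 1]")
    p_star = bh_threshold(p, q / n_comparisons)
    sig = np.zeros(mask.shape, dtype=int)
    sig[mask] = (p <= p_star) if p_star > 0 else False
    sig_map = StatMap(kind="significance", values=sig, feature=p_map.feature,
                      level=p_map.level, affine=p_map.affine, mask=mask)
    return sig_map, p_star


def bh_threshold(p: np.ndarray, q: float) -> float:
    """The BH critical p-value p* for a flat p vector (0 if nothing passes)."""
    p = np.sort(np.asarray(p, dtype=float))
    m = p.size
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(p <= crit)
    return float(p[passing[-1]]) if passing.size else 0.0


def positive_significance(sig_map: StatMap, t_map: StatMap) -> StatMap:
    """Restrict a significance map to positive effects (activation)."""
    values = (sig_map.values > 0) & (t_map.values > 0) & sig_map.mask
    return StatMap(kind="significance", values=values.astype(int),
                   feature=sig_map.feature, level=sig_map.level,
                   affine=sig_map.affine, mask=sig_map.mask)


def overlap_map(sig_maps: list[StatMap]) -> StatMap:
    """Voxelwise count of features with significant (positive) activation —
    the cumulative activation map over the eight social features."""
    ref = sig_maps[0]
    for m in sig_maps[1:]:
        if m.values.shape != ref.values.shape or not np.array_equal(
                m.mask, ref.mask):
            raise GeometryError("significance maps are misaligned")
    counts = np.sum([(m.values > 0).astype(int) for m in sig_maps], axis=0)
    counts = np.where(ref.mask, counts, 0)
    return StatMap(kind="overlap", values=counts, feature="social_overlap",
                   level="second", affine=ref.affine, mask=ref.mask)


def _as_map(kind: str, flat: np.ndarray, ref: StatMap, df: float) -> StatMap:
    vol = np.full(ref.values.shape, np.nan)
    vol[ref.mask] = flat
    return StatMap(kind=kind, values=vol, feature=ref.feature, level="second",
                   affine=ref.affine, mask=ref.mask, df=df)
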