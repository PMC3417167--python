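"""Spherical ROIs in world (MNI mm) coordinates.

Membership is by voxel-center distance: a voxel belongs to the sphere when its
world-space center lies within the closed ball of ``radius_mm`` around the
center (no partial-volume weighting). Beta summaries use 3-mm spheres;
connectivity time series use 6-mm spheres for signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CompletenessError, EmptyRoiError, ValidationError
from .glm import StatMap


@dataclass
class RoiSpec:
    name: str
    hemisphere: str
    center_mm: np.ndarray
    radius_mm: float

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        if self.center_mm.shape != (3,):
            raise ValidationError("center_mm must be a 3-vector")
        if self.radius_mm <= 0:
            raise ValidationError("radius_mm must be > 0")


def sphere_mask(spec: RoiSpec, affine: np.ndarray, shape: tuple[int, int, int],
                ) -> np.ndarray:
    """Boolean 3-D mask of voxels whose world centers lie within the ROI."""
    affine = np.asarray(affine, dtype=float)
    ijk = np.indices(shape).reshape(3, -1)
    world = affine[:3, :3] @ ijk + affine[:3, 3:4]
    d2 = np.sum((world - spec.center_mm[:, None]) ** 2, axis=0)
    mask = (d2 <= spec.radius_mm ** 2).reshape(shape)
    if not mask.any():
        raise EmptyRoiError(f"ROI {spec.name!r} contains no voxels")
    return mask


def mean_roi_timeseries(series, spec: RoiSpec) -> np.ndarray:
    """Per-volume mean over the in-mask voxels of the ROI sphere."""
    ball = sphere_mask(spec, series.affine, series.mask.shape)
    sel = ball & series.mask
    if not sel.any():
        raise EmptyRoiError(f"ROI {spec.name!r} lies entirely outside the mask")
    return series.data[sel].mean(axis=0)


def beta_summary(subject_betas: list[dict[str, StatMap]], spec: RoiSpec,
                 features: tuple[str, ...]) -> pd.DataFrame:
    """ROI-mean beta per subject and feature, with the across-subject mean
    and t-based 95% confidence interval.

    Returns a DataFrame indexed by feature with columns mean, ci_low,
    ci_high, and per-subject values in ``subject_values``.
    """
    if len(subject_betas) < 2:
        raise ValidationError("need at least 2 subjects")
    rows = []
    n = len(subject_betas)
    tcrit = stats.t.ppf(0.975, n - 1)
    for feat in features:
        vals = []
        for maps in subject_betas:
            if feat not in maps:
                raise CompletenessError(f"missing beta map for {feat!r}")
            m = maps[feat]
            ball = sphere_mask(spec, m.affine, m.mask.shape) & m.mask
            if not ball.any():
                raise EmptyRoiError(f"ROI {spec.name!r} outside mask")
            vals.append(float(np.nanmean(m.values[ball])))
        vals = np.asarray(vals)
        mean = vals.mean()
        sem = vals.std(ddof=1) / np.sqrt(n)
        rows.append({"feature": feat, "mean": mean,
                     "ci_low": mean - tcrit * sem,
                     "ci_high": mean + tcrit * sem,
                     "subject_values": vals.tolist()})
    return pd.DataFrame(rows).set_index("feature")


def find_overlap_peak(overlap: StatMap, t_mean: StatMap,
                      radius_mm: float = 3.0, name: str = "peak",
                      ) -> RoiSpec:
    """Locate the voxel of maximal overlap (ties broken by highest mean t,
    then lexicographic index order) and return a spherical ROI around it."""
    vals = np.where(overlap.mask, overlap.values, -1)
    best = vals.max()
    cand = np.argwhere(vals == best)
    t = np.where(np.isfinite(t_mean.values), t_mean.values, -np.inf)
    tvals = np.array([t[tuple(c)] for c in cand])
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -tvals))
    ijk = cand[order[0]]
    center = overlap.affine[:3, :3] @ ijk + overlap.affine[:3, 3]
    return RoiSpec(name=name, hemisphere="", center_mm=center,
                   radius_mm=radius_mm)
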