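"""Readers and writers for every external format the pipeline touches.

NIfTI-1 (via nibabel) for 4-D series, masks and statistical maps; long-format
TSV for rating tables (columns clip_id, feature, rater, sample_index, value)
and ROI tables (roi_name, hemisphere, x, y, z, radius_mm, in MNI mm);
weighted edge lists for graphs; JSON for reports. Every reader/writer pair is
a lossless round trip at stored precision. Internal voxel indices are
0-based; all user-facing coordinates are world (MNI mm) through the affine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .glm import StatMap
from .ratings import RATING_MAX, RATING_MIN, ClipTrack


@dataclass
class VolumeSeries:
    """A subject's 4-D BOLD data with geometry.

    ``data`` is (x, y, z, t) in arbitrary signal units; ``mask`` is a boolean
    3-D array on the same grid; statistics are computed only over mask-true
    voxels. ``n_discarded`` records how many initial volumes were already
    removed (equilibration volumes).
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    mask: np.ndarray
    subject_id: str = ""
    n_discarded: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValidationError("data must be 4-D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise GeometryError("mask shape differs from spatial data shape")
        if self.tr_s <= 0:
            raise ValidationError("tr_s must be > 0")
        if self.data.shape[-1] < 2:
            raise ValidationError("need at least 2 volumes")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    def flat(self) -> np.ndarray:
        """In-mask data as (T, V)."""
        return self.data[self.mask].T


# ---------------------------------------------------------------------------
# NIfTI

def read_volume_series(path, mask_path, n_discard: int = 2,
                       subject_id: str = "", tr_s: float | None = None,
                       ) -> VolumeSeries:
    """Load a 4-D NIfTI and its mask, discarding the first ``n_discard``
    volumes (equilibration). TR is taken from the header unless given."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValidationError(f"{path} is not 4-D")
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    if mask.shape != data.shape[:3]:
        raise GeometryError("mask grid does not match data grid")
    if not np.allclose(mask_img.affine, img.affine):
        raise GeometryError("mask affine does not match data affine")
    if data.shape[-1] <= n_discard:
        raise ValidationError("no volumes left after discarding")
    if tr_s is None:
        tr_s = float(img.header.get_zooms()[3])
    return VolumeSeries(data=data[..., n_discard:], affine=img.affine,
                        tr_s=tr_s, mask=mask, subject_id=subject_id,
                        n_discarded=n_discard)


def write_volume_series(series: VolumeSeries, path, mask_path=None) -> None:
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float64),
                          series.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], series.tr_s))
    nib.save(img, str(path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(series.mask.astype(np.uint8), series.affine),
                 str(mask_path))


def write_stat_map(stat_map: StatMap, path) -> None:
    """Write a StatMap as NIfTI; NaN outside the mask is preserved for real
    maps, integer maps (overlap/significance) keep 0 outside."""
    values = stat_map.values
    dtype = np.int16 if stat_map.kind in ("significance", "overlap") else np.float64
    img = nib.Nifti1Image(np.asarray(values, dtype=dtype), stat_map.affine)
    img.header["descrip"] = f"{stat_map.kind}:{stat_map.feature}:{stat_map.level}"
    nib.save(img, str(path))


def read_stat_map(path, mask: np.ndarray, kind: str = "", feature: str = "",
                  level: str = "first", df: float | None = None) -> StatMap:
    img = nib.load(str(path))
    if not kind:
        desc = img.header["descrip"].item().decode() or "::"
        kind, feature, level = desc.split(":")[:3]
    return StatMap(kind=kind, values=np.asarray(img.dataobj), feature=feature,
                   level=level, affine=img.affine, mask=mask, df=df)


# ---------------------------------------------------------------------------
# Rating tables

RATING_COLUMNS = ["clip_id", "feature", "rater", "sample_index", "value"]


def read_rating_table(path, rate_hz: float = 5.0,
                      ) -> dict[tuple[str, str, str], ClipTrack]:
    """Read a long-format rating TSV into per-(clip, feature, rater) tracks.

    Validates the declared 1–5 scale, uniqueness of
    (clip, feature, rater, sample) keys, and gap-free sample indices.
    """
    df = pd.read_csv(path, sep="\t", dtype={"clip_id": str, "feature": str,
                                            "rater": str})
    missing = set(RATING_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"rating table lacks columns: {sorted(missing)}")
    bad = df[(df["value"] < RATING_MIN) | (df["value"] > RATING_MAX)]
    if len(bad):
        raise ValidationError(
            f"{len(bad)} rating values outside [{RATING_MIN}, {RATING_MAX}]")
    keys = ["clip_id", "feature", "rater", "sample_index"]
    if df.duplicated(subset=keys).any():
        raise ValidationError("duplicated (clip, feature, rater, sample) rows")
    tracks: dict[tuple[str, str, str], ClipTrack] = {}
    for (clip, feature, rater), grp in df.groupby(["clip_id", "feature",
                                                   "rater"], sort=False):
        grp = grp.sort_values("sample_index")
        idx = grp["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValidationError(
                f"missing samples for ({clip}, {feature}, {rater})")
        tracks[(clip, feature, rater)] = ClipTrack(
            clip, feature, grp["value"].to_numpy(dtype=float), rate_hz,
            rater=rater)
    return tracks


def write_rating_table(tracks: dict[tuple[str, str, str], ClipTrack],
                       path) -> None:
    rows = []
    for (clip, feature, rater), track in tracks.items():
        for i, v in enumerate(track.values):
            rows.append((clip, feature, rater, i, v))
    pd.DataFrame(rows, columns=RATING_COLUMNS).to_csv(path, sep="\t",
                                                      index=False)


# ---------------------------------------------------------------------------
# ROI tables

ROI_COLUMNS = ["roi_name", "hemisphere", "x", "y", "z", "radius_mm"]


def read_roi_table(path) -> list["RoiSpec"]:
    from .roi import RoiSpec
    df = pd.read_csv(path, sep="\t")
    missing = set(ROI_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"ROI table lacks columns: {sorted(missing)}")
    return [RoiSpec(name=row.roi_name, hemisphere=row.hemisphere,
                    center_mm=np.array([row.x, row.y, row.z], dtype=float),
                    radius_mm=float(row.radius_mm))
            for row in df.itertuples()]


def write_roi_table(rois, path) -> None:
    rows = [(r.name, r.hemisphere, *r.center_mm, r.radius_mm) for r in rois]
    pd.DataFrame(rows, columns=ROI_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Graphs and reports

def write_edge_list(edges: list[tuple[str, str, float]], path) -> None:
    pd.DataFrame(edges, columns=["node_a", "node_b", "mean_r"]).to_csv(
        path, sep="\t", index=False)


def read_edge_list(path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(a), str(b), float(r))
            for a, b, r in df[["node_a", "node_b", "mean_r"]].itertuples(
                index=False)]


def save_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def load_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
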