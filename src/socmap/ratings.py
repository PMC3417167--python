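"""From raw two-rater clip ratings to regressor time courses.

Raters watched each clip and continuously moved a cursor on a 1 (feature not
present) to 5 (present very clearly) scale, sampled at 5 Hz. The analysis chain
is: average the two raters per clip, concatenate the clips in presentation
order, and down-sample to the acquisition grid (TR) by within-TR averaging.
Diagnostics: per-feature inter-rater Pearson r and the 14x14 between-feature
correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (AlignmentError, CompletenessError, DegenerateDataError,
                     ValidationError)

RATING_MIN, RATING_MAX = 1.0, 5.0

#: The eight social features and six non-social (filler) features.
SOCIAL_FEATURES = (
    "faces", "human_bodies", "biological_motion", "goal_oriented_action",
    "emotion", "social_interaction", "pain", "speech",
)
NONSOCIAL_FEATURES = (
    "places", "objects", "rigid_motion", "people_no_interaction",
    "non_goal_action", "non_human_sounds",
)
ALL_FEATURES = SOCIAL_FEATURES + NONSOCIAL_FEATURES


@dataclass
class ClipTrack:
    """One rater's (or the rater-averaged) track for one clip and feature,
    sampled at ``rate_hz`` during clip playback only (the 5-s pre-clip still
    frame used to pick the initial rating is excluded)."""

    clip_id: str
    feature: str
    values: np.ndarray
    rate_hz: float
    rater: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValidationError("track values must be a non-empty 1-D array")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be > 0")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz


@dataclass
class FeatureTimecourse:
    """One feature's regressor, either on the rating grid or the acquisition
    grid, with its processing provenance."""

    feature: str
    values: np.ndarray
    tr_s: float
    provenance: str = "raw"  # raw | averaged | downsampled | convolved | orthogonalized

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("timecourse values must be 1-D")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("timecourse contains missing values")
        if self.tr_s <= 0:
            raise ValidationError("tr_s must be > 0")

    def __len__(self) -> int:
        return self.values.size


def average_raters(a: ClipTrack, b: ClipTrack) -> ClipTrack:
    """Element-wise mean of the two raters' tracks for one clip and feature."""
    if a.clip_id != b.clip_id or a.feature != b.feature:
        raise AlignmentError(
            f"cannot average tracks of ({a.clip_id},{a.feature}) "
            f"and ({b.clip_id},{b.feature})")
    if a.values.size != b.values.size:
        raise AlignmentError(
            f"track length mismatch for ({a.clip_id},{a.feature}): "
            f"{a.values.size} vs {b.values.size}")
    if a.rate_hz != b.rate_hz:
        raise AlignmentError("sampling-rate mismatch between raters")
    return ClipTrack(a.clip_id, a.feature, (a.values + b.values) / 2.0,
                     a.rate_hz, rater="averaged")


def concatenate_clips(tracks: dict[tuple[str, str], ClipTrack],
                      presentation_order: list[str],
                      features: tuple[str, ...] = ALL_FEATURES,
                      ) -> dict[str, np.ndarray]:
    """Concatenate per-clip tracks in presentation order, one long track per
    feature. The stimulus stream contained no gaps between clips, so tracks
    are joined back to back."""
    out: dict[str, np.ndarray] = {}
    for feat in features:
        parts = []
        for clip in presentation_order:
            key = (clip, feat)
            if key not in tracks:
                raise CompletenessError(f"missing track for clip {clip!r}, "
                                        f"feature {feat!r}")
            parts.append(tracks[key].values)
        out[feat] = np.concatenate(parts)
    return out


def downsample_to_tr(values: np.ndarray, rate_hz: float, tr_s: float,
                     feature: str = "", provenance: str = "downsampled",
                     ) -> FeatureTimecourse:
    """Down-sample a rating-rate track to the acquisition grid.

    Output sample ``k`` is the mean of the raw samples whose time centers
    ``(i + 0.5) / rate_hz`` fall in ``[k*tr_s, (k+1)*tr_s)``; the partial final
    window is dropped, so the output length is ``floor(duration / tr_s)``.
    Averaging (rather than decimation) anti-aliases the 5 Hz track.
    """
    values = np.asarray(values, dtype=float)
    if rate_hz * tr_s <= 1:
        raise ValidationError("need rate_hz * tr_s > 1 so every TR window "
                              "contains at least one rating sample")
    duration = values.size / rate_hz
    n_out = int(np.floor(duration / tr_s))
    centers = (np.arange(values.size) + 0.5) / rate_hz
    window = np.floor(centers / tr_s).astype(int)
    out = np.empty(n_out)
    for k in range(n_out):
        sel = values[window == k]
        if sel.size == 0:  # cannot occur when rate_hz*tr_s > 1
            raise AssertionError("empty TR window")
        out[k] = sel.mean()
    return FeatureTimecourse(feature, out, tr_s, provenance=provenance)


def interrater_reliability(a_tracks: dict[str, np.ndarray],
                           b_tracks: dict[str, np.ndarray],
                           ) -> tuple[dict[str, float], float]:
    """Per-feature Pearson r between the two raters' concatenated tracks and
    the unweighted mean across features."""
    per_feature: dict[str, float] = {}
    for feat, a in a_tracks.items():
        b = b_tracks[feat]
        if a.size != b.size:
            raise AlignmentError(f"length mismatch for feature {feat!r}")
        per_feature[feat] = _pearson(a, b)
    return per_feature, float(np.mean(list(per_feature.values())))


def feature_correlation_matrix(tracks: dict[str, np.ndarray] |
                               list[FeatureTimecourse]) -> pd.DataFrame:
    """Pairwise Pearson correlations between the (mean-rating) feature
    tracks; symmetric with unit diagonal."""
    if isinstance(tracks, dict):
        names = list(tracks)
        data = np.vstack([tracks[n] for n in names])
    else:
        names = [tc.feature for tc in tracks]
        data = np.vstack([tc.values for tc in tracks])
    lengths = {row.size for row in data}
    if len(lengths) > 1:
        raise AlignmentError("tracks have unequal lengths")
    sds = data.std(axis=1)
    if np.any(sds == 0):
        bad = [names[i] for i in np.flatnonzero(sds == 0)]
        raise DegenerateDataError(f"zero-variance tracks: {bad}")
    corr = np.corrcoef(data)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def mean_abs_offdiagonal(corr: pd.DataFrame) -> float:
    """Mean |r| over the strictly upper triangle — the collinearity summary
    reported for the feature set."""
    c = np.asarray(corr, dtype=float)
    iu = np.triu_indices_from(c, k=1)
    return float(np.mean(np.abs(c[iu])))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        raise DegenerateDataError("correlation undefined for zero-variance track")
    return float(np.corrcoef(a, b)[0, 1])
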