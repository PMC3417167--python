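"""Synthetic ratings and BOLD data with known ground truth.

The generator emulates the study design so every downstream stage is testable
by parameter/structure recovery: 137 clips of duration 16.6 ± 2.7 s, 14
feature tracks (8 social + 6 non-social) on the 1–5 prominence scale sampled
at 5 Hz by two noisy raters, and per-subject BOLD series at TR 2.112 s with
AR(1) noise and planted region-specific responses, including one "hub" region
responsive to all eight social features and to no non-social feature.

Rating model: latent prominence tracks are correlated Gaussian processes
(squared-exponential kernel, length-scale ~2 s — raters moved a cursor
continuously, so tracks are smooth) mapped through 3 + 2*tanh(gain * z) into
the open interval (1, 5). Each rater adds smooth latent noise before the
squashing. The defaults are calibrated so the rater-averaged tracks show
inter-rater r ~ 0.78 and mean between-feature |r| ~ 0.18. The default
correlation structure places social features near mutual independence (clips
were selected to make them "as independent as possible"), filler features in
a correlated block (~0.45, objects–rigid motion highest) and a mild negative
social-filler correlation, reflecting that clips prominently social tend not
to dwell on scenery fillers.

BOLD noise is Gaussian AR(1) in time (default rho 0.4), optionally smoothed
in space (default FWHM 6 mm, variance-renormalized); per-subject effect sizes
are jittered around ``beta_true`` for a random-effects structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.signal import lfilter

from .errors import ValidationError
from .ratings import (ALL_FEATURES, NONSOCIAL_FEATURES, SOCIAL_FEATURES,
                      ClipTrack)

#: latent -> rating squashing gain (ratings = 3 + 2*tanh(gain*z))
SQUASH_GAIN = 0.8
#: latent-space rater noise calibrated for inter-rater r ~ 0.78
DEFAULT_RATER_NOISE_SD = 0.50
#: squared-exponential length-scale of latent tracks, seconds
LATENT_LENGTH_SCALE_S = 2.0

DEFAULT_N_CLIPS = 137
DEFAULT_DURATION_MEAN_S = 16.6
DEFAULT_DURATION_SD_S = 2.7
DEFAULT_DURATION_RANGE_S = (10.3, 27.3)
DEFAULT_RATE_HZ = 5.0


# ---------------------------------------------------------------------------
# Feature correlation target

def default_feature_corr(features: tuple[str, ...] = ALL_FEATURES,
                         ) -> np.ndarray:
    """Default 14x14 latent correlation target (see module docstring)."""
    n = len(features)
    corr = np.eye(n)
    social = set(SOCIAL_FEATURES)
    for i, fi in enumerate(features):
        for j, fj in enumerate(features):
            if i == j:
                continue
            si, sj = fi in social, fj in social
            if si and sj:
                r = 0.0
            elif not si and not sj:
                r = 0.55 if {fi, fj} == {"objects", "rigid_motion"} else 0.45
            else:
                r = -0.25
            corr[i, j] = r
    _check_corr(corr)
    return corr


def _check_corr(corr: np.ndarray) -> None:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValidationError("correlation target must be square")
    if not np.allclose(corr, corr.T):
        raise ValidationError("correlation target must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValidationError("correlation target must have unit diagonal")
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValidationError("correlation target is not positive semi-definite")


# ---------------------------------------------------------------------------
# Ratings

@dataclass
class RatingsSample:
    clip_ids: list[str]
    durations_s: np.ndarray
    rate_hz: float
    features: tuple[str, ...]
    tracks_a: dict[tuple[str, str], ClipTrack]
    tracks_b: dict[tuple[str, str], ClipTrack]
    latent: dict[tuple[str, str], np.ndarray]


def _smooth_unit_noise(rng: np.random.Generator, shape: tuple[int, int],
                       sigma_samples: float) -> np.ndarray:
    """Rows of smooth unit-variance Gaussian noise (SE-kernel GP)."""
    pad = int(np.ceil(4 * sigma_samples))
    raw = rng.standard_normal((shape[0], shape[1] + 2 * pad))
    sm = gaussian_filter1d(raw, sigma_samples, axis=1)[:, pad:pad + shape[1]]
    impulse = np.zeros(2 * pad + 1)
    impulse[pad] = 1.0
    kernel = gaussian_filter1d(impulse, sigma_samples)
    return sm / np.sqrt(np.sum(kernel ** 2))


def _squash(z: np.ndarray) -> np.ndarray:
    return 3.0 + 2.0 * np.tanh(SQUASH_GAIN * z)


def generate_ratings(n_clips: int = DEFAULT_N_CLIPS,
                     duration_mean_s: float = DEFAULT_DURATION_MEAN_S,
                     duration_sd_s: float = DEFAULT_DURATION_SD_S,
                     features: tuple[str, ...] = ALL_FEATURES,
                     corr_target: np.ndarray | None = None,
                     rater_noise_sd: float = DEFAULT_RATER_NOISE_SD,
                     rate_hz: float = DEFAULT_RATE_HZ,
                     seed: int = 0) -> RatingsSample:
    """Generate per-clip two-rater rating tracks plus the true latent tracks."""
    if n_clips < 1:
        raise ValidationError("n_clips must be >= 1")
    if corr_target is None:
        corr_target = default_feature_corr(features)
    corr_target = np.asarray(corr_target, dtype=float)
    if corr_target.shape != (len(features), len(features)):
        raise ValidationError("corr_target shape does not match feature count")
    _check_corr(corr_target)
    # guard the Cholesky against an exactly singular (but valid) target
    L = np.linalg.cholesky(corr_target + 1e-10 * np.eye(len(features)))

    rng = np.random.default_rng(seed)
    sigma = LATENT_LENGTH_SCALE_S * rate_hz / np.sqrt(2.0)
    lo, hi = DEFAULT_DURATION_RANGE_S
    durations = np.clip(rng.normal(duration_mean_s, duration_sd_s, n_clips),
                        lo, hi)
    clip_ids = [f"clip{idx:03d}" for idx in range(n_clips)]

    tracks_a: dict[tuple[str, str], ClipTrack] = {}
    tracks_b: dict[tuple[str, str], ClipTrack] = {}
    latent: dict[tuple[str, str], np.ndarray] = {}
    F = len(features)
    for clip, dur in zip(clip_ids, durations):
        n = max(2, int(round(dur * rate_hz)))
        g = L @ _smooth_unit_noise(rng, (F, n), sigma)
        noise_a = _smooth_unit_noise(rng, (F, n), sigma) * rater_noise_sd
        noise_b = _smooth_unit_noise(rng, (F, n), sigma) * rater_noise_sd
        for fi, feat in enumerate(features):
            latent[(clip, feat)] = _squash(g[fi])
            tracks_a[(clip, feat)] = ClipTrack(clip, feat,
                                               _squash(g[fi] + noise_a[fi]),
                                               rate_hz, rater="A")
            tracks_b[(clip, feat)] = ClipTrack(clip, feat,
                                               _squash(g[fi] + noise_b[fi]),
                                               rate_hz, rater="B")
    return RatingsSample(clip_ids=clip_ids, durations_s=durations,
                         rate_hz=rate_hz, features=features,
                         tracks_a=tracks_a, tracks_b=tracks_b, latent=latent)


# ---------------------------------------------------------------------------
# Ground truth geometry

@dataclass
class GroundTruth:
    """Planted effects for recovery tests.

    ``beta_true`` is (x, y, z, feature); ``region_labels`` names the planted
    regions (0 = null background). The hub region has positive betas for all
    eight social features and non-positive betas for every filler feature.
    """

    beta_true: np.ndarray
    region_labels: np.ndarray
    regions: dict[str, dict]
    affine: np.ndarray
    mask: np.ndarray
    features: tuple[str, ...]
    ar1_rho_true: float
    feature_corr_target: np.ndarray
    rater_noise_sd: float
    tr_s: float = 2.112

    def region_mask(self, name: str) -> np.ndarray:
        return self.region_labels == self.regions[name]["label"]

    def region_center_ijk(self, name: str) -> tuple[int, int, int]:
        return tuple(self.regions[name]["center_ijk"])


#: region name -> (center offset from grid center in voxels,
#:                 responsive features, intrinsic-fluctuation network)
_REGION_PLAN: dict[str, tuple[tuple[int, int, int], tuple[str, ...], str]] = {
    "hub_psts": ((0, 0, 0), SOCIAL_FEATURES, "temporo_social"),
    "fronto_parietal": ((-6, 0, 0),
                        ("human_bodies", "biological_motion",
                         "goal_oriented_action", "pain"), "fronto_parietal"),
    "temporo_amygdalar": ((6, 0, 0),
                          ("faces", "social_interaction", "speech"),
                          "temporo_social"),
    "fronto_insular": ((0, -6, 0),
                       ("pain", "emotion", "social_interaction", "speech"),
                       "fronto_parietal"),
    "fronto_temporal": ((0, 6, 0), ("faces", "emotion", "biological_motion"),
                        "temporo_social"),
    "nonsocial_scene": ((0, 0, -6), ("places", "objects", "rigid_motion"),
                        "nonsocial"),
    "nonsocial_sound": ((0, 0, 6),
                        ("non_goal_action", "non_human_sounds",
                         "people_no_interaction"), "nonsocial"),
}
SPECIALIZED_REGIONS = ("fronto_parietal", "temporo_amygdalar",
                       "fronto_insular", "fronto_temporal")
#: planted community structure of the ROI connectivity graph
PLANTED_NETWORKS: dict[str, tuple[str, ...]] = {
    "temporo_social": ("hub_psts", "temporo_amygdalar", "fronto_temporal"),
    "fronto_parietal": ("fronto_parietal", "fronto_insular"),
    "nonsocial": ("nonsocial_scene", "nonsocial_sound"),
}

HUB_SOCIAL_BETA = 1.0
HUB_NONSOCIAL_BETA = -0.3
REGION_BETA = 1.0


def make_ground_truth(shape: tuple[int, int, int] = (24, 24, 24),
                      voxel_mm: float = 4.0,
                      features: tuple[str, ...] = ALL_FEATURES,
                      ar1_rho: float = 0.4,
                      corr_target: np.ndarray | None = None,
                      rater_noise_sd: float = DEFAULT_RATER_NOISE_SD,
                      region_half_width: int = 1) -> GroundTruth:
    """Desk-scale ground truth: an ellipsoidal brain mask with a hub cube,
    four specialized social-network cubes and two non-social cubes planted
    around the grid center (cube half-width 1 voxel => 27 voxels each)."""
    if abs(ar1_rho) >= 1:
        raise ValidationError("|ar1_rho| must be < 1")
    if corr_target is None:
        corr_target = default_feature_corr(features)
    shape = tuple(shape)
    center = np.array([(s - 1) / 2.0 for s in shape])
    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = -center * voxel_mm

    ijk = np.indices(shape).astype(float)
    radius_vox = min(shape) / 2.0 - 0.5
    mask = np.sum(((ijk - center[:, None, None, None]) / radius_vox) ** 2,
                  axis=0) <= 1.0

    beta_true = np.zeros(shape + (len(features),))
    labels = np.zeros(shape, dtype=int)
    findex = {f: i for i, f in enumerate(features)}
    regions: dict[str, dict] = {}
    grid_center = np.round(center).astype(int)
    for label, (name, (offset, resp, network)) in enumerate(
            _REGION_PLAN.items(), start=1):
        c = grid_center + np.array(offset)
        sl = tuple(slice(ci - region_half_width, ci + region_half_width + 1)
                   for ci in c)
        labels[sl] = label
        for feat in resp:
            beta_true[sl + (findex[feat],)] = REGION_BETA
        if name == "hub_psts":
            for feat in NONSOCIAL_FEATURES:
                if feat in findex:
                    beta_true[sl + (findex[feat],)] = HUB_NONSOCIAL_BETA
        regions[name] = {"label": label, "center_ijk": tuple(int(x) for x in c),
                         "features": list(resp), "network": network}
    return GroundTruth(beta_true=beta_true, region_labels=labels,
                       regions=regions, affine=affine, mask=mask,
                       features=features, ar1_rho_true=ar1_rho,
                       feature_corr_target=np.asarray(corr_target),
                       rater_noise_sd=rater_noise_sd)


# ---------------------------------------------------------------------------
# BOLD generation

def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...],
               rho: float, sd: float, burn: int = 100,
               dtype=np.float32) -> np.ndarray:
    """Stationary AR(1) Gaussian noise along the last axis, marginal sd ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    w = rng.standard_normal(shape[:-1] + (shape[-1] + burn,),
                            dtype=dtype) * dtype(innov_sd)
    x = lfilter([1.0], [1.0, -rho], w, axis=-1)
    return np.asarray(x[..., burn:], dtype=dtype)


def _smooth_noise_inplace(noise: np.ndarray, fwhm_mm: float,
                          voxel_mm: float) -> np.ndarray:
    """Spatially smooth (x, y, z, t) noise and renormalize the voxel variance."""
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_mm
    out = gaussian_filter(noise, sigma=(sigma_vox,) * 3 + (0,), mode="wrap")
    impulse = np.zeros(noise.shape[0])
    impulse[noise.shape[0] // 2] = 1.0
    k2 = np.sum(gaussian_filter1d(impulse, sigma_vox, mode="wrap") ** 2)
    out /= np.sqrt(k2 ** 3)
    return out


def generate_subject_bold(regressors: np.ndarray, truth: GroundTruth,
                          subject_seed: np.random.SeedSequence | int,
                          noise_sd: float = 3.0,
                          smooth_fwhm_mm: float = 6.0,
                          between_subject_sd: float = 0.2,
                          subject_id: str = "", baseline: float = 100.0,
                          intrinsic_sd: float = 2.0,
                          dtype=np.float32):
    """One subject's 4-D series: planted signal + AR(1) noise.

    ``regressors`` is (T, n_features) on the acquisition grid (already
    HRF-convolved if the design calls for it); the voxel time series is
    sum_f beta_f * regressor_f + AR(1) noise, with the region's beta vector
    jittered per subject (only where beta_true is non-zero, so the null
    background stays null). Noise is generated in ``dtype`` (float32 by
    default — ample for unit-scale signal and noise; pass float64 for
    exact-recovery checks); all model fitting happens in float64 downstream.
    """
    from .io import VolumeSeries  # local import to avoid a cycle

    regressors = np.asarray(regressors, dtype=float)
    T, F = regressors.shape
    if F != len(truth.features):
        raise ValidationError("regressor count does not match ground truth")
    if abs(truth.ar1_rho_true) >= 1:
        raise ValidationError("|ar1_rho| must be < 1 for a stable process")
    rng = np.random.default_rng(subject_seed)
    shape = truth.region_labels.shape
    voxel_mm = float(np.abs(truth.affine[0, 0]))

    if noise_sd > 0:
        data = _ar1_noise(rng, shape + (T,), truth.ar1_rho_true, noise_sd,
                          dtype=dtype)
        if smooth_fwhm_mm > 0:
            data = _smooth_noise_inplace(data, smooth_fwhm_mm, voxel_mm)
    else:
        data = np.zeros(shape + (T,), dtype=dtype)
    data += dtype(baseline)

    # intrinsic network fluctuations: regions in the same functional network
    # share a latent AR(1) series, which is what gives the ROI connectivity
    # graph its community structure beyond stimulus-driven covariance
    networks = sorted({info["network"] for info in truth.regions.values()})
    if intrinsic_sd > 0:
        latents = {net: _ar1_noise(rng, (T,), truth.ar1_rho_true,
                                   intrinsic_sd, dtype=np.float64)
                   for net in networks}
    for name, info in truth.regions.items():
        sel = truth.region_labels == info["label"]
        beta = truth.beta_true[sel][0].copy()      # shared within the region
        jitter = rng.normal(0.0, between_subject_sd, size=F)
        beta = np.where(beta != 0, beta + jitter, 0.0)
        signal = regressors @ beta
        if intrinsic_sd > 0:
            signal = signal + latents[info["network"]]
        data[sel] += signal
    return VolumeSeries(data=data, affine=truth.affine, tr_s=truth.tr_s,
                        mask=truth.mask, subject_id=subject_id, n_discarded=2)


def generate_bold(regressors: np.ndarray, truth: GroundTruth,
                  n_subjects: int, noise_sd: float = 3.0,
                  smooth_fwhm_mm: float = 6.0,
                  between_subject_sd: float = 0.2, seed: int = 0,
                  intrinsic_sd: float = 2.0, dtype=np.float32):
    """Yield ``n_subjects`` VolumeSeries; subject i uses child seed i of the
    master seed so any subject is reproducible in isolation."""
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    for i, child in enumerate(children):
        yield generate_subject_bold(regressors, truth, child,
                                    noise_sd=noise_sd,
                                    smooth_fwhm_mm=smooth_fwhm_mm,
                                    between_subject_sd=between_subject_sd,
                                    subject_id=f"sub{i + 1:02d}",
                                    intrinsic_sd=intrinsic_sd, dtype=dtype)


# ---------------------------------------------------------------------------
# Planted-partition graphs

def planted_partition_graph(n_nodes: int, n_modules: int, p_in: float,
                            p_out: float, weight_dist=None, seed: int = 0,
                            sizes: list[int] | None = None,
                            weight_dist_out=None,
                            ) -> tuple[nx.Graph, np.ndarray]:
    """Undirected weighted graph with planted communities.

    Within-module node pairs are joined with probability ``p_in``, between-
    module pairs with ``p_out`` (requires p_in > p_out). Edge weights come
    from ``weight_dist(rng, size)`` (default uniform on [0.5, 1]) for
    within-module edges and ``weight_dist_out`` (default uniform on
    [0.15, 0.45]) for between-module edges — these graphs emulate thresholded
    correlation networks, where links inside a community carry the larger
    correlations. Pass the same callable for both to get unweighted-style
    planted partitions.
    """
    if not p_in > p_out:
        raise ValidationError("need p_in > p_out")
    if sizes is None:
        base = n_nodes // n_modules
        sizes = [base + (1 if i < n_nodes % n_modules else 0)
                 for i in range(n_modules)]
    if sum(sizes) != n_nodes or len(sizes) != n_modules:
        raise ValidationError("sizes must partition the nodes into modules")
    if weight_dist is None:
        weight_dist = lambda rng, size: rng.uniform(0.5, 1.0, size)  # noqa: E731
    if weight_dist_out is None:
        weight_dist_out = lambda rng, size: rng.uniform(0.15, 0.45, size)  # noqa: E731
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_modules), sizes)
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            within = labels[i] == labels[j]
            if rng.random() < (p_in if within else p_out):
                dist = weight_dist if within else weight_dist_out
                g.add_edge(i, j, weight=float(dist(rng, 1)[0]))
    return g, labels
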