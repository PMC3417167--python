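"""End-to-end synthetic study: ratings -> designs -> GLMs -> group maps ->
overlap -> ROI summaries -> connectivity -> communities.

`build_session` turns a generated rating sample into the 14 regressors on the
acquisition grid (rater averaging, presentation-order concatenation, TR
down-sampling), assembles the original and mutually orthogonalized designs,
and reports the rating diagnostics. `run_recovery` generates a cohort of
synthetic subjects against those regressors and runs both first-level
strategies through second-level inference, FDR thresholding and cumulative
overlap maps, returning everything a recovery check needs. `run_network`
builds the permutation-thresholded connectivity graph and its map-equation
community partition from per-subject ROI time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design as design_mod
from . import glm as glm_mod
from . import group as group_mod
from . import network as network_mod
from . import roi as roi_mod
from . import synth
from .config import RunConfig
from .errors import ValidationError
from .ratings import (ALL_FEATURES, SOCIAL_FEATURES, NONSOCIAL_FEATURES,
                      FeatureTimecourse, average_raters, concatenate_clips,
                      downsample_to_tr, feature_correlation_matrix,
                      interrater_reliability, mean_abs_offdiagonal)


@dataclass
class Session:
    """Regressors and designs for one synthetic scanning session."""

    timecourses: list[FeatureTimecourse]
    X_orig: pd.DataFrame            # rating regressors (T x 14)
    X_orth: pd.DataFrame            # mutually orthogonalized regressors
    ortho_ledger: dict
    conv_orig: np.ndarray           # HRF-convolved originals (T x 14)
    conv_orth: np.ndarray
    nuisance: np.ndarray            # drift + intercept (T x K+1)
    diagnostics: dict
    presentation_order: list[str]
    cfg: RunConfig


def build_session(seed: int, cfg: RunConfig | None = None,
                  n_volumes: int = 768,
                  n_clips: int = synth.DEFAULT_N_CLIPS) -> Session:
    """Generate a rating sample and assemble the session regressors/designs."""
    cfg = cfg or RunConfig()
    ss = np.random.SeedSequence(seed)
    seed_ratings, seed_order = [int(s.generate_state(1)[0] % (2 ** 31))
                                for s in ss.spawn(2)]
    sample = synth.generate_ratings(n_clips=n_clips, seed=seed_ratings,
                                    rate_hz=cfg.rating_rate_hz)
    order_rng = np.random.default_rng(seed_order)
    order = [sample.clip_ids[i]
             for i in order_rng.permutation(len(sample.clip_ids))]

    averaged = {}
    for clip in sample.clip_ids:
        for feat in sample.features:
            averaged[(clip, feat)] = average_raters(
                sample.tracks_a[(clip, feat)], sample.tracks_b[(clip, feat)])
    concatenated = concatenate_clips(averaged, order, sample.features)

    timecourses = []
    for feat in sample.features:
        tc = downsample_to_tr(concatenated[feat], cfg.rating_rate_hz,
                              cfg.tr_s, feature=feat)
        if len(tc) < n_volumes:
            raise ValidationError(
                f"rated material covers only {len(tc)} volumes < {n_volumes}")
        timecourses.append(FeatureTimecourse(feat, tc.values[:n_volumes],
                                             cfg.tr_s,
                                             provenance="downsampled"))

    X_orig = pd.DataFrame({tc.feature: tc.values for tc in timecourses})
    X_orth, ledger = design_mod.orthogonalize_all(X_orig)

    def _convolve(X: pd.DataFrame) -> np.ndarray:
        cols = []
        for feat in X.columns:
            tc = FeatureTimecourse(feat, X[feat].to_numpy(), cfg.tr_s)
            cols.append(design_mod.hrf_convolve(tc, cfg.hrf_mode).values)
        return np.column_stack(cols)

    conv_orig = _convolve(X_orig)
    conv_orth = _convolve(X_orth)
    drift = design_mod.dct_highpass_basis(n_volumes, cfg.tr_s,
                                          cfg.highpass_cutoff_s)
    nuisance = np.column_stack([drift, np.ones(n_volumes)])

    # rating diagnostics on the 5-Hz concatenated tracks (Figure-2 analogues)
    a_cat = concatenate_clips(sample.tracks_a, order, sample.features)
    b_cat = concatenate_clips(sample.tracks_b, order, sample.features)
    per_feat_r, mean_r = interrater_reliability(a_cat, b_cat)
    mean_tracks = {f: (a_cat[f] + b_cat[f]) / 2.0 for f in sample.features}
    corr = feature_correlation_matrix(mean_tracks)
    diagnostics = {
        "interrater_r": per_feat_r,
        "interrater_mean_r": mean_r,
        "feature_corr": corr,
        "mean_abs_feature_r": mean_abs_offdiagonal(corr),
        "n_clips": n_clips,
        "n_volumes": n_volumes,
    }
    return Session(timecourses=timecourses, X_orig=X_orig, X_orth=X_orth,
                   ortho_ledger=ledger, conv_orig=conv_orig,
                   conv_orth=conv_orth, nuisance=nuisance,
                   diagnostics=diagnostics, presentation_order=order, cfg=cfg)


@dataclass
class RecoveryResult:
    session: Session
    truth: synth.GroundTruth
    rho_estimates: list[float]
    subject_betas: dict[str, np.ndarray]       # mode -> (S, F, V)
    group: dict[str, dict]                     # mode -> second-level results
    overlap: dict[str, np.ndarray]             # mode -> 3-D overlap counts
    roi_series: list[np.ndarray] = field(default_factory=list)
    roi_names: list[str] = field(default_factory=list)
    contrast_t: np.ndarray | None = None       # social vs non-social, flat

    def overlap_at(self, mode: str, region: str) -> int:
        return int(self.overlap[mode][self.truth.region_center_ijk(region)])


def run_recovery(seed: int, cfg: RunConfig | None = None,
                 n_subjects: int = 19, n_volumes: int = 768,
                 noise_sd: float = 3.0, between_subject_sd: float = 0.2,
                 smooth_fwhm_mm: float = 6.0,
                 modes: tuple[str, ...] = ("original", "orthogonalized"),
                 collect_roi_series: bool = True,
                 rho_sample_voxels: int = 2000,
                 session: Session | None = None) -> RecoveryResult:
    """Full first+second-level recovery run on default synthetic data.

    Data are always generated from the *original* convolved regressors (the
    planted truth); the two analysis modes differ only in the regressors
    fitted. The per-feature strategy shares one pooled AR(1) estimate per
    subject, taken from OLS residuals of the combined original design on a
    voxel subsample.
    """
    cfg = cfg or RunConfig()
    if session is None:
        session = build_session(seed, cfg, n_volumes=n_volumes)
    truth = synth.make_ground_truth()
    mask = truth.mask
    V = int(mask.sum())
    F = len(truth.features)
    mode_regs = {"original": session.conv_orig,
                 "orthogonalized": session.conv_orth}

    bold_seed = int(np.random.SeedSequence([seed, 7]).generate_state(1)[0]
                    % (2 ** 31))
    combined = np.column_stack([session.conv_orig, session.nuisance])
    # design-based de-biasing of the pooled residual lag-1 autocorrelation,
    # computed once per session (the residual-forming matrix is shared)
    rho_grid = np.linspace(-0.2, 0.95, 24)
    rho_curve = glm_mod.expected_residual_lag1(combined, rho_grid)

    betas = {m: np.empty((n_subjects, F, V)) for m in modes}
    rhos: list[float] = []
    roi_series: list[np.ndarray] = []
    roi_names = list(truth.regions)
    roi_specs = [roi_mod.RoiSpec(name=n, hemisphere="",
                                 center_mm=_ijk_to_mm(truth.affine,
                                                      truth.region_center_ijk(n)),
                                 radius_mm=cfg.roi_radius_conn_mm)
                 for n in roi_names]
    contrast_subjects = np.empty((n_subjects, V))

    soc_idx = [truth.features.index(f) for f in SOCIAL_FEATURES]
    non_idx = [truth.features.index(f) for f in NONSOCIAL_FEATURES]

    for s, series in enumerate(synth.generate_bold(
            session.conv_orig, truth, n_subjects, noise_sd=noise_sd,
            smooth_fwhm_mm=smooth_fwhm_mm,
            between_subject_sd=between_subject_sd, seed=bold_seed)):
        Y = series.flat()                                   # (T, V)
        sub_rng = np.random.default_rng([bold_seed, s, 11])
        cols = sub_rng.choice(V, size=min(rho_sample_voxels, V),
                              replace=False)
        resid = glm_mod.ols_residuals(Y[:, cols], combined)
        raw_r1 = glm_mod.estimate_ar1(resid.T).rho
        rho = float(np.interp(raw_r1, rho_curve, rho_grid))
        rhos.append(rho)
        Yw = glm_mod.ar1_whiten(Y, rho)
        Nw = glm_mod.ar1_whiten(session.nuisance, rho)
        for m in modes:
            stats_m = glm_mod.per_feature_stats_whitened(
                Yw, glm_mod.ar1_whiten(mode_regs[m], rho), Nw,
                compute_tp=False)
            betas[m][s] = stats_m["beta"]
        b = betas[modes[0]][s]
        contrast_subjects[s] = (b[soc_idx].mean(axis=0)
                                - b[non_idx].mean(axis=0))
        if collect_roi_series:
            roi_series.append(np.vstack(
                [roi_mod.mean_roi_timeseries(series, spec)
                 for spec in roi_specs]))

    group: dict[str, dict] = {}
    overlap: dict[str, np.ndarray] = {}
    for m in modes:
        per_feature = {}
        sig_flat_social = []
        for fi, feat in enumerate(truth.features):
            t, p, df = group_mod.one_sample_t_flat(betas[m][:, fi, :])
            p_star = group_mod.bh_threshold(p, cfg.fdr_q)
            sig = (p <= p_star) & (t > 0) if p_star > 0 else np.zeros(V, bool)
            per_feature[feat] = {"t": t, "p": p, "df": df, "p_star": p_star,
                                 "sig_pos": sig}
            if feat in SOCIAL_FEATURES:
                sig_flat_social.append(sig)
        counts = np.sum(sig_flat_social, axis=0)
        vol = np.zeros(mask.shape, dtype=int)
        vol[mask] = counts
        overlap[m] = vol
        group[m] = per_feature

    t_contrast, p_contrast, _ = group_mod.one_sample_t_flat(contrast_subjects)

    return RecoveryResult(session=session, truth=truth, rho_estimates=rhos,
                          subject_betas=betas, group=group, overlap=overlap,
                          roi_series=roi_series, roi_names=roi_names,
                          contrast_t=t_contrast)


def spatial_map_correlations(result: RecoveryResult) -> dict[str, dict]:
    """Per-feature spatial r between original and orthogonalized second-level
    t-maps, plus temporal r between the original and orthogonalized
    regressors (the orthogonalization report)."""
    out = {}
    for feat in result.truth.features:
        ta = result.group["original"][feat]["t"]
        tb = result.group["orthogonalized"][feat]["t"]
        xa = result.session.X_orig[feat].to_numpy()
        xb = result.session.X_orth[feat].to_numpy()
        out[feat] = {"spatial_r": float(np.corrcoef(ta, tb)[0, 1]),
                     "temporal_r": float(np.corrcoef(xa, xb)[0, 1])}
    return out


def hub_beta_summary(result: RecoveryResult, mode: str = "original",
                     radius_mm: float | None = None) -> pd.DataFrame:
    """Figure-4-style per-feature mean beta (t-based 95% CI) in a small
    sphere at the planted hub."""
    truth = result.truth
    cfg = result.session.cfg
    spec = roi_mod.RoiSpec(
        name="hub_psts", hemisphere="",
        center_mm=_ijk_to_mm(truth.affine, truth.region_center_ijk("hub_psts")),
        radius_mm=radius_mm or cfg.roi_radius_beta_mm)
    subject_maps = []
    for s in range(result.subject_betas[mode].shape[0]):
        maps = {}
        for fi, feat in enumerate(truth.features):
            vol = np.full(truth.mask.shape, np.nan)
            vol[truth.mask] = result.subject_betas[mode][s, fi]
            maps[feat] = glm_mod.StatMap(kind="beta", values=vol, feature=feat,
                                         level="first", affine=truth.affine,
                                         mask=truth.mask)
        subject_maps.append(maps)
    return roi_mod.beta_summary(subject_maps, spec, truth.features)


def run_network(roi_series_per_subject: list[np.ndarray],
                node_names: list[str], cfg: RunConfig | None = None,
                n_perm: int | None = None, seed: int = 0) -> dict:
    """Connectivity graph + communities from per-subject ROI time series."""
    cfg = cfg or RunConfig()
    n_perm = n_perm if n_perm is not None else cfg.n_permutations
    subject_r = [network_mod.subject_connectivity(s)
                 for s in roi_series_per_subject]
    mean_r = network_mod.group_mean_connectivity(subject_r)
    threshold, null_summary = network_mod.permutation_threshold(
        roi_series_per_subject, n_perm=n_perm,
        min_shift=cfg.min_shift_samples, seed=seed)
    graph = network_mod.build_graph(mean_r, threshold, node_names,
                                    subject_r=subject_r)
    g = graph.to_networkx()
    if g.number_of_edges() > 0:
        partition = network_mod.detect_communities(
            g, n_restarts=cfg.n_community_restarts, seed=seed + 1)
    else:
        partition = network_mod.CommunityPartition(
            {n: i for i, n in enumerate(node_names)}, 0.0,
            cfg.n_community_restarts, 1.0)
    return {"subject_r": subject_r, "mean_r": mean_r, "threshold": threshold,
            "null_summary": null_summary, "graph": graph,
            "partition": partition}


def _ijk_to_mm(affine: np.ndarray, ijk) -> np.ndarray:
    return affine[:3, :3] @ np.asarray(ijk, dtype=float) + affine[:3, 3]
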