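"""First-level GLM: AR(1) estimation, exact prewhitening vs dense GLS,
per-feature fast path, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import toeplitz

from socmap.design import build_design
from socmap.errors import (AlignmentError, CollinearityError,
                           CompletenessError, DegenerateDataError)
from socmap.glm import (Ar1Model, StatMap, ar1_whiten, estimate_ar1,
                        expected_residual_lag1, fit_glm, fit_per_feature,
                        glm_stats, ols_residuals, per_feature_stats,
                        social_vs_nonsocial_contrast)
from socmap.io import VolumeSeries
from socmap.ratings import FeatureTimecourse


def _series(data_2d, shape=(2, 2, 2), tr=2.112):
    """Wrap (T, V) data into a VolumeSeries over a fully-true mask."""
    T, V = data_2d.shape
    assert V == np.prod(shape)
    vol = data_2d.T.reshape(shape + (T,))
    return VolumeSeries(data=vol, affine=np.eye(4), tr_s=tr,
                        mask=np.ones(shape, dtype=bool))


def _design(X, names, tr=2.112):
    df = pd.DataFrame(X, columns=names)
    return build_design([FeatureTimecourse(n, df[n].to_numpy(), tr)
                         for n in names], tr_s=tr, hrf_mode="none",
                        highpass_cutoff_s=1e9)  # intercept only


class TestEstimateAr1:
    def test_white_noise_gives_near_zero(self, rng):
        resid = rng.standard_normal((500, 768))
        assert abs(estimate_ar1(resid).rho) < 0.05

    def test_recovers_planted_rho(self, rng):
        rho = 0.4
        innov = rng.standard_normal((500, 868))
        from scipy.signal import lfilter
        series = lfilter([1.0], [1.0, -rho], innov, axis=1)[:, 100:]
        assert estimate_ar1(series).rho == pytest.approx(rho, abs=0.05)

    def test_constant_residuals_are_degenerate(self):
        with pytest.raises(DegenerateDataError):
            estimate_ar1(np.ones((10, 50)))

    def test_design_correction_removes_projection_bias(self, rng):
        # residuals of a 40-column smooth design are biased low; the
        # design-corrected estimate recovers the truth
        rho = 0.4
        T = 768
        from scipy.signal import lfilter
        from socmap.design import dct_highpass_basis
        X = np.column_stack([dct_highpass_basis(T, 2.112, 128.0),
                             rng.standard_normal((T, 14)), np.ones(T)])
        innov = rng.standard_normal((800, T + 100))
        noise = lfilter([1.0], [1.0, -rho], innov, axis=1)[:, 100:]
        resid = ols_residuals(noise.T, X).T
        raw = estimate_ar1(resid).rho
        corrected = estimate_ar1(resid, design=X).rho
        assert raw < rho - 0.03          # the bias is real
        assert corrected == pytest.approx(rho, abs=0.03)


class TestGlsEquivalence:
    @pytest.mark.parametrize("T", [20, 50])
    def test_prewhitened_ols_equals_dense_gls(self, T, rng):
        rho = 0.4
        X = np.column_stack([rng.standard_normal((T, 3)), np.ones(T)])
        Y = rng.standard_normal((T, 7))
        res = glm_stats(Y, X, rho)
        # dense GLS oracle with the full AR(1) covariance
        Sigma = toeplitz(rho ** np.arange(T))
        Si = np.linalg.inv(Sigma)
        XtSiX_inv = np.linalg.inv(X.T @ Si @ X)
        beta_gls = XtSiX_inv @ X.T @ Si @ Y
        assert np.max(np.abs(res["beta"] - beta_gls)) < 1e-8
        resid = Y - X @ beta_gls
        df = T - X.shape[1]
        for v in range(Y.shape[1]):
            sigma2 = (resid[:, v] @ Si @ resid[:, v]) / df * (1 - rho ** 2)
            se = np.sqrt(sigma2 * np.diag(XtSiX_inv) / (1 - rho ** 2))
            assert np.allclose(res["se"][:, v], se, atol=1e-8)

    def test_whitening_matrix_inverts_ar1_covariance(self):
        # W'W must be proportional to Sigma^{-1}
        T, rho = 30, 0.6
        W = ar1_whiten(np.eye(T), rho)
        Sigma = toeplitz(rho ** np.arange(T))
        assert np.allclose(W.T @ W @ Sigma, (1 - rho ** 2) * np.eye(T),
                           atol=1e-10)


class TestFitGlm:
    def test_noiseless_data_recovers_exact_betas(self, rng):
        T, V = 60, 8
        X = np.column_stack([rng.standard_normal((T, 2))])
        dm = _design(X, ["a", "b"])
        b_true = rng.standard_normal((dm.matrix.shape[1], V))
        Y = dm.matrix.to_numpy() @ b_true
        series = _series(Y)
        out = fit_glm(series, dm, Ar1Model(0.3))
        assert np.allclose(out["a"]["beta"].in_mask(), b_true[0], atol=1e-10)
        assert np.allclose(out["b"]["beta"].in_mask(), b_true[1], atol=1e-10)

    def test_rho_zero_is_plain_ols(self, rng):
        T, V = 40, 8
        X = rng.standard_normal((T, 2))
        dm = _design(X, ["a", "b"])
        Y = rng.standard_normal((T, V))
        out = fit_glm(_series(Y), dm, Ar1Model(0.0))
        Xm = dm.matrix.to_numpy()
        beta_ols = np.linalg.lstsq(Xm, Y, rcond=None)[0]
        assert np.allclose(out["a"]["beta"].in_mask(), beta_ols[0], atol=1e-10)

    def test_beta_invariant_to_drift_contamination(self, rng):
        # adding any vector in the drift span to Y leaves feature betas alone
        T, V = 300, 8
        tcs = [FeatureTimecourse("a", rng.standard_normal(T), 2.112)]
        dm = build_design(tcs, tr_s=2.112, hrf_mode="none")
        drift = dm.matrix[dm.drift_names].to_numpy()
        Y = rng.standard_normal((T, V))
        contaminated = Y + drift @ rng.standard_normal((drift.shape[1], V)) * 5
        b0 = fit_glm(_series(Y), dm, Ar1Model(0.2))["a"]["beta"].in_mask()
        b1 = fit_glm(_series(contaminated), dm,
                     Ar1Model(0.2))["a"]["beta"].in_mask()
        assert np.allclose(b0, b1, atol=1e-8)

    def test_time_dimension_mismatch_raises(self, rng):
        dm = _design(rng.standard_normal((40, 2)), ["a", "b"])
        with pytest.raises(AlignmentError):
            fit_glm(_series(rng.standard_normal((39, 8))), dm, Ar1Model(0.0))

    def test_rank_deficient_design_raises(self, rng):
        x = rng.standard_normal(40)
        dm = _design(np.column_stack([x, x]), ["a", "b"])
        with pytest.raises(CollinearityError):
            fit_glm(_series(rng.standard_normal((40, 8))), dm, Ar1Model(0.0))


class TestPerFeaturePath:
    def test_matches_generic_single_feature_fits(self, rng):
        """The FWL fast path equals 14 independent full GLM fits."""
        T, V, F = 120, 16, 5
        feats = rng.standard_normal((T, F))
        from socmap.design import dct_highpass_basis
        nuis = np.column_stack([dct_highpass_basis(T, 2.112, 128.0),
                                np.ones(T)])
        Y = rng.standard_normal((T, V))
        rho = 0.35
        fast = per_feature_stats(Y, feats, nuis, rho)
        for f in range(F):
            full = glm_stats(Y, np.column_stack([feats[:, [f]], nuis]), rho)
            assert np.allclose(fast["beta"][f], full["beta"][0], atol=1e-10)
            assert np.allclose(fast["t"][f], full["t"][0], atol=1e-8)
            assert np.allclose(fast["p"][f], full["p"][0], atol=1e-10)
        assert fast["df"] == T - nuis.shape[1] - 1

    def test_volume_series_wrapper_agrees(self, rng):
        T = 90
        tcs = [FeatureTimecourse(f"f{i}", rng.standard_normal(T), 2.112)
               for i in range(3)]
        dm = build_design(tcs, tr_s=2.112, hrf_mode="none")
        Y = rng.standard_normal((T, 8))
        series = _series(Y)
        out = fit_per_feature(series, dm, Ar1Model(0.2))
        flat = per_feature_stats(Y, dm.features().to_numpy(),
                                 dm.nuisance().to_numpy(), 0.2)
        assert np.allclose(out["f1"]["beta"].in_mask(), flat["beta"][1])


class TestContrast:
    def _beta_maps(self, values_by_feature, mask):
        return {f: StatMap(kind="beta", values=v, feature=f, level="first",
                           affine=np.eye(4), mask=mask)
                for f, v in values_by_feature.items()}

    def test_equal_betas_give_zero_contrast(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        maps = self._beta_maps({f: np.full((2, 2, 2), 1.3)
                                for f in ("s1", "s2", "n1", "n2")}, mask)
        out = social_vs_nonsocial_contrast(maps, ("s1", "s2"), ("n1", "n2"))
        assert np.allclose(out.values[mask], 0.0)

    def test_unit_separation(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        vals = {"s1": np.ones((2, 2, 2)), "s2": np.ones((2, 2, 2)),
                "n1": np.zeros((2, 2, 2)), "n2": np.zeros((2, 2, 2))}
        out = social_vs_nonsocial_contrast(self._beta_maps(vals, mask),
                                           ("s1", "s2"), ("n1", "n2"))
        assert np.allclose(out.values[mask], 1.0)

    def test_random_betas_match_mean_difference_oracle(self, rng):
        mask = np.ones((3, 3, 3), dtype=bool)
        vals = {f: rng.standard_normal((3, 3, 3)) for f in "abcd"}
        out = social_vs_nonsocial_contrast(self._beta_maps(vals, mask),
                                           ("a", "b"), ("c", "d"))
        expected = (vals["a"] + vals["b"]) / 2 - (vals["c"] + vals["d"]) / 2
        assert np.allclose(out.values[mask], expected[mask])

    def test_missing_feature_raises(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        maps = self._beta_maps({"s1": np.ones((2, 2, 2))}, mask)
        with pytest.raises(CompletenessError):
            social_vs_nonsocial_contrast(maps, ("s1",), ("n1",))
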