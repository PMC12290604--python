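import numpy as np
import pytest

import lamvaso as lv
from lamvaso.acquisition import Trial
from lamvaso.glm import build_design, fit_glm, gamma_hrf, highpass_basis, t_to_z


class TestGammaHRF:
    def test_moment_matching(self):
        hrf = gamma_hrf(6.0, 3.0, dt_s=0.1)
        shape = (6.0 / 3.0) ** 2
        scale = 3.0**2 / 6.0
        assert shape == pytest.approx(4.0)
        assert scale == pytest.approx(1.5)
        mean, sd = hrf.moments()
        assert mean == pytest.approx(6.0, abs=0.05)
        assert sd == pytest.approx(3.0, abs=0.05)

    def test_unit_area(self):
        hrf = gamma_hrf(6.0, 3.0, dt_s=0.05)
        assert hrf.values.sum() * hrf.dt_s == pytest.approx(1.0)
        assert np.all(hrf.values >= 0)

    def test_mode_at_4_5_seconds(self):
        hrf = gamma_hrf(6.0, 3.0, dt_s=0.01)
        assert hrf.t[np.argmax(hrf.values)] == pytest.approx(4.5, abs=0.02)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            gamma_hrf(0.0, 3.0)


class TestHighpassBasis:
    def test_column_count_formula(self):
        # 100 volumes at 3.14 s = 314 s; K = floor(2 * 314 * 0.01) = 6
        drift = highpass_basis(100, 3.14, 0.01)
        assert drift.shape == (100, 6)

    def test_zero_cutoff_no_columns(self):
        assert highpass_basis(50, 3.14, 0.0).shape == (50, 0)

    def test_columns_orthogonal(self):
        drift = highpass_basis(120, 3.14, 0.02)
        gram = drift.T @ drift
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-9


class TestBuildDesign:
    def test_single_trial_regressor_peaks_near_offset(self):
        hrf = gamma_hrf()
        trials = [Trial(30.0, 24.0, 0, 40.0)]
        X = build_design(trials, hrf, n_vols=60, dt_s=3.14, cutoff_hz=0.0)
        reg = X.matrix[:, 0]
        t_peak = 3.14 * np.argmax(reg)
        assert 54.0 - 5.0 < t_peak < 54.0 + 8.0  # near trial offset at 54 s

    def test_zero_regressor_rejected(self):
        hrf = gamma_hrf()
        trials = [Trial(1e5, 2.0, 0, 10.0)]  # far beyond the run
        with pytest.raises(ValueError):
            build_design(trials, hrf, n_vols=50, dt_s=3.14)

    def test_short_duration_regressors_scale_linearly(self):
        hrf = gamma_hrf()
        mk = lambda d: build_design([Trial(30.0, d, 0, 20.0)], hrf, 40, 3.14,
                                    cutoff_hz=0.0).matrix[:, 0].max()
        assert mk(2.0) / mk(1.0) == pytest.approx(2.0, rel=0.15)

    def test_full_design_has_all_duration_columns(self, acq):
        design = lv.make_design(acq, n_runs=1, seed=0)
        hrf = gamma_hrf()
        n = int(np.ceil(design.run_duration_s[0] / acq.cycle_s))
        X = build_design(design.runs[0], hrf, n, acq.cycle_s, acq.block_s)
        stim_cols = [c for c in X.names if c.startswith("stim_")]
        assert len(stim_cols) == 5
        assert np.linalg.matrix_rank(X.matrix) == X.matrix.shape[1]


class TestFitGLM:
    @pytest.fixture()
    def design(self, acq):
        des = lv.make_design(acq, n_runs=1, seed=1)
        n = int(np.ceil(des.run_duration_s[0] / acq.cycle_s))
        return build_design(des.runs[0], gamma_hrf(), n, acq.cycle_s, acq.block_s)

    def test_noise_free_recovery_is_exact(self, design):
        w = np.array([1.5, -0.5, 2.0, 0.3, 1.0] + [0.0] * (design.matrix.shape[1] - 6) + [7.0])
        y = design.matrix @ w
        res = fit_glm(y[None], design)
        np.testing.assert_allclose(res.beta[0], w, atol=1e-8)

    def test_zero_residual_voxel_flagged(self, design):
        y = design.matrix @ np.ones(design.matrix.shape[1])
        res = fit_glm(y[None], design)
        _, z = res.contrast(design.contrast_for(1.0))
        assert np.isnan(z[0])

    def test_null_z_scores_are_standard_normal(self, design):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(6000, design.matrix.shape[0]))
        res = fit_glm(y, design)
        _, z = res.contrast(design.contrast_for(24.0))
        assert z.std() == pytest.approx(1.0, abs=0.1)
        assert abs(np.mean(np.abs(z) > 1.96) - 0.05) < 0.01

    def test_ols_matches_statsmodels_oracle(self, design):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        y = rng.normal(size=design.matrix.shape[0])
        res = fit_glm(y[None], design)
        ref = sm.OLS(y, design.matrix).fit()
        np.testing.assert_allclose(res.beta[0], ref.params, atol=1e-10)
        assert res.sigma2[0] == pytest.approx(ref.mse_resid, rel=1e-10)

    def test_summary_lists_regressors(self, design):
        rng = np.random.default_rng(5)
        res = fit_glm(rng.normal(size=(3, design.matrix.shape[0])), design)
        table = res.summary()
        assert list(table["regressor"]) == design.names


class TestTToZ:
    def test_symmetry_and_sign(self):
        z = t_to_z(np.array([-2.0, 0.0, 2.0]), df=30)
        assert z[1] == pytest.approx(0.0, abs=1e-12)
        assert z[0] == pytest.approx(-z[2])
        assert 0 < z[2] < 2.0  # t thicker-tailed than normal at low df

    def test_extreme_t_stays_finite(self):
        z = t_to_z(np.array([80.0]), df=200)
        assert np.isfinite(z[0]) and z[0] > 8


class TestCombineSessions:
    def test_single_session_identity(self):
        z = np.random.default_rng(6).normal(size=(4, 4))
        np.testing.assert_allclose(lv.combine_sessions([z]), z)

    def test_two_identical_maps_scale_sqrt2(self):
        z = np.random.default_rng(7).normal(size=(4, 4))
        np.testing.assert_allclose(lv.combine_sessions([z, z]), z * np.sqrt(2))

    def test_null_maps_stay_standard_normal(self):
        rng = np.random.default_rng(8)
        maps = [rng.normal(size=100_000) for _ in range(4)]
        combined = lv.combine_sessions(maps)
        assert combined.std() == pytest.approx(1.0, abs=0.02)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lv.combine_sessions([np.zeros((2, 2)), np.zeros((3, 3))])


class TestLayerProfile:
    def test_depth_map_profile_recovers_bin_centers(self):
        rng = np.random.default_rng(9)
        depth = rng.uniform(size=(20, 20, 5))
        layers = np.floor(depth * 11).astype(int) + 1
        layers = np.clip(layers, 1, 11)
        prof = lv.layer_profile(depth, layers, n_layers=11)
        centers = (np.arange(11) + 0.5) / 11
        np.testing.assert_allclose(prof, centers, atol=0.02)

    def test_constant_map_flat_profile(self):
        layers = np.ones((5, 5, 5), dtype=int)
        prof = lv.layer_profile(np.full((5, 5, 5), 3.0), layers, n_layers=2)
        assert prof[0] == 3.0 and np.isnan(prof[1])

    def test_minmax_examples(self):
        np.testing.assert_allclose(lv.minmax_normalise([2.0, 4.0, 6.0]),
                                   [0.0, 0.5, 1.0])
        p = np.array([1.0, 3.0, 2.0])
        np.testing.assert_allclose(lv.minmax_normalise(5 * p - 2),
                                   lv.minmax_normalise(p))
        with pytest.raises(ValueError):
            lv.minmax_normalise([1.0, 1.0])


def test_cbv_glm_profile_peaks_mid_depth(participant):
    """Noise-free 24 s CBV activation (middle-layer dominant by construction)
    produces a GLM layer profile with its maximum at mid depth."""
    acq = participant.acq
    run = participant.runs[0]
    vaso_native = lv.boco(run.nulled, run.bold)
    trials = participant.design.runs[0]
    X = build_design(trials, gamma_hrf(), vaso_native.n_volumes,
                     vaso_native.dt_s, vaso_native.t0_s)
    res = fit_glm(-vaso_native.data, X)  # invert: CBV increase -> positive
    beta, z = res.contrast(X.contrast_for(24.0))
    depth = lv.depth_map(participant.geometry.volume, "equivolume")
    layers = lv.bin_layers(depth, 11)
    prof = lv.layer_profile(beta, layers, n_layers=11)
    assert np.isfinite(prof).all()
    assert 3 <= np.argmax(prof) <= 7  # middle bins
    norm = lv.minmax_normalise(prof)
    assert norm.min() == 0.0 and norm.max() == 1.0
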