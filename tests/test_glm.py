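import numpy as np
import pytest

import boldretest as bt
from boldretest.design import DesignMatrix, PipelineSpec, build_design, contrast_vector
from boldretest.glm import (
    VoxelwiseGLM,
    estimate_global_ar1,
    expected_residual_ar1,
    fit_voxelwise,
    prewhiten,
)
from boldretest.phantom import _session_state, _stationary_ar1
from boldretest.runner import _fit_run


@pytest.fixture(scope="module")
def design(schedule):
    motion = np.cumsum(np.random.default_rng(3).normal(0, 0.05, (378, 6)), axis=0)
    return build_design(schedule, PipelineSpec.from_name("default"), motion, 378, 2.0)


class TestEstimateGlobalAr1:
    def test_white_noise_estimates_near_zero(self, rng):
        resid = rng.standard_normal((378, 5000))
        assert abs(estimate_global_ar1(resid)) < 0.01

    def test_recovers_injected_ar1_through_the_design(self, design, rng):
        """With the design-projection bias correction, pooled rho over OLS
        residuals recovers the injected rho = 0.3 with bias < 0.05."""
        X = design.values
        noise = _stationary_ar1(rng, 0.3, 1.0, (378, 4000))
        resid = noise - X @ np.linalg.lstsq(X, noise, rcond=None)[0]
        rho = estimate_global_ar1(resid, design=X)
        assert abs(rho - 0.3) < 0.05
        # the raw residual autocorrelation is visibly attenuated, hence the need
        assert estimate_global_ar1(resid) < rho - 0.03

    def test_expected_residual_ar1_matches_brute_force(self, design):
        X = design.values[:, :10]
        n = X.shape[0]
        M = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
        L = np.zeros((n, n))
        idx = np.arange(n - 1)
        L[idx, idx + 1] = L[idx + 1, idx] = 0.5
        for rho in (0.0, 0.4, -0.25):
            S = rho ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
            B = M @ S @ M
            brute = np.trace(L @ B) / np.trace(B)
            assert expected_residual_ar1(rho, X) == pytest.approx(brute, abs=1e-10)

    def test_guards(self):
        with pytest.raises(ValueError, match="three time points"):
            estimate_global_ar1(np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="constant"):
            estimate_global_ar1(np.full(20, 3.0))


class TestPrewhiten:
    def test_rho_zero_is_identity(self, rng):
        X = rng.normal(size=(30, 3))
        Y = rng.normal(size=(30, 2))
        Xw, Yw = prewhiten(X, Y, 0.0)
        assert Xw is X and Yw is Y

    def test_whitening_at_true_rho_removes_autocorrelation(self, rng):
        noise = _stationary_ar1(rng, 0.5, 1.0, (500, 2000))
        _, white = prewhiten(np.ones((500, 1)), noise, 0.5)
        assert abs(estimate_global_ar1(white)) < 0.01

    def test_sequential_opposite_rhos_do_not_cancel(self):
        y = np.array([[1.0], [2.0], [0.5]])
        _, once = prewhiten(np.ones((3, 1)), y, 0.4)
        _, twice = prewhiten(np.ones((3, 1)), once, -0.4)
        assert not np.allclose(twice, y)

    def test_rho_bound(self):
        with pytest.raises(ValueError):
            prewhiten(np.ones((3, 1)), np.ones((3, 1)), 1.0)


class TestFitVoxelwise:
    def test_noise_free_phantom_recovers_injected_contrast_exactly(
        self, small_geometry, schedule, clean_config
    ):
        import dataclasses

        config = dataclasses.replace(clean_config, sigma2_noise=0.0, seed=42)
        run = bt.simulate_session(small_geometry, schedule, config, 1, 2)
        fit = _fit_run(
            run, small_geometry, schedule, PipelineSpec.from_name("default"), 128.0
        )
        state = _session_state(config, 1, 2)
        injected = state["amplitude"] - config.shape_response_scale * config.amplitude_mean
        vis = np.flatnonzero(
            small_geometry.visual_mask.ravel()[small_geometry.brain_mask.ravel()]
        )
        assert np.allclose(fit.contrast_value[vis], injected, atol=1e-8)

    def test_duplicate_column_raises_rank_error(self, design):
        frame = design.frame.copy()
        frame["shapes_copy"] = frame["shapes"]
        groups = dict(design.column_groups, shapes_copy="task-canonical")
        dupe = DesignMatrix(frame, groups, design.tr_seconds, design.highpass_cutoff)
        data = np.random.default_rng(0).normal(size=(378, 4))
        with pytest.raises(ValueError, match="collinear"):
            fit_voxelwise(dupe, data)

    def test_gls_equals_ols_when_whitening_disabled_on_white_noise(self, design, rng):
        """At rho = 0 the whitening transform is the identity, so the GLS refit
        reproduces the OLS solution bit for bit."""
        Y = rng.normal(size=(378, 5))
        model = VoxelwiseGLM(Y, design)
        ols = model.fit(prewhiten_data=False)
        X = design.values
        betas = np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.array_equal(ols.betas, betas)
        assert ols.rho_hat == 0.0

    def test_residuals_orthogonal_to_whitened_design(self, clean_fit):
        X = clean_fit.whitened_design
        e = clean_fit.residuals
        cross = np.abs(X.T @ e).max()
        assert cross / (np.linalg.norm(X) * np.linalg.norm(e)) < 1e-8

    def test_df_error_is_volumes_minus_rank(self, clean_fit):
        assert clean_fit.df_error == 378 - clean_fit.whitened_design.shape[1]

    def test_lower_noise_gives_larger_in_roi_t(self, small_geometry, schedule):
        import dataclasses

        medians = []
        vis = np.flatnonzero(
            small_geometry.visual_mask.ravel()[small_geometry.brain_mask.ravel()]
        )
        for sigma2 in (1.0, 0.25):
            config = bt.SimulationConfig(
                n_subjects=2,
                physio_amplitude=0.0,
                hrf_latency_sd=0.0,
                hrf_latency_session_sd=0.0,
                hrf_dispersion_sd=0.0,
                hrf_dispersion_session_sd=0.0,
                sigma2_noise=sigma2,
                seed=5,
            )
            run = bt.simulate_session(small_geometry, schedule, config, 0, 1)
            fit = _fit_run(
                run, small_geometry, schedule, PipelineSpec.from_name("default"), 128.0
            )
            medians.append(np.median(np.abs(fit.t_value[vis])))
        assert medians[1] > medians[0]

    def test_matches_statsmodels_ols_for_single_voxel(self, design, rng):
        sm = pytest.importorskip("statsmodels.api")
        y = rng.normal(size=378)
        fit = fit_voxelwise(design, y[:, None], prewhiten_data=False)
        ref = sm.OLS(y, design.values).fit()
        assert np.allclose(fit.betas[:, 0], ref.params, atol=1e-10)
        assert fit.sigma2[0] == pytest.approx(ref.mse_resid)

    def test_contrast_weight_length_checked(self, clean_fit):
        with pytest.raises(ValueError, match="contrast length"):
            clean_fit.contrast(np.ones(3))

    def test_summary_mentions_key_quantities(self, clean_fit):
        text = clean_fit.summary()
        assert "AR(1)" in text and "error df" in text


class TestPipelineDirection:
    def test_mcompcor_removes_confound_variance_and_restores_rho(
        self, small_geometry, schedule
    ):
        """With the physiological confound active, the mCompCor pipeline
        removes its variance from the residuals and the pooled AR(1)
        estimate returns to the noise value (the confound's high-frequency
        band otherwise dilutes it)."""
        from boldretest.runner import _mcompcor_for_run

        config = bt.SimulationConfig(n_subjects=2, seed=9)
        sigma2, rho = {}, {}
        for subject in (0, 1):
            run = bt.simulate_session(small_geometry, schedule, config, subject, 1)
            mc = _mcompcor_for_run(run, small_geometry)
            for name in ("default", "mcompcor"):
                fit = _fit_run(
                    run,
                    small_geometry,
                    schedule,
                    PipelineSpec.from_name(name),
                    128.0,
                    mc if name == "mcompcor" else None,
                )
                sigma2.setdefault(name, []).append(np.median(fit.sigma2))
                rho.setdefault(name, []).append(fit.rho_hat)
        assert np.mean(sigma2["mcompcor"]) < 0.9 * np.mean(sigma2["default"])
        assert abs(np.mean(rho["mcompcor"]) - config.ar1_rho) < 0.05
        assert np.mean(rho["default"]) < np.mean(rho["mcompcor"])
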