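import numpy as np
import pandas as pd
import pytest

from boldretest.design import (
    HrfParams,
    PipelineSpec,
    build_design,
    canonical_hrf,
    condition_regressor,
    contrast_vector,
    dct_drift_basis,
    hrf_derivatives,
)
from boldretest.design import _double_gamma


class TestCanonicalHrf:
    def test_peak_location_on_dense_grid(self):
        params = HrfParams(dt=0.01)
        h = canonical_hrf(params)
        t_peak = np.argmax(h) * params.dt
        assert 4.5 <= t_peak <= 5.5
        assert h.max() == pytest.approx(1.0)

    def test_late_tail_below_one_percent_of_peak(self):
        params = HrfParams(dt=0.01, kernel_length=32.01)
        h = canonical_hrf(params)
        assert abs(h[-1]) < 0.01

    def test_zero_undershoot_is_a_positive_gamma_density(self):
        h = canonical_hrf(HrfParams(undershoot_ratio=0.0, dt=0.05))
        assert np.all(h[1:] > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HrfParams(dt=0.0)
        with pytest.raises(ValueError):
            HrfParams(peak_delay=-1.0)

    def test_matches_spm_reference_shape(self):
        """Cross-check against nilearn's SPM HRF (independent implementation)."""
        nilearn_hrf = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        ours = canonical_hrf(HrfParams(dt=0.1))
        ref = nilearn_hrf.spm_hrf(2.0, oversampling=20.0, time_length=32.0)
        n = min(len(ours), len(ref))
        r = np.corrcoef(ours[:n], ref[:n])[0, 1]
        assert r > 0.999


class TestHrfDerivatives:
    def test_temporal_derivative_integrates_to_zero(self):
        params = HrfParams(dt=0.01, kernel_length=40.0)
        temporal, _ = hrf_derivatives(params)
        canon = canonical_hrf(params)
        mass = np.sum(np.abs(canon)) * params.dt
        assert abs(np.sum(temporal) * params.dt) < 1e-3 * mass

    def test_finite_difference_converges_to_analytic_derivative(self):
        params = HrfParams(dt=0.01)
        temporal, _ = hrf_derivatives(params, delta_t=1e-5)
        t = np.arange(0.0, params.kernel_length, params.dt)
        dense = _double_gamma(t, params)
        analytic = np.gradient(dense, params.dt) / dense.max()
        interior = slice(10, -10)
        assert np.allclose(temporal[interior], analytic[interior], atol=5e-3)

    def test_zero_step_rejected(self):
        with pytest.raises(ValueError):
            hrf_derivatives(delta_t=0.0)
        with pytest.raises(ValueError):
            hrf_derivatives(delta_disp=0.0)


class TestDriftBasis:
    def test_column_count_at_study_defaults(self):
        basis = dct_drift_basis(378, 2.0, 128.0)
        assert basis.shape == (378, int(np.floor(2 * 378 * 2 / 128)) + 1)
        assert basis.shape[1] == 12

    def test_columns_orthonormal(self):
        basis = dct_drift_basis(200, 2.0, 100.0)
        gram = basis.T @ basis
        assert np.allclose(gram, np.eye(basis.shape[1]), atol=1e-10)

    def test_removes_slow_sinusoid_and_linear_trend(self):
        n, tr = 378, 2.0
        basis = dct_drift_basis(n, tr, 128.0)
        X = np.column_stack([basis, np.ones(n)])
        t = np.arange(n) * tr
        for slow in (np.sin(2 * np.pi * t / 400.0), t / t.max()):
            resid = slow - X @ np.linalg.lstsq(X, slow, rcond=None)[0]
            assert np.var(resid) < 0.01 * np.var(slow)

    def test_cutoff_guard(self):
        with pytest.raises(ValueError):
            dct_drift_basis(100, 2.0, cutoff_s=4.0)
        with pytest.raises(ValueError):
            dct_drift_basis(1, 2.0)


class TestConditionRegressor:
    def test_empty_boxcar_gives_zero_column(self):
        kernel = canonical_hrf(HrfParams(dt=0.125))
        reg = condition_regressor([], [], 100, 2.0, kernel, 0.125)
        assert np.all(reg == 0)

    def test_convolution_linearity_over_merged_schedules(self):
        kernel = canonical_hrf(HrfParams(dt=0.125))
        a = condition_regressor([10.0], [12.0], 120, 2.0, kernel, 0.125)
        b = condition_regressor([100.0], [6.0], 120, 2.0, kernel, 0.125)
        both = condition_regressor([10.0, 100.0], [12.0, 6.0], 120, 2.0, kernel, 0.125)
        assert np.allclose(both, a + b, atol=1e-12)

    def test_microtime_agrees_with_tr_grid_convolution(self):
        """Oversampled convolution matches the package's own direct TR-grid
        convolution for block regressors. The comparison's residual is
        dominated by the TR-grid path's left-rule Riemann error, about
        (TR/2) * |h(a) - h(b)| at the block edges, so the bound is 2% of the
        plateau plus that quadrature term."""
        n, tr = 120, 2.0
        fine = condition_regressor(
            [20.0], [12.0], n, tr, canonical_hrf(HrfParams(dt=0.125)), 0.125
        )
        coarse = condition_regressor(
            [20.0], [12.0], n, tr, canonical_hrf(HrfParams(dt=tr)), tr
        )
        quadrature = tr / 2.0 * np.max(np.abs(np.diff(canonical_hrf(HrfParams(dt=tr)))))
        assert np.max(np.abs(fine - coarse)) < 0.02 * fine.max() + quadrature


class TestPipelineSpec:
    def test_named_pipelines(self):
        assert not PipelineSpec.from_name("default").use_derivatives
        flex = PipelineSpec.from_name("flexhrf")
        assert flex.use_derivatives and flex.event_model == "mixed-block-event"
        combined = PipelineSpec.from_name("combined")
        assert combined.use_derivatives and combined.use_mcompcor

    def test_invariant_enforced(self):
        with pytest.raises(ValueError):
            PipelineSpec("bad", use_derivatives=True, event_model="block")
        with pytest.raises(ValueError):
            PipelineSpec.from_name("nope")


class TestBuildDesign:
    @pytest.fixture()
    def motion(self):
        return np.cumsum(np.random.default_rng(0).normal(0, 0.05, (378, 6)), axis=0)

    def test_default_pipeline_column_structure(self, schedule, motion):
        design = build_design(
            schedule, PipelineSpec.from_name("default"), motion, 378, 2.0
        )
        assert len(design.columns_in_group("task-canonical")) == 5
        assert len(design.columns_in_group("motion")) == 6
        assert len(design.columns_in_group("drift")) == 12
        assert len(design.columns_in_group("intercept")) == 1
        assert design.columns_in_group("mcompcor") == []
        assert design.values.shape == (378, 24)

    def test_flexhrf_has_three_bases_per_condition(self, schedule, motion):
        design = build_design(
            schedule, PipelineSpec.from_name("flexhrf"), motion, 378, 2.0
        )
        assert len(design.columns_in_group("task-canonical")) == 5
        assert len(design.columns_in_group("task-temporal-derivative")) == 5
        assert len(design.columns_in_group("task-dispersion-derivative")) == 5

    def test_mcompcor_column_requirements(self, schedule, motion):
        series = np.sin(np.arange(378) / 10.0)
        design = build_design(
            schedule,
            PipelineSpec.from_name("mcompcor"),
            motion,
            378,
            2.0,
            mcompcor_series=series,
        )
        assert design.columns_in_group("mcompcor") == ["mcompcor"]
        with pytest.raises(ValueError, match="requires an mCompCor"):
            build_design(schedule, PipelineSpec.from_name("mcompcor"), motion, 378, 2.0)
        with pytest.raises(ValueError, match="does not accept"):
            build_design(
                schedule,
                PipelineSpec.from_name("default"),
                motion,
                378,
                2.0,
                mcompcor_series=series,
            )

    def test_empty_schedule_rejected(self, motion):
        empty = pd.DataFrame(columns=["onset", "duration", "trial_type"])
        with pytest.raises(ValueError, match="empty"):
            build_design(empty, PipelineSpec.from_name("default"), motion, 378, 2.0)


class TestContrastVector:
    @pytest.fixture()
    def design(self, schedule):
        motion = np.cumsum(np.random.default_rng(0).normal(0, 0.05, (378, 6)), axis=0)
        return build_design(schedule, PipelineSpec.from_name("flexhrf"), motion, 378, 2.0)

    def test_weights_sum_to_zero_with_expected_pattern(self, design):
        weights = contrast_vector(design)
        assert weights.sum() == pytest.approx(0.0)
        assert np.sum(weights == 0.25) == 4
        assert np.sum(weights == -1.0) == 1
        assert np.sum(weights == 0.0) == len(weights) - 5

    def test_derivative_columns_weighted_zero(self, design):
        weights = pd.Series(contrast_vector(design), index=design.labels)
        for group in ("task-temporal-derivative", "task-dispersion-derivative"):
            assert (weights[design.columns_in_group(group)] == 0).all()

    def test_lookup_is_label_based_not_positional(self, design):
        permuted = design.frame[list(design.frame.columns)[::-1]]
        from boldretest.design import DesignMatrix

        design_perm = DesignMatrix(
            frame=permuted,
            column_groups=design.column_groups,
            tr_seconds=design.tr_seconds,
            highpass_cutoff=design.highpass_cutoff,
        )
        w = pd.Series(contrast_vector(design), index=design.labels)
        w_perm = pd.Series(contrast_vector(design_perm), index=design_perm.labels)
        assert (w.sort_index() == w_perm.sort_index()).all()

    def test_unknown_contrast_rejected(self, design):
        with pytest.raises(ValueError, match="unknown contrast"):
            contrast_vector(design, "faces_minus_houses")
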