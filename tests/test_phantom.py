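import dataclasses

import numpy as np
import pytest

import boldretest as bt
from boldretest.glm import estimate_global_ar1
from boldretest.phantom import (
    EMOTIONS,
    GroundTruth,
    _session_state,
    default_geometry,
    make_paradigm,
    simulate_cohort,
    simulate_session,
)
from boldretest.reliability import icc_from_matrix


class TestParadigm:
    def test_block_counts_and_conditions(self):
        schedule = make_paradigm(0)
        frame = schedule.frame
        assert len(frame) == 18
        emotions = frame[frame.trial_type.isin(EMOTIONS)]
        assert len(emotions) == 12
        assert emotions.trial_type.nunique() == 4
        assert (emotions.n_stimuli == 12).all()
        shapes = frame[frame.trial_type == "shapes"]
        assert len(shapes) == 6 and (shapes.n_stimuli == 6).all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 17, 99])
    def test_no_two_consecutive_blocks_share_a_condition(self, seed):
        types = list(make_paradigm(seed).frame.trial_type)
        assert all(a != b for a, b in zip(types, types[1:]))

    def test_same_seed_reproduces_schedule(self):
        a = make_paradigm(5).frame
        b = make_paradigm(5).frame
        assert a.equals(b)

    def test_schedule_fits_in_run(self):
        schedule = make_paradigm(3, n_volumes=378, tr=2.0)
        assert schedule.span <= 378 * 2.0

    def test_identity_control_flag_adds_blocks(self):
        schedule = make_paradigm(0, include_identity_control=True)
        assert (schedule.frame.trial_type == "identity").sum() == 3

    def test_stimulus_events_are_contiguous_one_second_movies(self):
        events = make_paradigm(0).stimulus_events()
        assert (events.duration == 1.0).all()
        assert len(events) == 12 * 12 + 6 * 6


class TestGeometry:
    def test_regions_disjoint_and_inside_brain(self):
        g = default_geometry()
        labels = g.region_labels
        assert set(np.unique(labels)) <= {0, 1, 2, 3, 4, 5}
        assert np.all(g.brain_mask == (labels > 0))
        assert g.visual_mask.sum() > 50
        assert g.amygdala_mask.sum() >= 8
        assert g.wm_csf_mask.sum() > 0
        assert g.highvar_mask.sum() > 0

    def test_invalid_geometry_rejected(self):
        g = default_geometry()
        bad_highvar = np.ones(g.shape, dtype=bool)  # extends outside the brain
        with pytest.raises(ValueError):
            dataclasses.replace(g, highvar_mask=bad_highvar)


class TestSimulateSession:
    def test_deterministic_given_seed_and_identity(
        self, small_geometry, schedule, clean_config
    ):
        a = simulate_session(small_geometry, schedule, clean_config, 2, 1)
        b = simulate_session(small_geometry, schedule, clean_config, 2, 1)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.motion, b.motion)
        c = simulate_session(small_geometry, schedule, clean_config, 2, 2)
        assert not np.array_equal(a.data, c.data)

    def test_all_sources_off_gives_constant_baseline(self, small_geometry, schedule):
        config = bt.SimulationConfig(
            n_subjects=2, sigma2_noise=0.0, physio_amplitude=0.0, amplitude_mean=0.0,
            seed=0,
        )
        run = simulate_session(small_geometry, schedule, config, 0, 1)
        brain = small_geometry.brain_mask
        assert np.all(run.data[brain] == 100.0)
        assert np.all(run.data[~brain] == 0.0)

    def test_noise_autocorrelation_matches_ar1_parameter(self, schedule):
        """Pooled lag-1 autocorrelation over >= 10^4 voxel series ~ rho."""
        g = default_geometry()
        config = bt.SimulationConfig(
            n_subjects=5, amplitude_mean=0.0, physio_amplitude=0.0, ar1_rho=0.3,
            seed=21,
        )
        series = []
        for subject in range(5):
            run = simulate_session(g, schedule, config, subject, 1)
            series.append(run.timeseries(g.brain_mask) - 100.0)
        pooled = np.concatenate(series, axis=1)
        assert pooled.shape[1] >= 10000
        assert abs(estimate_global_ar1(pooled) - 0.3) < 0.01

    def test_zero_within_variance_repeats_amplitudes_across_sessions(self):
        config = bt.SimulationConfig(n_subjects=4, sigma2_within=0.0, seed=3)
        _, truth = simulate_cohort(config, default_geometry(shape=(8, 8, 6)))
        assert np.allclose(
            truth.subject_amplitudes[:, 0], truth.subject_amplitudes[:, 1]
        )

    def test_wm_csf_series_equals_confound_when_noise_free(
        self, small_geometry, schedule
    ):
        config = bt.SimulationConfig(
            n_subjects=2, sigma2_noise=0.0, amplitude_mean=0.0, seed=4
        )
        run = simulate_session(small_geometry, schedule, config, 0, 1)
        confound = _session_state(config, 0, 1)["confound"]
        wm_series = run.timeseries(small_geometry.wm_csf_mask)
        for v in range(0, wm_series.shape[1], 25):
            r = np.corrcoef(wm_series[:, v], confound)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_overlong_schedule_rejected(self, small_geometry, schedule):
        config = bt.SimulationConfig(n_subjects=2, n_volumes=100, seed=0)
        with pytest.raises(ValueError, match="truncated"):
            simulate_session(small_geometry, schedule, config, 0, 1)

    def test_mean_brain_series_has_no_trend_without_drift(
        self, small_geometry, schedule, clean_config
    ):
        run = simulate_session(small_geometry, schedule, clean_config, 1, 1)
        mean_series = run.timeseries(small_geometry.brain_mask).mean(axis=1)
        t = np.arange(len(mean_series))
        slope = np.polyfit(t, mean_series, 1)[0]
        resid_sd = np.std(mean_series - np.polyval(np.polyfit(t, mean_series, 1), t))
        se_slope = resid_sd / np.sqrt(np.sum((t - t.mean()) ** 2))
        assert abs(slope) < 3.0 * se_slope

    def test_smoothing_option_runs(self, small_geometry, schedule, clean_config):
        config = dataclasses.replace(clean_config, smoothing_fwhm_mm=6.0)
        run = simulate_session(small_geometry, schedule, config, 0, 1)
        assert run.data.shape == small_geometry.shape + (config.n_volumes,)


class TestSimulateCohort:
    def test_48_subjects_give_96_runs_with_two_sessions_each(self):
        config = bt.SimulationConfig(n_subjects=48, seed=0)
        cohort, truth = simulate_cohort(config, default_geometry(shape=(8, 8, 6)))
        assert len(cohort) == 96
        assert cohort.sessions == (1, 2)
        assert truth.subject_amplitudes.shape == (48, 2)
        assert truth.confound_series.shape == (48, 2, 378)

    def test_true_icc_edge_cases(self):
        g = default_geometry(shape=(8, 8, 6))
        _, truth0 = simulate_cohort(
            bt.SimulationConfig(n_subjects=2, sigma2_between=0.0, seed=0), g
        )
        assert truth0.true_icc_by_region == {"visual": 0.0, "amygdala": 0.0}
        _, truth_half = simulate_cohort(
            bt.SimulationConfig(
                n_subjects=2, sigma2_between=1.0, sigma2_within=1.0, seed=0
            ),
            g,
        )
        assert truth_half.true_icc_by_region["visual"] == pytest.approx(0.5)

    def test_ground_truth_validates_icc_range(self):
        with pytest.raises(ValueError):
            GroundTruth(
                true_icc_by_region={"visual": 1.5},
                subject_amplitudes=np.zeros((2, 2)),
                shape_amplitude=0.0,
                confound_series=np.zeros((2, 2, 10)),
                subject_hrf_params=None,
            )

    def test_amplitude_icc_converges_to_variance_ratio(self):
        """ICC(3,1) of the drawn amplitudes approaches s2_b/(s2_b+s2_w)."""
        estimates = []
        for rep in range(8):
            config = bt.SimulationConfig(n_subjects=100, seed=100 + rep)
            _, truth = simulate_cohort(config, default_geometry(shape=(6, 6, 4)))
            estimates.append(icc_from_matrix(truth.subject_amplitudes))
        assert abs(np.mean(estimates) - config.true_icc) < 0.05

    def test_ground_truth_round_trips_through_json(self):
        config = bt.SimulationConfig(n_subjects=2, seed=6)
        _, truth = simulate_cohort(config, default_geometry(shape=(6, 6, 4)))
        restored = GroundTruth.from_json(truth.to_json())
        assert restored.true_icc_by_region == truth.true_icc_by_region
        assert np.allclose(restored.subject_amplitudes, truth.subject_amplitudes)
        assert np.allclose(restored.confound_series, truth.confound_series)


class TestConfigValidation:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            bt.SimulationConfig(ar1_rho=1.0)
        with pytest.raises(ValueError):
            bt.SimulationConfig(sigma2_noise=-1.0)
        with pytest.raises(ValueError):
            bt.SimulationConfig(n_volumes=1)

    def test_config_round_trips_through_json(self):
        config = bt.SimulationConfig(n_subjects=5, seed=9, ar1_rho=0.25)
        assert bt.SimulationConfig.from_json(config.to_json()) == config
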