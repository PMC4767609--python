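import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from hierfdr import (
    FMRISimConfig,
    block_design,
    double_gamma_hrf,
    expected_bold,
    glm_pvalues,
    octant_partition,
    run_simulation_study,
    sim_a_config,
    sim_b_config,
    simulate_dataset,
    sphere_mask,
)
from hierfdr.fmri import _correlated_noise


class TestBlockDesign:
    def test_default_design_has_45_task_volumes(self):
        d = block_design(105, (16, 46, 76), 15)
        assert d.sum() == 45
        assert d[15] == 1 and d[14] == 0 and d[30] == 0 and d[29] == 1

    def test_degenerate_designs(self):
        np.testing.assert_array_equal(block_design(10, (1,), 10), np.ones(10))
        np.testing.assert_array_equal(block_design(10, (), 5), np.zeros(10))

    def test_overlap_and_overflow_rejected(self):
        with pytest.raises(ValueError):
            block_design(105, (16, 20), 15)
        with pytest.raises(ValueError):
            block_design(105, (100,), 15)


class TestHRF:
    def test_canonical_shape(self):
        t = np.arange(0, 32, 0.1)
        h = double_gamma_hrf(t)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)
        peak_time = t[np.argmax(h)]
        assert 5.0 <= peak_time <= 7.0
        # undershoot: a negative lobe after ~10 s
        assert h[t > 10].min() < 0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            double_gamma_hrf([1.0], peak_shape=-1)
        with pytest.raises(ValueError):
            double_gamma_hrf([-1.0])


class TestExpectedBold:
    def test_zero_design_gives_zero_signal(self):
        np.testing.assert_array_equal(expected_bold(np.zeros(50)), np.zeros(50))

    def test_causality_and_lag(self):
        d = block_design(105, (16,), 15)
        bold = expected_bold(d, tr=2.0)
        # no response before the block starts (volume 16, 0-based 15)
        assert np.all(bold[:15] == 0)
        # hemodynamic lag ~6 s = 3 volumes: the peak trails the onset
        assert np.argmax(bold) > 15 + 2
        assert bold.max() == pytest.approx(1.0)


class TestGeometry:
    def test_sphere_counts(self):
        assert sphere_mask((50, 50, 50), (25, 25, 25), 3).sum() == 123
        assert sphere_mask((9, 9, 9), (5, 5, 5), 0).sum() == 1

    def test_center_validation(self):
        with pytest.raises(ValueError):
            sphere_mask((10, 10, 10), (0, 5, 5), 2)

    def test_octants(self):
        lab = octant_partition((20, 20, 20))
        assert sorted(np.unique(lab)) == list(range(1, 9))
        assert np.all(np.bincount(lab.ravel())[1:] == 1000)
        assert lab[4, 4, 4] == 1      # voxel (5,5,5)
        assert lab[10, 10, 10] == 8   # voxel (11,11,11)
        with pytest.raises(ValueError):
            octant_partition((19, 20, 20))

    def test_scenario_a_sphere_within_one_family(self):
        cfg = sim_a_config()
        mask = sphere_mask(cfg.grid, cfg.center, cfg.radius)
        lab = octant_partition(cfg.grid)
        assert set(np.unique(lab[mask])) == {1}

    def test_scenario_b_sphere_touches_all_families(self):
        cfg = sim_b_config()
        mask = sphere_mask(cfg.grid, cfg.center, cfg.radius)
        lab = octant_partition(cfg.grid)
        assert set(np.unique(lab[mask])) == set(range(1, 9))


class TestSimulateDataset:
    def test_noiseless_equals_clean(self):
        cfg = sim_a_config(noise_sd=0.0)
        data, active = simulate_dataset(cfg)
        assert active.sum() == 123
        inactive_series = data[~active]
        np.testing.assert_allclose(inactive_series, cfg.baseline)
        assert data[active].max() > cfg.baseline

    def test_deterministic_under_seed(self):
        cfg = replace(sim_a_config(), seed=9)
        d1, _ = simulate_dataset(cfg)
        d2, _ = simulate_dataset(cfg)
        np.testing.assert_array_equal(d1, d2)

    def test_noise_lag1_autocorrelation(self, rng):
        x = _correlated_noise((8, 8, 8, 200), 0.4, 0.0, rng)
        flat = x.reshape(-1, 200)
        num = (flat[:, 1:] * flat[:, :-1]).sum()
        den = (flat[:, :-1] ** 2).sum()
        assert num / den == pytest.approx(0.4, abs=0.03)
        assert x.std() == pytest.approx(1.0, abs=0.05)

    def test_smoothed_noise_keeps_unit_interior_variance(self, rng):
        x = _correlated_noise((24, 24, 24, 20), 0.0, 2.0, rng)
        interior = x[8:16, 8:16, 8:16]
        assert interior.std() == pytest.approx(1.0, abs=0.08)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FMRISimConfig(ar_coefficient=1.2)
        with pytest.raises(ValueError):
            FMRISimConfig(onsets=(100,), duration=15, n_volumes=105)


class TestGLM:
    def test_overwhelming_signal_detected(self, rng):
        cfg = sim_a_config(grid=(6, 6, 6), center=(3, 3, 3), radius=0.0,
                          effect_amplitude=40.0, noise_sd=0.5,
                          spatial_fwhm=0.0)
        data, active = simulate_dataset(cfg, rng)
        p = glm_pvalues(data, cfg)
        assert p.shape == cfg.grid
        assert p[active].max() < 1e-6

    def test_noiseless_limit(self):
        cfg = sim_a_config(grid=(6, 6, 6), center=(3, 3, 3), radius=1.0,
                          noise_sd=0.0)
        data, active = simulate_dataset(cfg)
        p = glm_pvalues(data, cfg)
        assert np.all(p[active] == 0.0)
        assert np.all(p[~active] == 1.0)

    def test_null_pvalues_roughly_uniform(self, rng):
        """Prewhitened t-test calibration on pure autocorrelated noise."""
        cfg = sim_a_config(grid=(12, 12, 12), center=(6, 6, 6), radius=0.0,
                          spatial_fwhm=0.0)
        data, active = simulate_dataset(cfg, rng)
        p = glm_pvalues(data, cfg)[~active]
        assert stats.kstest(p, "uniform").statistic < 1.63 / np.sqrt(p.size)


class TestStudyHarness:
    def test_noiseless_study_is_error_free(self):
        cfg = sim_a_config(grid=(8, 8, 8), center=(3, 3, 3), radius=1.5,
                          noise_sd=0.0)
        reports = run_simulation_study(cfg, B=1, seed=0)
        n_active = int(sphere_mask(cfg.grid, cfg.center, cfg.radius).sum())
        for rep in reports.values():
            assert rep.gFDR == 0.0
            assert rep.gpower == 1.0
        assert n_active == 19

    def test_report_layout(self):
        cfg = sim_a_config(grid=(8, 8, 8), center=(3, 3, 3), radius=1.0,
                          noise_sd=0.0)
        reports = run_simulation_study(cfg, B=2, seed=4)
        assert set(reports) == {"ho", "lsu", "bog"}
        assert all(r.per_family_FDR.size == 8 and r.B == 2 for r in reports.values())
        assert reports["ho"].stage1_FWER is not None
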