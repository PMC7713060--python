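"""Generators: ground-truth laws of the simulator, ACF synthesis, spot images."""

import numpy as np
import pytest

from svfcs import (
    ObservationVolume,
    OneComponentParams,
    PRESETS,
    SimConfig,
    SpotImageConfig,
    TwoComponentParams,
    acf_one_component,
    default_lag_grid,
    diffusion_time,
    preset_params,
    simulate_sted_image,
    simulate_trace,
    synthesize_acf,
)


class TestPresets:
    def test_known_conditions_present(self):
        for name in ("egfp", "alpha_synuclein", "synapsin", "anti_goat_antibody"):
            assert name in PRESETS

    def test_egfp_is_single_component(self, vol):
        params = preset_params("egfp", vol, mode="on_pattern")
        assert isinstance(params, OneComponentParams)
        assert params.tau_D == pytest.approx(diffusion_time(85.0, vol.w0))

    def test_on_pattern_params_encode_bound_fraction(self, vol):
        params = preset_params("synapsin", vol, mode="on_pattern")
        assert isinstance(params, TwoComponentParams)
        assert params.bound_fraction == pytest.approx(0.30)
        assert params.tau_D1 < params.tau_D2


class TestSimulateTrace:
    def test_zero_particles_is_background_poisson(self):
        cfg = SimConfig(
            D_free=10.0, n_particles=0, background=4.0, dt=1e-4, duration=0.5, seed=7
        )
        res = simulate_trace(cfg)
        counts = res.trace.counts
        assert len(counts) == cfg.n_steps
        assert counts.mean() == pytest.approx(4.0, rel=0.1)
        assert counts.var() == pytest.approx(4.0, rel=0.2)  # Poisson: var = mean

    def test_immobile_particle_at_focus_constant_signal(self):
        vol = ObservationVolume.default()
        cfg = SimConfig(
            D_free=1e-6,
            n_particles=1,
            brightness=100.0,
            background=1.0,
            dt=1e-4,
            duration=0.05,
            vol=vol,
            seed=1,
            poisson_noise=False,
        )
        res = simulate_trace(cfg)
        # particle wanders negligibly: signal nearly constant
        assert res.trace.counts.std() / res.trace.counts.mean() < 0.05

    def test_bound_time_fraction_matches_stationary_distribution(self):
        r_fb, r_bf = 400.0, 600.0
        cfg = SimConfig(
            D_free=10.0,
            D_bound=2.0,
            r_fb=r_fb,
            r_bf=r_bf,
            n_particles=40,
            dt=1e-4,
            duration=2.0,
            seed=11,
        )
        res = simulate_trace(cfg)
        expected = r_fb / (r_fb + r_bf)
        n_eff = cfg.n_particles * cfg.n_steps
        # binomial error bound is generous: switching correlates samples
        tol = 10 * np.sqrt(expected * (1 - expected) / n_eff) + 0.01
        assert abs(res.bound_time_fraction - expected) < tol

    def test_msd_law_free_diffusion(self):
        # per-axis displacement variance over k steps = 2 D k dt
        D, dt = 15.0, 1e-4
        cfg = SimConfig(
            D_free=D,
            n_particles=60,
            dt=dt,
            duration=0.2,
            seed=3,
            record_positions=True,
        )
        res = simulate_trace(cfg)
        for k in (1, 4, 16):
            disp = res.positions[k:] - res.positions[:-k]  # unwrapped
            np.testing.assert_allclose(
                disp.var(axis=(0, 1)), 2 * D * k * dt, rtol=0.05
            )

    def test_reproducible_from_seed(self):
        cfg = dict(D_free=10.0, n_particles=10, dt=1e-4, duration=0.1)
        a = simulate_trace(SimConfig(**cfg, seed=5)).trace.counts
        b = simulate_trace(SimConfig(**cfg, seed=5)).trace.counts
        c = simulate_trace(SimConfig(**cfg, seed=6)).trace.counts
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_coarse_dt_rejected_for_fast_rates(self):
        with pytest.raises(ValueError, match="r\\*dt"):
            SimConfig(D_free=50.0, r_fb=5000.0, r_bf=5000.0, dt=1e-4, duration=1.0)

    def test_coarse_dt_rejected_for_fast_diffusion(self):
        with pytest.raises(ValueError, match="RMS"):
            SimConfig(D_free=500.0, dt=1e-3, duration=1.0)


class TestSynthesizeAcf:
    def test_noiseless_equals_model(self, vol):
        params = OneComponentParams(N=2.0, tau_D=3e-4)
        curve = synthesize_acf(params, vol, noise_fraction=0.0)[0]
        np.testing.assert_allclose(
            curve.values, acf_one_component(curve.lags, params, vol), rtol=1e-14
        )

    def test_ensemble_mean_is_unbiased(self, vol):
        params = OneComponentParams(N=2.0, tau_D=3e-4)
        curves = synthesize_acf(
            params, vol, noise_fraction=0.05, n_curves=1000, seed=42
        )
        values = np.vstack([c.values for c in curves])
        model = acf_one_component(curves[0].lags, params, vol)
        se = values.std(axis=0, ddof=1) / np.sqrt(len(curves))
        # check a few fixed lags at 3 standard errors
        for idx in (0, 30, 60, 90):
            assert abs(values[:, idx].mean() - model[idx]) < 3 * se[idx]

    def test_seed_determinism(self, vol):
        params = OneComponentParams(N=2.0, tau_D=3e-4)
        a = synthesize_acf(params, vol, n_curves=2, seed=9)
        b = synthesize_acf(params, vol, n_curves=2, seed=9)
        c = synthesize_acf(params, vol, n_curves=2, seed=10)
        np.testing.assert_array_equal(a[1].values, b[1].values)
        assert not np.array_equal(a[0].values, c[0].values)

    def test_two_component_grid(self, vol):
        params = TwoComponentParams(N1=0.8, N2=0.2, tau_D1=1e-4, tau_D2=1e-2)
        lags = default_lag_grid(1e-6, 0.5)
        curve = synthesize_acf(params, vol, noise_fraction=0.0, lags=lags)[0]
        assert curve.lags[0] == pytest.approx(1e-6)
        assert curve.values[0] == pytest.approx(vol.gamma, rel=0.02)


class TestSimulateStedImage:
    def test_zero_density_noise_only(self):
        cfg = SpotImageConfig(density=0.0, shape_px=(64, 64), seed=1)
        image, pos = simulate_sted_image(cfg)
        assert len(pos) == 0
        assert image.mean() == pytest.approx(cfg.background_counts, rel=0.2)

    def test_spot_count_poisson_at_density(self):
        # 15 per um^2 on a ~10x10 um field: expect ~1500 +- sqrt(1500)
        cfg = SpotImageConfig(
            density=15.0, pixel_size_um=0.02, shape_px=(500, 500), seed=2
        )
        _, pos = simulate_sted_image(cfg)
        expected = 15.0 * cfg.area_um2
        assert abs(len(pos) - expected) < 4 * np.sqrt(expected)

    def test_nearest_neighbor_distance_poisson_process(self):
        # for a 2D Poisson process, mean NN distance = 1/(2 sqrt(lambda))
        from scipy.spatial import cKDTree

        cfg = SpotImageConfig(
            density=15.0,
            pixel_size_um=0.02,
            shape_px=(500, 500),
            min_separation_um=0.0,
            seed=3,
        )
        _, pos = simulate_sted_image(cfg)
        d, _ = cKDTree(pos).query(pos, k=2)
        expected = 1.0 / (2.0 * np.sqrt(15.0))
        assert d[:, 1].mean() == pytest.approx(expected, rel=0.05)

    def test_min_separation_respected(self):
        from scipy.spatial import cKDTree

        cfg = SpotImageConfig(
            density=5.0,
            pixel_size_um=0.02,
            shape_px=(256, 256),
            min_separation_um=0.15,
            seed=4,
        )
        _, pos = simulate_sted_image(cfg)
        d, _ = cKDTree(pos).query(pos, k=2)
        assert d[:, 1].min() >= 0.15

    def test_infeasible_packing_raises(self):
        cfg = SpotImageConfig(
            density=100.0,
            pixel_size_um=0.02,
            shape_px=(128, 128),
            min_separation_um=0.5,
            seed=5,
        )
        with pytest.raises(RuntimeError, match="packing"):
            simulate_sted_image(cfg, max_attempts_per_spot=20)

    def test_psf_smaller_than_two_pixels_rejected(self):
        with pytest.raises(ValueError):
            SpotImageConfig(psf_fwhm_um=0.03, pixel_size_um=0.02)
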