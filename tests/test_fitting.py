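"""Curve fitting: self-consistency, calibration, model selection, exclusion."""

import numpy as np
import pytest

from svfcs import (
    IntensityTrace,
    ObservationVolume,
    OneComponentParams,
    TwoComponentParams,
    batch_analyze,
    calibrate_volume,
    exclude_aggregate_traces,
    fit_one_component,
    fit_two_component,
    preset_params,
    select_model,
    synthesize_acf,
)

REF_TAU_D = 6.00625e-5  # 310 nm waist at D = 400 um^2/s


class TestOneComponentFit:
    def test_noiseless_recovery_to_machine_precision(self, vol):
        params = OneComponentParams(N=1.0, tau_D=REF_TAU_D)
        curve = synthesize_acf(params, vol, noise_fraction=0.0)[0]
        fit = fit_one_component(curve, vol)
        assert fit.converged
        assert fit.tau_D1 == pytest.approx(REF_TAU_D, rel=1e-6)
        assert fit.N1 == pytest.approx(1.0, rel=1e-6)

    def test_derived_diffusion_coefficient(self, vol):
        params = OneComponentParams(N=1.0, tau_D=REF_TAU_D)
        curve = synthesize_acf(params, vol, noise_fraction=0.0)[0]
        fit = fit_one_component(curve, vol)
        assert fit.d_free == pytest.approx(400.0, rel=1e-6)

    def test_noisy_ensemble_recovery_egfp_regime(self, vol):
        params = preset_params("egfp", vol, mode="bulk")
        curves = synthesize_acf(
            params, vol, noise_fraction=0.02, n_curves=25, seed=77
        )
        d = np.array([fit_one_component(c, vol).d_free for c in curves])
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - 85.0) < 3 * se

    def test_reports_standard_errors(self, vol):
        params = OneComponentParams(N=2.0, tau_D=1e-4)
        curve = synthesize_acf(params, vol, noise_fraction=0.02, seed=1)[0]
        fit = fit_one_component(curve, vol)
        assert fit.stderr["tau_D"] > 0
        assert np.isfinite(fit.rss)

    def test_short_curve_rejected(self, vol):
        curve = synthesize_acf(
            OneComponentParams(N=1.0, tau_D=1e-4),
            vol,
            noise_fraction=0.0,
            lags=np.geomspace(1e-5, 1e-3, 5),
        )[0]
        with pytest.raises(ValueError):
            fit_one_component(curve, vol)


class TestTwoComponentFit:
    def test_noiseless_recovery_all_four_parameters(self, vol):
        truth = TwoComponentParams(
            N1=0.85, N2=0.15, tau_D1=REF_TAU_D, tau_D2=15 * REF_TAU_D
        )
        curve = synthesize_acf(truth, vol, noise_fraction=0.0)[0]
        fit = fit_two_component(curve, vol)
        assert fit.converged and "unresolved" not in fit.flags
        assert fit.N1 == pytest.approx(truth.N1, rel=1e-4)
        assert fit.N2 == pytest.approx(truth.N2, rel=1e-4)
        assert fit.tau_D1 == pytest.approx(truth.tau_D1, rel=1e-4)
        assert fit.tau_D2 == pytest.approx(truth.tau_D2, rel=1e-4)
        assert fit.bound_fraction == pytest.approx(0.15, rel=1e-4)

    def test_canonical_ordering_invariant(self, vol):
        params = preset_params("alpha_synuclein_on_sv", vol)
        curves = synthesize_acf(params, vol, noise_fraction=0.02, n_curves=10, seed=5)
        for curve in curves:
            fit = fit_two_component(curve, vol)
            assert fit.d_free > fit.d_bound

    def test_single_species_input_degenerates(self, vol):
        curve = synthesize_acf(
            OneComponentParams(N=1.0, tau_D=1e-4), vol, noise_fraction=0.0
        )[0]
        fit = fit_two_component(curve, vol)
        assert ("unresolved" in fit.flags) or min(fit.N1, fit.N2) < 0.01

    def test_objective_not_worse_than_one_component(self, vol):
        params = preset_params("synapsin", vol)
        curve = synthesize_acf(params, vol, noise_fraction=0.02, seed=8)[0]
        one = fit_one_component(curve, vol)
        two = fit_two_component(curve, vol)
        assert two.rss <= one.rss * (1 + 1e-9)


class TestCalibration:
    def test_reference_dye_beam_waist(self, vol):
        curve = synthesize_acf(
            OneComponentParams(N=1.0, tau_D=REF_TAU_D), vol, noise_fraction=0.0
        )[0]
        cal = calibrate_volume(curve, D_ref=400.0)
        assert cal.w0 == pytest.approx(0.310, abs=5e-4)
        assert cal.z0 == pytest.approx(5 * cal.w0)
        assert cal.gamma == 0.35

    def test_waist_scales_with_sqrt_d_ref(self, vol):
        curve = synthesize_acf(
            OneComponentParams(N=1.0, tau_D=REF_TAU_D), vol, noise_fraction=0.0
        )[0]
        w1 = calibrate_volume(curve, D_ref=400.0).w0
        w2 = calibrate_volume(curve, D_ref=800.0).w0
        assert w2 / w1 == pytest.approx(np.sqrt(2.0), rel=1e-9)

    def test_round_trip_within_one_percent(self):
        # synthesize at a volume, calibrate, recover the waist
        truth = ObservationVolume.default(w0=0.29)
        curve = synthesize_acf(
            OneComponentParams(N=1.5, tau_D=21e-5), truth, noise_fraction=0.0
        )[0]
        cal = calibrate_volume(curve, D_ref=0.29**2 / (4 * 21e-5))
        assert cal.w0 == pytest.approx(0.29, rel=0.01)

    def test_invalid_reference_rejected(self, vol):
        curve = synthesize_acf(
            OneComponentParams(N=1.0, tau_D=REF_TAU_D), vol, noise_fraction=0.0
        )[0]
        with pytest.raises(ValueError):
            calibrate_volume(curve, D_ref=-5.0)


class TestModelSelection:
    def test_single_species_prefers_one(self, vol):
        curve = synthesize_acf(
            OneComponentParams(N=1.0, tau_D=2e-4), vol, noise_fraction=0.0
        )[0]
        choice, _, _ = select_model(curve, vol)
        assert choice == "one"

    def test_noisy_single_species_mostly_one(self, vol):
        params = preset_params("egfp", vol, mode="bulk")
        curves = synthesize_acf(params, vol, noise_fraction=0.02, n_curves=20, seed=21)
        choices = [select_model(c, vol)[0] for c in curves]
        assert choices.count("one") >= 19  # >= 95% under the null

    def test_separated_mixture_prefers_two(self, vol):
        params = preset_params("alpha_synuclein_on_sv", vol)
        curves = synthesize_acf(params, vol, noise_fraction=0.02, n_curves=5, seed=22)
        for curve in curves:
            assert select_model(curve, vol)[0] == "two"


class TestAggregateExclusion:
    def make_trace(self, counts, dt=1e-4):
        return IntensityTrace(dt=dt, counts=counts)

    def test_stationary_poisson_kept(self, rng):
        trace = self.make_trace(rng.poisson(50, size=20_000))
        assert exclude_aggregate_traces(trace).keep

    def test_sustained_bright_spike_excluded(self, rng):
        counts = rng.poisson(50, size=20_000).astype(float)
        counts[4000:5000] *= 50  # 100 ms aggregate transit
        verdict = exclude_aggregate_traces(self.make_trace(counts))
        assert not verdict.keep
        assert len(verdict.offending_bins) >= 3

    def test_short_spike_survives_run_requirement(self, rng):
        counts = rng.poisson(50, size=20_000).astype(float)
        counts[4000:4100] *= 50  # one 10 ms bin only
        assert exclude_aggregate_traces(self.make_trace(counts)).keep

    def test_bin_exactly_at_threshold_kept(self):
        counts = np.full(20_000, 10.0)
        trace = self.make_trace(counts)
        # constant trace: MAD = 0, threshold = median; all bins equal it
        assert exclude_aggregate_traces(trace).keep

    def test_short_trace_rejected(self, rng):
        with pytest.raises(ValueError):
            exclude_aggregate_traces(self.make_trace(rng.poisson(5, 100)))


class TestBatchAnalyze:
    def test_bulk_summary_schema(self, vol):
        params = preset_params("egfp", vol, mode="bulk")
        curves = synthesize_acf(params, vol, noise_fraction=0.02, n_curves=4, seed=31)
        summary = batch_analyze({"egfp": curves}, vol, mode="bulk")[0]
        assert summary.d_bulk_mean is not None
        assert summary.d_bound_mean is None  # no bound pool in bulk mode

    def test_on_pattern_summary_recovers_bound_fraction(self, vol):
        params = preset_params("synapsin", vol)
        curves = synthesize_acf(params, vol, noise_fraction=0.02, n_curves=12, seed=32)
        summary = batch_analyze(
            {"synapsin": curves}, vol, mode="on_pattern", use_model_selection=False
        )[0]
        se = summary.pct_bound_sd / np.sqrt(summary.n_curves)
        assert abs(summary.pct_bound_mean - 30.0) < 3 * se + 0.5

    def test_duplicated_curves_have_zero_sd(self, vol):
        params = preset_params("egfp", vol, mode="bulk")
        curve = synthesize_acf(params, vol, noise_fraction=0.02, seed=33)[0]
        summary = batch_analyze({"x": [curve, curve, curve]}, vol, mode="bulk")[0]
        assert summary.d_bulk_sd == pytest.approx(0.0, abs=1e-9)

    def test_too_few_curves_rejected(self, vol):
        params = preset_params("egfp", vol, mode="bulk")
        curves = synthesize_acf(params, vol, noise_fraction=0.02, n_curves=2, seed=34)
        with pytest.raises(ValueError):
            batch_analyze({"egfp": curves}, vol, mode="bulk")
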