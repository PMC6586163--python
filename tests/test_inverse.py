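"""Inverse analysis: β calibration, exponential fits, biphasic splitting,
transport-parameter recovery and cut-test QC."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rootprobe import (
    PressureTrace,
    ProbeSystem,
    TransportParams,
    analytic_tmin,
    analyze_osmotic_trace,
    calibrate_beta,
    fit_exponential_phase,
    hydraulic_conductivity,
    hydrostatic_rate_constant,
    qc_cut_test,
    reflection_coefficient,
    simulate_hydrostatic_relaxation,
    simulate_osmotic_response,
    solute_permeability,
    solute_rate_constant,
    split_biphasic,
    xylem_volume,
)
from rootprobe.inverse import CalibrationError, FitError, NoMinimumError, RelaxationFit

LN2 = math.log(2)


class TestCalibrateBeta:
    def test_exact_line_through_origin(self):
        beta, resid = calibrate_beta([1e-11, 2e-11], [0.109, 0.218])
        assert beta == pytest.approx(1.09e10, rel=1e-12)
        assert np.allclose(resid, 0.0)

    def test_single_pair_is_ratio(self):
        beta, _ = calibrate_beta([2e-11], [0.218])
        assert beta == pytest.approx(0.218 / 2e-11, rel=1e-12)

    def test_no_elastic_response_rejected(self):
        with pytest.raises(CalibrationError, match="no elastic response"):
            calibrate_beta([1e-11, 2e-11], [0.0, 0.0])

    def test_inconsistent_signs_rejected(self):
        with pytest.raises(CalibrationError, match="inconsistent"):
            calibrate_beta([1e-11, 2e-11], [0.109, -0.218])


class TestExponentialFit:
    def test_noise_free_recovery(self, control_params, probe):
        """On a clean relaxation the rate constant is recovered to < 10⁻⁶."""
        kwr = hydrostatic_rate_constant(control_params, probe)
        tr = simulate_hydrostatic_relaxation(control_params, probe, 0.2, 0.05, 60, 0.05)
        fit = fit_exponential_phase(tr)
        assert abs(fit.rate_constant - kwr) / kwr < 1e-6
        assert fit.asymptote == pytest.approx(0.2, abs=1e-8)
        assert fit.amplitude == pytest.approx(0.05, abs=1e-8)

    def test_constant_trace_is_a_fit_error(self):
        tr = PressureTrace(np.arange(0, 10, 0.5), np.full(20, 0.2),
                           "hydrostatic_step", 0.0)
        with pytest.raises(FitError, match="constant"):
            fit_exponential_phase(tr)

    def test_too_few_samples_is_a_fit_error(self, control_params, probe):
        tr = simulate_hydrostatic_relaxation(control_params, probe, 0.2, 0.05, 60, 0.05)
        with pytest.raises(FitError, match="5 samples"):
            fit_exponential_phase(tr, window=(0.0, 0.16))

    def test_noisy_rate_constant_median_error_below_2pct(self, control_params, probe):
        """sd 0.002 MPa on a 0.05 MPa relaxation: median |k̂−k|/k < 2 %
        over 200 seeded replicates."""
        kwr = hydrostatic_rate_constant(control_params, probe)
        clean = simulate_hydrostatic_relaxation(control_params, probe, 0.2, 0.05, 60, 0.05)
        rng = np.random.default_rng(42)
        errors = []
        for _ in range(200):
            noisy = PressureTrace(
                clean.time, clean.pressure + rng.normal(0, 0.002, clean.n),
                clean.event_kind, clean.event_magnitude,
            )
            fit = fit_exponential_phase(noisy)
            errors.append(abs(fit.rate_constant - kwr) / kwr)
        assert np.median(errors) < 0.02

    def test_fixed_asymptote_is_respected(self, control_params, probe):
        tr = simulate_hydrostatic_relaxation(control_params, probe, 0.2, 0.05, 60, 0.05)
        fit = fit_exponential_phase(tr, fixed_asymptote=0.2)
        assert fit.asymptote == 0.2

    def test_relaxation_fit_invariants(self):
        with pytest.raises(ValueError):
            RelaxationFit(rate_constant=-1.0, half_time=1.0, asymptote=0.0,
                          amplitude=0.1, rss=0.0, n_points=10)
        with pytest.raises(ValueError):
            RelaxationFit(rate_constant=0.1, half_time=1.0, asymptote=0.0,
                          amplitude=0.1, rss=0.0, n_points=10)


class TestSplitBiphasic:
    def test_tmin_matches_analytic_within_one_sample(self, control_params, probe, geometry):
        kwr = hydrostatic_rate_constant(control_params, probe)
        ksr = solute_rate_constant(control_params, probe, geometry)
        dt = 0.1
        tr = simulate_osmotic_response(control_params, probe, geometry, 0.2, 0.148, 3000, dt)
        decomp = split_biphasic(tr)
        assert abs(decomp.tmin - analytic_tmin(kwr, ksr)) <= dt
        assert decomp.solute_fit.rate_constant == pytest.approx(ksr, rel=0.02)

    def test_flat_trace_has_no_minimum(self, probe, geometry):
        params = TransportParams(Lpr=8.11e-8, Psr=2.24e-9, sigma=0.0)
        tr = simulate_osmotic_response(params, probe, geometry, 0.2, 0.148, 3000, 0.5)
        with pytest.raises(NoMinimumError):
            split_biphasic(tr)

    def test_impermeant_monotone_trace_has_no_minimum(self, probe, geometry):
        params = TransportParams(Lpr=8.11e-8, Psr=0.0, sigma=0.38)
        tr = simulate_osmotic_response(params, probe, geometry, 0.2, 0.148, 300, 0.1)
        with pytest.raises(NoMinimumError, match="impermeant|monotone"):
            split_biphasic(tr)


class TestTransportFormulas:
    def test_lpr_hand_arithmetic(self):
        """t½w = 5 s with the default probe gives the control-scale Lpr."""
        lpr = hydraulic_conductivity(5.0, 1.57e-4, 1.09e10)
        assert lpr == pytest.approx(8.10e-8, rel=2e-3)

    def test_psr_hand_arithmetic(self):
        psr = solute_permeability(580.0, 1.57e-4, 2.945e-10)
        assert psr == pytest.approx(2.24e-9, rel=2e-3)

    @given(st.floats(1.0, 1e4), st.floats(2.0, 10.0))
    def test_inverse_proportionality_in_half_time(self, t_half, factor):
        """Doubling the half-time halves the conductivity, exactly."""
        a, b = 1.57e-4, 1.09e10
        assert hydraulic_conductivity(factor * t_half, a, b) == pytest.approx(
            hydraulic_conductivity(t_half, a, b) / factor, rel=1e-12
        )
        assert solute_permeability(factor * t_half, a, 3e-10) == pytest.approx(
            solute_permeability(t_half, a, 3e-10) / factor, rel=1e-12
        )

    def test_sigma_no_correction_at_tmin_zero(self):
        assert reflection_coefficient(0.05, 0.148, 1e-3, 0.0) == pytest.approx(
            0.05 / 0.148, rel=1e-12
        )

    def test_sigma_control_values(self):
        sigma = reflection_coefficient(0.0539, 0.148, 1.194e-3, 34.6)
        assert sigma == pytest.approx(0.380, abs=0.002)

    def test_sigma_homogeneity_degree_zero(self):
        """Rescaling ΔPr and Δπ together leaves σ unchanged."""
        base = reflection_coefficient(0.05, 0.148, 1e-3, 30.0)
        scaled = reflection_coefficient(0.05 * 7.3, 0.148 * 7.3, 1e-3, 30.0)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_sigma_above_one_warns(self):
        with pytest.warns(UserWarning, match="exceeds 1"):
            reflection_coefficient(0.2, 0.148, 1e-3, 100.0)

    def test_sigma_domain_errors(self):
        with pytest.raises(ValueError):
            reflection_coefficient(0.05, 0.0, 1e-3, 30.0)


class TestForwardInverseRoundtrip:
    @pytest.mark.parametrize("lpr", [1e-8, 3e-8, 8e-8])
    @pytest.mark.parametrize("psr", [0.5e-9, 2.2e-9])
    @pytest.mark.parametrize("sigma", [0.2, 0.38, 0.8])
    def test_noise_free_grid_recovery_within_1pct(self, lpr, psr, sigma, probe, geometry):
        """Noise-free traces return the generating (Lpr, Psr, σ) to < 1 %
        (discretisation only)."""
        params = TransportParams(Lpr=lpr, Psr=psr, sigma=sigma)
        kwr = hydrostatic_rate_constant(params, probe)
        ksr = solute_rate_constant(params, probe, geometry)
        t_half_w = LN2 / kwr
        hydro = simulate_hydrostatic_relaxation(
            params, probe, 0.2, 0.05, 20 * t_half_w, t_half_w / 50
        )
        fit = fit_exponential_phase(hydro)
        lpr_hat = hydraulic_conductivity(fit.half_time, probe.Ar, probe.beta)
        assert abs(lpr_hat - lpr) / lpr < 0.01

        osmo = simulate_osmotic_response(
            params, probe, geometry, 0.2, 0.148, 4 / ksr, min(t_half_w / 50, 0.5)
        )
        res = analyze_osmotic_trace(osmo, probe, geometry)
        assert abs(res["Psr"] - psr) / psr < 0.01
        assert abs(res["sigma"] - sigma) / sigma < 0.01

    def test_noisy_recovery_medians(self, control_params, probe, geometry):
        """Gaussian sensor noise sd 0.002 MPa, 200 seeded replicates:
        median relative error < 5 % for Lpr, < 10 % for Psr and σ."""
        rng = np.random.default_rng(7)
        hydro = simulate_hydrostatic_relaxation(control_params, probe, 0.2, 0.05, 60, 0.05)
        osmo = simulate_osmotic_response(control_params, probe, geometry, 0.2, 0.148, 3000, 0.1)
        err_lpr, err_psr, err_sigma = [], [], []
        for _ in range(200):
            h = PressureTrace(hydro.time, hydro.pressure + rng.normal(0, 0.002, hydro.n),
                              hydro.event_kind, hydro.event_magnitude)
            fit = fit_exponential_phase(h)
            lpr_hat = hydraulic_conductivity(fit.half_time, probe.Ar, probe.beta)
            err_lpr.append(abs(lpr_hat - control_params.Lpr) / control_params.Lpr)

            o = PressureTrace(osmo.time, osmo.pressure + rng.normal(0, 0.002, osmo.n),
                              osmo.event_kind, osmo.event_magnitude)
            res = analyze_osmotic_trace(o, probe, geometry)
            err_psr.append(abs(res["Psr"] - control_params.Psr) / control_params.Psr)
            err_sigma.append(abs(res["sigma"] - control_params.sigma) / control_params.sigma)
        assert np.median(err_lpr) < 0.05
        assert np.median(err_psr) < 0.10
        assert np.median(err_sigma) < 0.10


class TestCutTestQC:
    def _pre_fit(self, t_half: float) -> RelaxationFit:
        k = LN2 / t_half
        return RelaxationFit(rate_constant=k, half_time=t_half, asymptote=0.2,
                             amplitude=0.05, rss=0.0, n_points=100)

    def _decay_trace(self, t_half: float, final_fraction: float = 0.0) -> PressureTrace:
        """Post-cut pressure collapsing toward final_fraction × steady."""
        k = LN2 / t_half
        t = np.arange(0, 20 * t_half, t_half / 20)
        p = 0.2 * final_fraction + 0.2 * (1 - final_fraction) * np.exp(-k * t)
        return PressureTrace(t, p, "cut", 0.0)

    def test_fast_collapse_passes(self):
        verdict, reasons = qc_cut_test(self._pre_fit(5.0), self._decay_trace(5.0 / 20))
        assert verdict == "pass"
        assert reasons == []

    def test_retained_pressure_fails(self):
        """Pressure staying at 80 % of steady: overtightened seal, fail."""
        verdict, reasons = qc_cut_test(self._pre_fit(5.0),
                                       self._decay_trace(5.0 / 20, final_fraction=0.8))
        assert verdict == "fail"
        assert any("collapse" in r for r in reasons)

    def test_insufficient_speedup_fails(self):
        verdict, reasons = qc_cut_test(self._pre_fit(5.0), self._decay_trace(5.0 / 2))
        assert verdict == "fail"
        assert any("faster" in r for r in reasons)

    def test_missing_post_cut_data_is_indeterminate(self):
        verdict, reasons = qc_cut_test(self._pre_fit(5.0), None)
        assert verdict == "indeterminate"
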