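"""Anomalous-diffusion model, fitting, calibration and physical units."""

import numpy as np
import pytest

from fcsflim.correlation import InvalidParameterError
from fcsflim.fcs import (
    CalibrationResult,
    FcsModelParams,
    brightness_qc,
    calibrate_focus,
    concentration_nM,
    derive_physical,
    effective_volume,
    eval_acf_model,
    fit_acf,
    fit_acf_global,
    molecules_in_focus,
)
from fcsflim.synthetic import simulate_model_acf


class TestForwardModel:
    def test_two_component_reduces_to_one(self):
        lags = np.geomspace(1e-6, 1.0, 80)
        two = FcsModelParams(N=5.0, F2=0.0, tauD1=2e-3, tauD2=0.5,
                             alpha1=0.9, alpha2=1.4)
        one = FcsModelParams(N=5.0, F2=0.0, tauD1=2e-3, alpha1=0.9)
        np.testing.assert_allclose(eval_acf_model(two, lags),
                                   eval_acf_model(one, lags), rtol=1e-14)

    def test_small_lag_amplitude(self):
        p = FcsModelParams(N=8.0, G_inf=0.02)
        val = eval_acf_model(p, [1e-12])[0]
        assert val == pytest.approx(0.02 + 1.0 / 8.0, rel=1e-6)

    def test_closed_form_at_tau_equals_tauD(self):
        # alpha = 1, tau = tauD: G - Ginf = (1/2N) / sqrt(1 + 1/kappa^2)
        n, kappa = 5.0, 5.0
        p = FcsModelParams(N=n, tauD1=3e-3, alpha1=1.0, kappa=kappa)
        expected = 1.0 / (2.0 * n) / np.sqrt(1.0 + 1.0 / kappa ** 2)
        assert eval_acf_model(p, [3e-3])[0] == pytest.approx(expected, rel=1e-12)

    def test_monotone_nonincreasing_for_subdiffusive(self):
        p = FcsModelParams(N=3.0, F2=0.4, tauD1=1e-3, tauD2=0.2,
                           alpha1=1.0, alpha2=0.7)
        g = eval_acf_model(p, np.geomspace(1e-6, 10, 200))
        assert np.all(np.diff(g) <= 1e-15)

    def test_invalid_params(self):
        with pytest.raises(InvalidParameterError):
            FcsModelParams(N=-1.0)
        with pytest.raises(InvalidParameterError):
            FcsModelParams(N=1.0, F2=1.2)
        with pytest.raises(InvalidParameterError):
            FcsModelParams(N=1.0, alpha1=2.5)


class TestFitAcf:
    def test_noiseless_two_component_exact_recovery(self, oct4_like_params):
        curve = simulate_model_acf(oct4_like_params, noise_sd=0.0)
        fit = fit_acf(curve, model="two")
        p, t = fit.params, oct4_like_params
        assert fit.success
        for got, want in [(p.N, t.N), (p.F2, t.F2), (p.tauD1, t.tauD1),
                          (p.tauD2, t.tauD2), (p.alpha1, t.alpha1),
                          (p.alpha2, t.alpha2)]:
            assert got == pytest.approx(want, rel=1e-6)

    def test_one_component_data_collapses_two_component_fit(self):
        """Free-GFP-like data: the two-component fit becomes effectively one."""
        gfp = FcsModelParams(N=10.0, F2=0.0, tauD1=4e-4, alpha1=1.0)
        curve = simulate_model_acf(gfp, noise_sd="auto", seed=12)
        fit = fit_acf(curve, model="two")
        assert fit.n_components_effective == 1
        assert fit.params.F2 < 0.05 or fit.params.tauD2 / fit.params.tauD1 < 3

    def test_relabeling_invariance(self, oct4_like_params):
        """Swapped component labels in init give the same physical fit."""
        curve = simulate_model_acf(oct4_like_params, noise_sd=0.0)
        a = fit_acf(curve, model="two",
                    init={"tauD1": 2e-3, "tauD2": 0.08, "F2": 0.3})
        b = fit_acf(curve, model="two",
                    init={"tauD1": 0.08, "tauD2": 2e-3, "F2": 0.7})
        assert a.params.tauD1 < a.params.tauD2
        assert b.params.tauD1 < b.params.tauD2
        assert a.params.tauD1 == pytest.approx(b.params.tauD1, rel=1e-4)
        assert a.params.F2 == pytest.approx(b.params.F2, abs=1e-4)

    def test_f1_plus_f2_is_one_exactly(self, oct4_like_params):
        curve = simulate_model_acf(oct4_like_params, noise_sd="auto", seed=13)
        fit = fit_acf(curve, model="two")
        assert fit.params.F1 + fit.params.F2 == 1.0

    def test_flat_curve_flagged_not_raised(self):
        from fcsflim.correlation import CorrelationCurve
        lags = np.geomspace(1e-6, 1.0, 60)
        curve = CorrelationCurve(lags=lags, G=np.full_like(lags, -1e-4))
        fit = fit_acf(curve, model="two")
        assert not fit.success
        assert "amplitude" in fit.message

    def test_concentration_linearity(self, calib):
        """Doubling concentration halves the fitted amplitude G(0) - Ginf."""
        amps = []
        for conc in (25.0, 50.0):
            p = FcsModelParams(N=molecules_in_focus(conc, calib.V_eff),
                               F2=0.2, tauD1=3e-3, tauD2=0.1)
            curve = simulate_model_acf(p, noise_sd="auto", seed=14)
            amps.append(1.0 / fit_acf(curve, model="two").params.N)
        assert amps[0] / amps[1] == pytest.approx(2.0, rel=0.05)

    def test_recovery_bias_small_over_replicates(self, oct4_like_params):
        """Fast-path round trip: shared-tauD1 refit is unbiased in F2."""
        curves = [simulate_model_acf(oct4_like_params, seed=100 + i)
                  for i in range(60)]
        f2 = np.array([
            fit_acf(c, model="two", fix_tauD1=oct4_like_params.tauD1).params.F2
            for c in curves
        ])
        sem = f2.std(ddof=1) / np.sqrt(len(f2))
        assert abs(f2.mean() - oct4_like_params.F2) < 3 * sem + 0.01


class TestGlobalFit:
    def test_single_curve_matches_individual(self, oct4_like_params):
        curve = simulate_model_acf(oct4_like_params, noise_sd="auto", seed=15)
        fits, tau1, _ = fit_acf_global([curve])
        assert tau1 == pytest.approx(fit_acf(curve, model="two").params.tauD1)

    def test_global_residual_not_worse_than_pinned_individual(self, oct4_like_params):
        curves = [simulate_model_acf(oct4_like_params, seed=200 + i)
                  for i in range(6)]
        fits, tau1, _ = fit_acf_global(curves)
        total_global = sum(f.chi2_reduced * (len(c) - len(f.se))
                           for f, c in zip(fits, curves))
        pinned = [fit_acf(c, model="two", fix_tauD1=tau1) for c in curves]
        total_pinned = sum(f.chi2_reduced * (len(c) - len(f.se))
                           for f, c in zip(pinned, curves))
        assert total_global <= total_pinned * (1 + 1e-9)


class TestCalibration:
    def test_closed_form_w0(self):
        # tauD 25 us at D = 400 um^2/s -> w0 = 0.2 um
        assert np.sqrt(4 * 400.0 * 25e-6) == pytest.approx(0.2, rel=1e-12)
        dye = FcsModelParams(N=0.13, tauD1=25e-6, alpha1=1.0)
        curve = simulate_model_acf(dye, lag_grid=np.geomspace(2e-6, 1.0, 160),
                                   noise_sd=0.0)
        calib = calibrate_focus(curve, known_D=400.0, kappa=5.0)
        assert calib.w0 == pytest.approx(0.2, rel=1e-4)
        assert calib.V_eff == pytest.approx(np.pi ** 1.5 * 5.0 * 0.2 ** 3, rel=1e-3)

    def test_scaling_law_doubled_tauD(self):
        lags = np.geomspace(2e-6, 1.0, 160)
        c1 = simulate_model_acf(FcsModelParams(N=0.2, tauD1=25e-6, alpha1=1.0),
                                lag_grid=lags, noise_sd=0.0)
        c2 = simulate_model_acf(FcsModelParams(N=0.2, tauD1=50e-6, alpha1=1.0),
                                lag_grid=lags, noise_sd=0.0)
        a = calibrate_focus(c1, known_D=400.0)
        b = calibrate_focus(c2, known_D=400.0)
        assert b.w0 / a.w0 == pytest.approx(np.sqrt(2), rel=1e-3)
        assert b.V_eff / a.V_eff == pytest.approx(2 ** 1.5, rel=1e-3)

    def test_two_component_dye_curve_warns(self):
        bad = FcsModelParams(N=0.2, F2=0.4, tauD1=25e-6, tauD2=5e-3)
        curve = simulate_model_acf(bad, lag_grid=np.geomspace(2e-6, 1.0, 160),
                                   noise_sd=0.0)
        with pytest.warns(UserWarning, match="two-component"):
            calibrate_focus(curve, known_D=400.0)


class TestPhysicalUnits:
    def test_unit_arithmetic_one_molecule(self):
        # N = 1 in 1 fl: C = 1/(N_A * 1e-15 L) = 1.661 nM
        assert concentration_nM(1.0, 1.0) == pytest.approx(1.6606, rel=1e-4)

    def test_blastula_regime(self):
        # N = 26.7 in 1 fl sits at the measured blastula concentration scale
        assert concentration_nM(26.7, 1.0) == pytest.approx(44.34, rel=1e-3)

    def test_diffusion_from_tau(self, calib, oct4_like_params):
        fit = fit_acf(simulate_model_acf(oct4_like_params, noise_sd=0.0),
                      model="two")
        derive_physical(fit, calib)
        assert fit.D1 == pytest.approx(
            calib.w0 ** 2 / (4 * oct4_like_params.tauD1), rel=1e-4)
        assert fit.concentration == pytest.approx(44.39, rel=1e-3)

    def test_molecules_and_concentration_inverse(self):
        v = effective_volume(0.2, 5.0)
        assert concentration_nM(molecules_in_focus(37.0, v), v) == \
            pytest.approx(37.0, rel=1e-12)


class TestBrightnessQC:
    def test_boundary_window(self):
        assert brightness_qc(1.00, 1.0, 1.0).passed
        assert brightness_qc(1.099, 1.0, 1.0).passed
        assert not brightness_qc(1.101, 1.0, 1.0).passed

    def test_aberration_like_widening_fails(self, calib):
        """Wider focus at the same C inflates fitted N and halves brightness."""
        conc = 40.0
        rate = 50000.0  # detected counts/s, fixed by the detector
        n_true = molecules_in_focus(conc, calib.V_eff)
        reference = rate / n_true
        v_wide = effective_volume(calib.w0 * np.sqrt(2), calib.kappa)
        n_wide = molecules_in_focus(conc, v_wide)
        qc = brightness_qc(rate, n_wide, reference)
        assert not qc.passed and qc.ratio < 0.6

    def test_invalid_reference(self):
        with pytest.raises(InvalidParameterError):
            brightness_qc(1.0, 1.0, 0.0)
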