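"""Generator-level checks: equilibrium solver, traces, model curves, decays."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import linregress

import fcsflim as ff
from fcsflim.correlation import InvalidParameterError
from fcsflim.fcs import FcsModelParams, eval_acf_model
from fcsflim.flim import decay_expectation
from fcsflim.synthetic import (
    BindingEnsembleParams,
    DecaySimParams,
    SimTraceParams,
    acf_noise_profile,
    mean_detection_efficiency,
    simulate_binding_ensemble,
    simulate_brownian_trace,
    simulate_model_acf,
    simulate_tcspc_decay,
    solve_equilibrium,
)


class TestSolveEquilibrium:
    def test_kd_zero_full_complexation(self):
        assert solve_equilibrium(100.0, 100.0, 0.0) == pytest.approx(100.0)
        assert solve_equilibrium(30.0, 80.0, 0.0) == pytest.approx(30.0)

    def test_zero_total_gives_zero_complex(self):
        assert solve_equilibrium(0.0, 50.0, 15.0) == 0.0

    def test_matches_bisection_oracle(self):
        # independent root of (A - x)(B - x) = Kd x by bisection
        a, b, kd = 100.0, 100.0, 15.0
        oracle = brentq(lambda x: (a - x) * (b - x) - kd * x, 0.0, min(a, b))
        assert solve_equilibrium(a, b, kd) == pytest.approx(oracle, abs=1e-10)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            solve_equilibrium(-1.0, 10.0, 1.0)

    @settings(deadline=None, max_examples=200)
    @given(
        a=st.floats(0.0, 1e4), b=st.floats(0.0, 1e4),
        kd=st.floats(0.0, 1e5),
    )
    def test_mass_action_residual(self, a, b, kd):
        """Root satisfies mass action to |residual| < 1e-9 nM^2 and bounds."""
        x = solve_equilibrium(a, b, kd)
        assert 0.0 <= x <= min(a, b) + 1e-12
        assert abs((a - x) * (b - x) - kd * x) < 1e-9 * max(1.0, a * b)


class TestBrownianTrace:
    def test_zero_molecules_zero_background_all_zero(self):
        p = SimTraceParams(duration=0.2, dt=1e-4,
                           n_molecules_per_species=(0,), seed=1)
        trace = simulate_brownian_trace(p)
        assert np.all(trace.counts_g == 0)

    def test_fixed_seed_bit_identical(self):
        p = SimTraceParams(duration=0.2, dt=1e-4, seed=42)
        a = simulate_brownian_trace(p)
        b = simulate_brownian_trace(p)
        assert np.array_equal(a.counts_g, b.counts_g)

    def test_mean_counts_match_detection_integral(self):
        """Mean counts/bin ~ dt*(bg + n*b*<W>), <W> by numerical integration."""
        p = SimTraceParams(duration=4.0, dt=1e-4, box_size=3.0,
                           n_molecules_per_species=(20,),
                           diffusion_coeffs=(10.0,),
                           brightness_per_molecule=(50000.0,),
                           background_rate=500.0, seed=3)
        trace = simulate_brownian_trace(p)

        def gauss_mean(s):  # 1-axis box average of exp(-2u^2/s^2)
            val, _ = quad(lambda u: np.exp(-2 * u ** 2 / s ** 2),
                          -p.box_size / 2, p.box_size / 2)
            return val / p.box_size

        w_mean = gauss_mean(p.w0) ** 2 * gauss_mean(p.z0)
        assert mean_detection_efficiency(p.w0, p.kappa, p.box_size) == \
            pytest.approx(w_mean, rel=1e-8)
        expected = p.dt * (p.background_rate + 20 * 50000.0 * w_mean)
        assert trace.counts_g.mean() == pytest.approx(expected, rel=0.10)

    def test_two_channels_via_crosstalk(self):
        p = SimTraceParams(duration=0.2, dt=1e-4, crosstalk_coeff=0.1, seed=2)
        trace = simulate_brownian_trace(p)
        assert trace.n_channels == 2
        # red counts are pure bleed-through here: ~10% of green on average
        assert trace.counts_r.sum() < 0.3 * trace.counts_g.sum()

    def test_invalid_params(self):
        with pytest.raises(InvalidParameterError):
            SimTraceParams(duration=1e-4, dt=1e-3)
        with pytest.raises(InvalidParameterError):
            SimTraceParams(crosstalk_coeff=1.5)


class TestModelAcf:
    def test_zero_noise_equals_forward_model(self, oct4_like_params):
        curve = simulate_model_acf(oct4_like_params, noise_sd=0.0)
        np.testing.assert_allclose(
            curve.G, eval_acf_model(oct4_like_params, curve.lags), rtol=0, atol=0)

    def test_amplitude_limit_small_lag(self):
        p = FcsModelParams(N=4.0, F2=0.3, tauD1=1e-3, tauD2=0.1, G_inf=0.01)
        lags = np.geomspace(1e-9, 1.0, 50)
        g = simulate_model_acf(p, lag_grid=lags, noise_sd=0.0).G
        assert g[0] == pytest.approx(p.G_inf + 1.0 / p.N, rel=1e-5)

    def test_noise_sd_calibrated(self, oct4_like_params):
        """Per-lag sample std over replicates matches the requested sigma."""
        lags = np.geomspace(1e-5, 1.0, 10)
        sd = np.linspace(0.01, 0.002, 10)
        reps = np.stack([
            simulate_model_acf(oct4_like_params, lag_grid=lags, noise_sd=sd,
                               seed=i).G
            for i in range(1000)
        ])
        np.testing.assert_allclose(reps.std(axis=0, ddof=1), sd, rtol=0.05)

    def test_negative_sigma_rejected(self, oct4_like_params):
        with pytest.raises(InvalidParameterError):
            simulate_model_acf(oct4_like_params, noise_sd=-0.1)

    def test_auto_noise_profile_shape(self, oct4_like_params):
        curve = simulate_model_acf(oct4_like_params, noise_sd="auto", seed=1)
        prof = acf_noise_profile(oct4_like_params, curve.lags)
        np.testing.assert_allclose(curve.sigma, prof)
        assert prof[0] > prof[-1] > 0  # decays to a positive floor


class TestBindingEnsemble:
    def test_truth_satisfies_mass_action_exactly(self):
        cells = simulate_binding_ensemble(
            BindingEnsembleParams(n_cells=10, kd=15.34, seed=1))
        for cell in cells:
            t = cell.truth
            assert t["C_free_g"] * t["C_free_r"] == pytest.approx(
                t["kd"] * t["C_complex"], rel=1e-9)

    def test_kd_zero_full_association(self):
        p = BindingEnsembleParams(n_cells=8, kd=0.0,
                                  total_green_range=(50.0, 50.0),
                                  total_red_range=(50.0, 50.0), seed=2)
        for cell in simulate_binding_ensemble(p):
            assert cell.truth["C_complex"] == pytest.approx(50.0)

    def test_huge_kd_no_complex(self):
        p = BindingEnsembleParams(n_cells=8, kd=1e9, seed=3)
        for cell in simulate_binding_ensemble(p):
            assert cell.truth["C_complex"] < 1e-4 * cell.truth["C_total_g"]

    def test_curves_output_has_triplet_with_sigma(self):
        cells = simulate_binding_ensemble(
            BindingEnsembleParams(n_cells=3, seed=4))
        for cell in cells:
            assert set(cell.curves) == {"ACF_g", "ACF_r", "CCF"}
            for c in cell.curves.values():
                assert c.sigma is not None and np.all(c.sigma > 0)

    def test_traces_output_dual_channel(self):
        cells = simulate_binding_ensemble(
            BindingEnsembleParams(n_cells=2, seed=5,
                                  total_green_range=(30.0, 40.0),
                                  total_red_range=(30.0, 40.0)),
            output="traces",
            trace_kwargs={"duration": 0.05, "dt": 1e-4})
        for cell in cells:
            assert cell.trace.n_channels == 2


class TestTcspcDecay:
    def test_log_linear_slope_mono_no_irf(self):
        """Pure mono decay: log expected counts linear with slope -1/tau."""
        p = DecaySimParams(lifetimes=(2.5,), amplitude_fractions=(1.0,),
                           total_counts=5e6, irf_fwhm=0.0, irf_shift=0.0,
                           background_fraction=0.0, seed=6)
        hist = simulate_tcspc_decay(p)
        t = hist.t
        sel = (t > 0.5) & (t < 10.0) & (hist.counts > 50)
        res = linregress(t[sel], np.log(hist.counts[sel]))
        assert -1.0 / res.slope == pytest.approx(2.5, rel=0.02)

    def test_degenerate_fraction_matches_mono_same_seed(self):
        mono = DecaySimParams(lifetimes=(2.3,), amplitude_fractions=(1.0,), seed=7)
        degen = DecaySimParams(lifetimes=(2.3, 0.8),
                               amplitude_fractions=(1.0, 0.0), seed=7)
        a = simulate_tcspc_decay(mono)
        b = simulate_tcspc_decay(degen)
        assert np.array_equal(a.counts, b.counts)

    def test_total_counts_expectation(self):
        p = DecaySimParams(total_counts=1e6, seed=8)
        hist = simulate_tcspc_decay(p)
        assert hist.counts.sum() == pytest.approx(1e6, rel=0.01)

    def test_short_window_warns(self):
        with pytest.warns(UserWarning, match="truncation"):
            simulate_tcspc_decay(DecaySimParams(lifetimes=(4.0,), window=10.0,
                                                n_bins=500, seed=9))

    def test_expectation_is_irf_convolved_mixture(self):
        # Poisson mean of the histogram follows the analytic EMG mixture
        p = DecaySimParams(lifetimes=(2.3, 0.8), amplitude_fractions=(0.7, 0.3),
                           total_counts=1e7, background_fraction=0.0, seed=10)
        hist = simulate_tcspc_decay(p)
        t = hist.t
        dens = decay_expectation(t, p.lifetimes, p.amplitude_fractions,
                                 p.irf_fwhm, p.irf_shift)
        mu = 1e7 * dens / dens.sum()
        sel = mu > 2000
        z = (hist.counts[sel] - mu[sel]) / np.sqrt(mu[sel])
        assert abs(z.mean()) < 3.0 / np.sqrt(sel.sum())  # 3-sigma on the mean
        assert 0.8 < z.std() < 1.2

    def test_invalid_fractions(self):
        with pytest.raises(InvalidParameterError):
            DecaySimParams(lifetimes=(2.0, 1.0), amplitude_fractions=(0.6, 0.6))
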