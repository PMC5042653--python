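# fcsflim

Quantitative inference of transcription-factor concentration, mobility and
binding in living embryonic nuclei from fluorescence fluctuation and
lifetime data.

Three measurement modalities share one pipeline:

* **FCS** — the autocorrelation G(τ) of intensity fluctuations from
  molecules crossing a calibrated confocal volume is fit with a
  two-component anomalous-diffusion model

  G(τ) = G∞ + (1/N) Σᵢ Fᵢ [1+(τ/τ_{D,i})^{αᵢ}]⁻¹ [1+(τ/τ_{D,i})^{αᵢ}/κ²]^{-1/2}

  giving the absolute concentration C = N/(N_A·V_eff), diffusion
  coefficients Dᵢ = w₀²/(4τ_{D,i}) and the slow, DNA-bound fraction F₂.
* **FCCS** — dual-color auto- and cross-correlation amplitudes give
  per-cell free and complex concentrations; across an ensemble of cells in
  binding equilibrium, regressing C_free_g·C_free_r on C_complex through
  the origin yields the dissociation constant K_d as the slope
  (mass action: C_free_g·C_free_r = K_d·C_complex).
* **FLIM-FRET** — TCSPC decays are fit (Poisson MLE, IRF-convolved) with
  mono/bi-exponential models; the amplitude fraction of the short-lifetime
  component, 100·a₂/(a₁+a₂), is the percentage of donor bound to an
  acceptor-tagged partner.

Because the original embryo recordings are not deposited, the package
ships a first-class synthetic-data generator (Brownian-dynamics photon
traces through a 3D Gaussian focus, model correlation curves with
realistic noise, equilibrium binding ensembles, TCSPC decays) whose
defaults are the study conditions; every stage is validated by parameter
recovery. See `docs/methods.md` for models, assumptions and numerics.

Intended users: microscopists and quantitative biologists analysing
in-vivo FCS/FCCS/FLIM measurements of protein–protein and protein–DNA
interactions, and developers who need a fully synthetic, ground-truthed
test bed for such pipelines.

## Worked example

```python
import numpy as np
import fcsflim as ff

# 1. calibrate the focal volume from a 30-s reference-dye trace
dye = ff.simulate_brownian_trace(ff.SimTraceParams(
    duration=30.0, dt=2e-6, diffusion_coeffs=(400.0,), seed=7))
dye_curve = ff.multitau_correlate(dye)
cal = ff.calibrate_focus(dye_curve, known_D=400.0, kappa=5.0)
print(f"w0 = {cal.w0:.4f} um, V_eff = {cal.V_eff:.4f} fl")

# 2. fit a nuclear measurement and derive physical quantities
truth = ff.FcsModelParams(N=ff.molecules_in_focus(44.39, cal.V_eff),
                          F2=0.27, tauD1=3.03e-3, tauD2=0.1, alpha2=0.8)
curve = ff.simulate_model_acf(truth, seed=1)
fit = ff.fit_acf(curve, model="two", fix_tauD1=3.03e-3)
ff.derive_physical(fit, cal)
print(f"C = {fit.concentration:.1f} nM, bound fraction F2 = {fit.params.F2:.3f}, "
      f"D1 = {fit.D1:.2f} um2/s")
```

Output (seed 7 calibration trace, seed 1 curve):

```
w0 = 0.1981 um, V_eff = 0.2165 fl
C = 44.3 nM, bound fraction F2 = 0.255, D1 = 3.24 um2/s
```

The calibration recovers the 0.2-µm focal radius within 1%; the fit
returns the generating concentration (44.39 nM), bound fraction (0.27)
and free-pool mobility (w₀²/4τ_D1 = 3.3 µm²/s) within their statistical
errors. The same objects drive K_d estimation
(`fcsflim.fccs.estimate_kd`), lifetime unmixing (`fcsflim.flim`), and the
config-driven end-to-end pipeline
(`fcsflim report --config study.yaml --out results/`).

A CLI mirrors the library: `fcsflim simulate|correlate|calibrate|fit-fcs|
fit-fccs|fit-flim|report` (see `--help`).

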