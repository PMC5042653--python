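# Methods

`fcsflim` implements the quantitative inference chain used to measure
transcription-factor concentration, DNA-bound fraction, complex formation
and binding affinity in live embryonic nuclei: fluorescence correlation
spectroscopy (FCS), dual-color cross-correlation (FCCS) and lifetime
imaging (FLIM-FRET). Because no raw embryo measurements are available, a
first-class synthetic-data generator reproduces every input with known
ground truth, and the whole pipeline is validated by parameter recovery.

## Models

### FCS: two-component anomalous diffusion

The autocorrelation of intensity fluctuations from molecules crossing a 3D
Gaussian focus (lateral 1/e² radius `w0`, structure parameter
`kappa = z0/w0`) is modelled as

    G(tau) = G_inf + (1/N) * sum_i F_i [1 + (tau/tauD_i)^alpha_i]^-1
                                    [1 + (tau/tauD_i)^alpha_i / kappa^2]^-1/2

with `F1 + F2 = 1`. Component 1 is the fast, freely diffusing pool
(`alpha1 ~ 1`); component 2 the slow, chromatin-interacting pool
(`alpha2 < 1`, subdiffusion). `F2` is reported as the DNA-bound fraction
with no further interpretation. With the effective volume
`V_eff = pi^{3/2} w0^2 z0` (femtoliters), concentration and mobility follow
as `C = N/(N_A V_eff)` and `D_i = w0^2/(4 tauD_i)`.

Calibration fits a reference-dye curve with the pure-diffusion model
(`alpha = 1` fixed) and converts the known dye constant
(Atto 488, `D = 400 µm²/s` at room temperature) into
`w0 = sqrt(4 D tauD_dye)`.

**Identifiability.** A free 7-parameter two-component fit of a single noisy
curve is ill-posed: `F2`, `tauD2` and the anomaly exponents trade off along
a ridge on which the model curves are nearly indistinguishable, and
per-cell `F2` can wander by ±0.2 at realistic noise. The pipeline therefore
follows the global-fitting workflow: the fast diffusion time `tauD1` is
estimated once by profiling the summed weighted residual of all curves of
an experiment over a shared `tauD1` (each profile evaluation refits every
curve with `tauD1` pinned and everything else free), and the per-cell
parameters are then recalculated at the shared optimum. This reduces the
per-cell `F2` scatter by an order of magnitude and removes the ridge bias.
Inner fits always start from deterministic method-of-moments values
(amplitude → `N`, half-decay lag → `tauD`); warm-starting from the free
per-cell fits would park the optimizer on the ridge.

Two-component fits collapse to an effective one-component result when
`F2 < 0.05` or `tauD2/tauD1 < 3` — the behaviour expected for a genuinely
one-component sample such as free GFP.

### FCCS: concentrations and Kd

Zero-lag amplitudes of the two ACFs and the CCF give, per cell,

    C_total_g = 1/(G_g0 N_A V_g)     C_total_r = 1/(G_r0 N_A V_r)
    C_complex = G_x0/(G_g0 G_r0 N_A V_x)

with the overlap volume `V_x` defaulting to the green `V_eff`. Free
concentrations are totals minus complex (floored at 0 with a QC flag; such
cells are excluded from the regression). Spectral bleed-through `k`
(donor-only red/green intensity ratio) is undone on covariance amplitudes:
`cov_gr_true = cov_gr - k cov_gg`, `cov_rr_true = cov_rr - 2k cov_gr_true -
k² cov_gg`, `F_r_true = F_r - k F_g`.

At binding equilibrium, mass action makes
`C_free_g * C_free_r = Kd * C_complex` exact, so Kd is the slope of the
through-origin regression of the free-concentration product on the complex
concentration. The free (not total) concentrations are used because only
then is the slope exactly Kd. The slope SE is heteroscedasticity-robust
(HC1): residuals of the product scale with the complex concentration, and
the homoscedastic formula understates the uncertainty severalfold.
Linearity ("association detected") requires squared Pearson correlation
r² ≥ 0.5 and a positive slope; otherwise the ensemble is reported as
"N.L" with no Kd.

### FLIM-FRET: bi-exponential lifetimes

TCSPC histograms are fit by maximum likelihood under Poisson counting
noise with an amplitude-fraction mixture of exponentials convolved with a
Gaussian IRF (evaluated via the exponentially-modified-normal density for
stability at short lifetimes) plus a flat background. The binding
percentage is the amplitude fraction of the short-lifetime (FRET)
component, `100 a2/(a1+a2)`. In standard practice the donor-only lifetime
is fitted from donor-alone cells and then fixed as `tau1` in all
donor+acceptor fits; this measurably shrinks the SE of `a2`. Model
selection (mono vs biexp) accepts the biexp only when an F-test on the
Pearson chi-square improves at the 1% level AND the fitted `a2 ≥ 2%`. The
fit range starts half an IRF width before the excitation pulse. Both the
amplitude-weighted mean lifetime `sum a_i tau_i` and the components are
reported, since summaries of "the" lifetime under acceptor co-expression
can refer to either.

### Correlator

The multi-tau estimator uses 16 points per octave: lags 1..32 at the
native bin width, then factor-2 rebinning with lags 17..32 per level, with
symmetric normalisation (per-lag monitor means over the overlapping
windows). First lag = dt; lags at bin centres. Per-lag noise comes from
splitting the trace into segments (default 10), correlating each, and
taking std/sqrt(n); the sigma profile is smoothed across neighbouring lags
(geometric moving average over 9 lags) because a raw 10-segment std
carries ~30% sampling error that 1/sigma² weighting would amplify into
fit bias. The dye-calibration path fits unweighted curves: multi-tau lag
estimates are mutually correlated and segment-derived weights measurably
bias the fitted decay time.

Photobleaching is removed before correlation with the ratio-plus-offset
corrector `I_corr = I sqrt(<I>/f) + <I>(1 - sqrt(f/<I>))`, where the trend
`f` is a 1-s moving average (normalized box sum; the window shrinks at the
edges rather than padding with noisy edge bins) or a forward-backward
exponential smoother with time constant ~window/4. The offset term uses
`sqrt(f/<I>)`, for which `E[I_corr] = <I>` holds exactly; the corrector
preserves shot-noise scaling.

### Group statistics

Groups are summarised as mean ± SEM when they pass Shapiro–Wilk normality
at alpha = 0.05, else as median + IQR (both always stored). Two-group
comparisons use Welch's unpaired two-tailed t-test when BOTH groups pass
normality, else two-sided Mann–Whitney U. No multiple-testing correction
is applied by default; significance tiers (*, **, ***, ****) are
annotations only.

## Synthetic data

The generator's defaults are the study conditions of the zebrafish
blastula measurements being emulated (`STUDY_PRESETS`): w0 = 0.2 µm,
kappa = 5, dye D = 400 µm²/s, free diffusion time 3.03 ms, donor lifetime
2.30 ns, FRET lifetime 0.8 ns, bound fractions 0.27/0.19/0.12,
Kd 15.34 nM (mesendoderm) and 61.9 nM (ectoderm), binding percentages
27%/2.2%. The bound-component diffusion time defaults to 100 ms
(D2 = 0.1 µm²/s), a typical chromatin-bound mobility that keeps the
two-component problem well conditioned (tauD2/tauD1 ≥ 30).

* **Brownian traces.** Molecules take per-axis Gaussian steps of std
  `sqrt(2 D dt_sim)` with `dt_sim = dt/5` in a periodic 3-µm box (≥10×
  the focal radius, so edge bias is negligible); detection is
  `exp(-2r²/w0² - 2z²/z0²)`; counts per bin are Poisson on the
  substep-averaged rate. Bleaching decays brightness exponentially;
  cross-talk leaks green molecular signal into the red channel. Steps are
  pre-generated in fixed-size chunks with numpy's ziggurat sampler and
  consumed by a numba kernel; a fixed seed gives bit-identical output.
* **Model curves (fast path).** Forward-model values plus Gaussian noise
  whose default per-lag sigma profile (4% of the amplitude at the first
  lags falling to a 0.05% floor) reproduces the shape the Brownian +
  segment-sigma pipeline measures on a 30-s trace.
* **Binding ensembles.** Per-cell totals are drawn log-uniformly over
  20–150 nM (the real expression spread across nuclei is unknown; the
  log-uniform choice is a stand-in that spreads the regression abscissa),
  the complex follows from the closed-form mass-action root (computed in a
  cancellation-free form; ground-truth triples satisfy mass action
  exactly), and curve triplets are built from the amplitude relations
  above with the complex co-diffusing in both channels. CCF noise scales
  with the ACF amplitudes, not the CCF amplitude, so no-association
  ensembles still carry realistic noise.
* **TCSPC decays.** Poisson counts around the IRF-convolved mixture plus
  flat background, normalised so expected total counts are exact.
  Defaults: 25-ns window, 1250 bins, 0.3-ns FWHM IRF at 2 ns, 2%
  background.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning keyed by (seed, stream, index), so any cell or module can be
regenerated in isolation.

What the generator does **not** emulate: triplet/blinking photophysics,
detector afterpulsing and dead time, photon-timestamp (TTTR) data, optical
aberrations, autofluorescent background structure, or cell-to-cell
variation in focal geometry. Passing recovery tests therefore demonstrate
the correctness of the estimators under the stated physical model, not
robustness to every artefact of real embryo data.

## Problem sizes and numerics

Recovery studies use the model-curve fast path (39 curves per condition
for bound fractions, 35 for the global fit, five 15-cell ensembles for
Kd, 20 decays per FLIM condition, 10⁶ counts per decay). The
Brownian-dynamics round trip runs once per session: a single 30-s dye
trace at 2-µs bins (15M bins, 5 substeps, 16 molecules) feeds
calibration and refit; multi-replicate bias properties run on the fast
path. Fit bounds: tauD1 ∈ [10 µs, 50 ms], tauD2 ∈ [1 ms, 10 s],
alpha ∈ (0.2, 2.0], |G_inf| ≤ 10% of the amplitude (fitted; whether the
original instrument fitted or pinned the baseline is unknown). For known
pure-diffusion samples (the calibration dye) the anomaly exponent is
restricted to (0.2, 1.0]: superdiffusion is physically excluded there,
and a free alpha > 1 trades against tauD and scatters the recovered D by
±15% on single 30-s traces. Parameter starts are always placed strictly
inside their bounds (a bounded optimizer's transform has zero gradient on
the boundary). kappa is fixed at 5 by default and never fitted — it is
degenerate with the anomaly exponents. Lifetime fits optimize log/logit-transformed
parameters with Nelder–Mead and derive SEs from a finite-difference
Hessian of the Poisson deviance.

## Known limitations

* Per-cell two-component fits without a shared `tauD1` are reported but
  should not be averaged; see the identifiability note.
* The Kd estimator carries a small (<1%) positive bias from nonlinear
  propagation of amplitude noise at the default noise level; it is well
  inside the regression SE at n = 15 cells.
* The analytic-Gaussian IRF path assumes the instrument response is
  symmetric; a measured-IRF histogram can be supplied instead.
* The Brownian simulator's axial Gaussian tail is truncated by the 3-µm
  box (z0 = 1 µm), biasing the absolute ACF amplitude by ~1–2%; decay
  times are unaffected.
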