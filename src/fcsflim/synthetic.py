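"""Synthetic-data generation with known ground truth.

Every input the inference pipeline consumes can be generated here:

* binned photon-count traces of molecules diffusing through a 3D Gaussian
  focus (Brownian dynamics in a periodic box, Poisson photon statistics,
  optional photobleaching and spectral cross-talk),
* noisy model correlation curves (fast path for fit-recovery studies),
* dual-color cell ensembles in binding equilibrium at a prescribed Kd with
  cell-to-cell expression variation,
* TCSPC decay histograms (1- or 2-exponential mixtures convolved with a
  Gaussian IRF plus Poisson noise).

All randomness flows from one integer seed through numpy SeedSequence
spawning keyed by (seed, stream, index), so individual cells and modules
are reproducible in isolation.  Fixed seed => bit-identical output.

``STUDY_PRESETS`` collects the parameter sets of the zebrafish
transcription-factor study the package emulates (blastula-stage GFP-Oct4
concentrations and bound fractions, the mesendoderm/ectoderm Kd values,
donor lifetimes and FLIM binding fractions, and the Atto 488 calibration
constant); these defaults ARE the study conditions used by the recovery
tests and the acceptance script.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .correlation import (
    CorrelationCurve,
    IntensityTrace,
    InvalidParameterError,
)
from .fcs import FcsModelParams, effective_volume, eval_acf_model, molecules_in_focus
from .flim import DecayHistogram, decay_expectation

# molecules per µm^3 at 1 nM
NM_TO_PER_UM3 = 1e-9 * 6.02214076e23 * 1e-15

# parameter sets of the study being emulated (defaults for recovery tests)
STUDY_PRESETS: dict = {
    "w0_um": 0.2,                 # back-projected pinhole radius
    "kappa": 5.0,
    "dye_D_um2_s": 400.0,         # Atto 488 at room temperature
    "free_tauD_s": 3.03e-3,       # global-fit fast diffusion time (GFP-Oct4)
    "bound_tauD_s": 0.1,          # slow (chromatin-interacting) component
    "alpha_free": 1.0,
    "alpha_bound": 0.8,
    "oct4_rescued": {"concentration_nM": 44.39, "f2": 0.27},
    "oct4_nonrescued": {"concentration_nM": 43.90, "f2": 0.19},
    "oct4_delta_hd": {"concentration_nM": 44.0, "f2": 0.12},
    "kd_mesendoderm_nM": 15.34,
    "kd_ectoderm_nM": 61.9,
    "donor_lifetime_ns": 2.30,
    "fret_lifetime_ns": 0.8,
    "binding_mesendoderm": 0.27,
    "binding_ectoderm": 0.022,
}


def spawn_rng(seed: int, *stream: int) -> np.random.Generator:
    """Counter-based seed splitting: one master seed, independent streams."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def _kernel_seed(seed: int, *stream: int) -> int:
    ss = np.random.SeedSequence([int(seed), *map(int, stream)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# mass-action equilibrium
# ---------------------------------------------------------------------------

def solve_equilibrium(total_a: float, total_b: float, kd: float) -> float:
    """Complex concentration at binding equilibrium (all in nM).

    Solves (A_tot - x)(B_tot - x) = Kd * x for the unique root with
    0 <= x <= min(A_tot, B_tot), in the cancellation-free form
    x = 2ab / (s + sqrt(s^2 - 4ab)) with s = a + b + Kd.
    """
    if total_a < 0 or total_b < 0 or kd < 0:
        raise InvalidParameterError("totals and kd must be non-negative")
    if total_a == 0 or total_b == 0:
        return 0.0
    s = total_a + total_b + kd
    disc = s * s - 4.0 * total_a * total_b
    x = 2.0 * total_a * total_b / (s + np.sqrt(max(disc, 0.0)))
    return min(x, total_a, total_b)  # clamp rounding above the physical bound


# ---------------------------------------------------------------------------
# Brownian-dynamics photon traces
# ---------------------------------------------------------------------------

@dataclass
class SimTraceParams:
    """Conditions for a Brownian-dynamics photon-count trace.

    One entry per diffusing species in ``n_molecules_per_species``,
    ``diffusion_coeffs``, ``brightness_per_molecule`` and
    ``species_channels`` ("g", "r" or "gr" for dual-labelled complexes).
    Lengths are µm, times seconds, brightnesses counts/s at focus centre.
    """

    duration: float = 30.0
    dt: float = 2e-6
    box_size: float = 3.0
    n_molecules_per_species: tuple = (16,)
    diffusion_coeffs: tuple = (400.0,)
    brightness_per_molecule: tuple = (30000.0,)
    species_channels: tuple = ("g",)
    w0: float = 0.2
    kappa: float = 5.0
    background_rate: float = 0.0
    bleach_time: Optional[float] = None
    crosstalk_coeff: float = 0.0
    seed: int = 0
    substeps: int = 5

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise InvalidParameterError("duration and dt must be positive")
        if self.dt >= self.duration:
            raise InvalidParameterError("dt must be smaller than duration")
        if self.w0 <= 0 or self.kappa < 1:
            raise InvalidParameterError("need w0 > 0 and kappa >= 1")
        if self.background_rate < 0 or any(b < 0 for b in self.brightness_per_molecule):
            raise InvalidParameterError("rates must be non-negative")
        if not 0.0 <= self.crosstalk_coeff < 1.0:
            raise InvalidParameterError("crosstalk_coeff must be in [0, 1)")
        n = len(self.n_molecules_per_species)
        if not (len(self.diffusion_coeffs) == len(self.brightness_per_molecule)
                == len(self.species_channels) == n):
            raise InvalidParameterError("per-species tuples must have equal length")
        if self.bleach_time is not None and self.bleach_time <= 0:
            raise InvalidParameterError("bleach_time must be positive")
        if self.substeps < 5:
            raise InvalidParameterError("need >= 5 inner steps per bin")

    @property
    def z0(self) -> float:
        return self.kappa * self.w0

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.dt))


# steps are pre-generated per chunk with numpy's ziggurat sampler (much
# faster than drawing scalars inside the kernel); the chunk size is a fixed
# constant so that a given seed always yields the same draw sequence
CHUNK_BINS = 16384


@njit(cache=True, fastmath=True)
def _chunk_rates(steps, x, y, z, substeps, bright_g, bright_r,
                 inv_w02, inv_z02, half_box, rate_g, rate_r, two_channels):
    n_sub = steps.shape[0]
    total = steps.shape[1]
    n_bins = n_sub // substeps
    box = 2.0 * half_box
    for b in range(n_bins):
        rg = 0.0
        rr = 0.0
        for k in range(substeps):
            i = b * substeps + k
            for m in range(total):
                xx = x[m] + steps[i, m, 0]
                yy = y[m] + steps[i, m, 1]
                zz = z[m] + steps[i, m, 2]
                # periodic wrap (single step is always << box)
                if xx >= half_box:
                    xx -= box
                elif xx < -half_box:
                    xx += box
                if yy >= half_box:
                    yy -= box
                elif yy < -half_box:
                    yy += box
                if zz >= half_box:
                    zz -= box
                elif zz < -half_box:
                    zz += box
                x[m] = xx
                y[m] = yy
                z[m] = zz
                w = np.exp(-(xx * xx + yy * yy) * inv_w02 - zz * zz * inv_z02)
                rg += bright_g[m] * w
                if two_channels:
                    rr += bright_r[m] * w
        rate_g[b] = rg / substeps
        if two_channels:
            rate_r[b] = rr / substeps


def simulate_brownian_trace(params: SimTraceParams) -> IntensityTrace:
    """Simulate a binned photon-count trace by Brownian dynamics.

    Molecules take per-axis Gaussian steps of std sqrt(2 D dt_sim)
    (dt_sim = dt / substeps <= dt/5, resolving the focal transit) in a
    periodic box; the detection profile is exp(-2 r^2/w0^2 - 2 z^2/z0^2)
    and counts per bin are Poisson draws on the substep-averaged molecular
    rate plus background.  Photobleaching decays all molecular
    brightnesses exponentially with time constant ``bleach_time``;
    ``crosstalk_coeff`` leaks the green molecular signal into the red
    channel.  Output is bit-identical for a fixed seed.
    """
    p = params
    rng = spawn_rng(p.seed, 1)
    dt_sub = p.dt / p.substeps
    # per-molecule step sigma and channel brightnesses
    sig_mol, bright_g, bright_r = [], [], []
    for n, D, b, ch in zip(p.n_molecules_per_species, p.diffusion_coeffs,
                           p.brightness_per_molecule, p.species_channels):
        sig_mol += [np.sqrt(2.0 * D * dt_sub)] * n
        bright_g += [b if ch in ("g", "gr") else 0.0] * n
        bright_r += [b if ch in ("r", "gr") else 0.0] * n
    sig_mol = np.asarray(sig_mol)
    bright_g = np.asarray(bright_g)
    bright_r = np.asarray(bright_r)
    total = len(sig_mol)
    two_channels = bool(np.any(bright_r > 0) or p.crosstalk_coeff > 0)

    n_bins = p.n_bins
    x = rng.uniform(-0.5, 0.5, total) * p.box_size
    y = rng.uniform(-0.5, 0.5, total) * p.box_size
    z = rng.uniform(-0.5, 0.5, total) * p.box_size
    rate_g = np.empty(n_bins)
    rate_r = np.empty(n_bins) if two_channels else np.empty(0)
    inv_w02 = 2.0 / p.w0 ** 2
    inv_z02 = 2.0 / p.z0 ** 2
    for start in range(0, n_bins, CHUNK_BINS):
        nb = min(CHUNK_BINS, n_bins - start)
        steps = rng.standard_normal((nb * p.substeps, total, 3))
        steps *= sig_mol[None, :, None]
        _chunk_rates(steps, x, y, z, p.substeps, bright_g, bright_r,
                     inv_w02, inv_z02, p.box_size / 2.0,
                     rate_g[start:start + nb],
                     rate_r[start:start + nb] if two_channels else rate_r,
                     two_channels)
    if p.bleach_time is not None:
        t = (np.arange(n_bins) + 0.5) * p.dt
        fade = np.exp(-t / p.bleach_time)
        rate_g *= fade
        if two_channels:
            rate_r *= fade
    lam_g = (rate_g + p.background_rate) * p.dt
    counts_g = rng.poisson(lam_g)
    counts_r = None
    if two_channels:
        lam_r = (rate_r + p.crosstalk_coeff * rate_g + p.background_rate) * p.dt
        counts_r = rng.poisson(lam_r)
    meta = {"simulation": "brownian", "params": p}
    return IntensityTrace(dt=p.dt, counts_g=counts_g, counts_r=counts_r,
                          metadata=meta)


def mean_detection_efficiency(w0: float, kappa: float, box_size: float) -> float:
    """Box average of the 3D Gaussian detection profile (closed form)."""
    from scipy.special import erf
    L = box_size
    z0 = kappa * w0

    def axis(s: float) -> float:
        return s * np.sqrt(np.pi / 2.0) * erf(np.sqrt(2.0) * (L / 2.0) / s) / L

    return axis(w0) ** 2 * axis(z0)


# ---------------------------------------------------------------------------
# model-ACF fast path
# ---------------------------------------------------------------------------

def default_lag_grid(tmin: float = 2e-6, tmax: float = 3.0, n: int = 160) -> np.ndarray:
    """Quasi-logarithmic lag grid spanning the instrument's usable range."""
    return np.geomspace(tmin, tmax, n)


def acf_noise_profile(
    params: FcsModelParams,
    lags: np.ndarray,
    rel_peak: float = 0.04,
    rel_floor: float = 5e-4,
) -> np.ndarray:
    """Per-lag noise sigma emulating a 30-s in-vivo correlation curve.

    The empirical across-segment noise of the Brownian-dynamics pipeline is
    largest at the shortest lags (shot noise, few fluctuations per lag) and
    falls to a small floor in the long-lag tail where thousands of
    fluctuations average; this profile reproduces that shape as
    sigma(tau) = amplitude * (rel_peak * decay(tau) + rel_floor) with
    decay the normalised model curve.
    """
    g = eval_acf_model(params, lags) - params.G_inf
    amp = 1.0 / params.N
    return amp * (rel_peak * g / amp + rel_floor)


def simulate_model_acf(
    fit_params: FcsModelParams,
    lag_grid: Optional[np.ndarray] = None,
    noise_sd: float | np.ndarray | str = "auto",
    seed: int = 0,
    kind: str = "ACF_g",
    mean_intensity: Optional[dict] = None,
) -> CorrelationCurve:
    """Forward-model correlation curve plus zero-mean Gaussian noise.

    The fast path for fit-recovery studies: model values from
    :func:`fcsflim.fcs.eval_acf_model` with per-lag noise of the requested
    sigma, which is recorded in the curve for weighted fitting.
    ``noise_sd="auto"`` uses :func:`acf_noise_profile` with its defaults.
    """
    lags = default_lag_grid() if lag_grid is None else np.asarray(lag_grid, dtype=float)
    g = eval_acf_model(fit_params, lags)
    if isinstance(noise_sd, str):
        if noise_sd != "auto":
            raise InvalidParameterError("noise_sd must be numeric or 'auto'")
        noise_sd = acf_noise_profile(fit_params, lags)
    sigma = np.broadcast_to(np.asarray(noise_sd, dtype=float), lags.shape).copy()
    if np.any(sigma < 0):
        raise InvalidParameterError("noise sd must be non-negative")
    if np.any(sigma > 0):
        g = g + spawn_rng(seed, 2).normal(0.0, sigma)
    return CorrelationCurve(
        lags=lags, G=g, sigma=sigma if np.any(sigma > 0) else None, kind=kind,
        mean_intensity=dict(mean_intensity or {}),
        metadata={"simulation": "model_acf", "truth": fit_params},
    )


# ---------------------------------------------------------------------------
# dual-color binding ensembles
# ---------------------------------------------------------------------------

@dataclass
class BindingEnsembleParams:
    """Cell ensemble in binding equilibrium at a prescribed Kd.

    Per-cell total concentrations are drawn log-uniformly over the stated
    ranges (the expression spread across nuclei is not known for the real
    embryos; log-uniform is a documented stand-in).  The complex
    co-diffuses in both channels with ``complex_diffusion``.
    """

    n_cells: int = 15
    total_green_range: tuple = (20.0, 150.0)    # nM
    total_red_range: tuple = (20.0, 150.0)      # nM
    kd: float = 15.34                           # nM
    complex_diffusion: float = 0.3              # µm²/s
    free_diffusion: float = 3.3                 # µm²/s
    seed: int = 0
    w0: float = 0.2
    kappa: float = 5.0
    noise_sd_rel: float = 0.04                  # peak per-lag sigma / curve amplitude
    brightness: float = 10000.0                 # counts/s per molecule
    crosstalk_coeff: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise InvalidParameterError("n_cells must be >= 2")
        if self.kd < 0:
            raise InvalidParameterError("kd must be non-negative")
        for r in (self.total_green_range, self.total_red_range):
            if r[0] <= 0 or r[1] < r[0]:
                raise InvalidParameterError("concentration ranges must be positive")
        if not 0.0 <= self.crosstalk_coeff < 1.0:
            raise InvalidParameterError("crosstalk_coeff must be in [0, 1)")


@dataclass
class DualColorCell:
    """One simulated cell: curves (or trace) plus generating ground truth."""

    cell_id: str
    curves: dict = field(default_factory=dict)   # kind -> CorrelationCurve
    trace: Optional[IntensityTrace] = None
    truth: dict = field(default_factory=dict)


def _tau_from_D(D: float, w0: float) -> float:
    return w0 ** 2 / (4.0 * D)


def apply_crosstalk_to_curves(
    curves: dict,
    bleedthrough: float,
    f_g: float,
    f_r_true: float,
) -> tuple[dict, dict]:
    """Forward spectral bleed-through mixing of a (ACF_g, ACF_r, CCF) triplet.

    The measured red signal is r = r_true + kappa_bt * g; covariances mix
    accordingly and the measured curves are renormalised by the measured
    mean intensities.  Returns (measured curves, measured intensities).
    """
    k = bleedthrough
    g_g = curves["ACF_g"].G
    g_r = curves["ACF_r"].G
    g_x = curves["CCF"].G
    cov_gg = g_g * f_g ** 2
    cov_rr = g_r * f_r_true ** 2
    cov_gr = g_x * f_g * f_r_true
    f_r_meas = f_r_true + k * f_g
    cov_gr_m = cov_gr + k * cov_gg
    cov_rr_m = cov_rr + 2 * k * cov_gr + k * k * cov_gg
    out = {
        "ACF_g": curves["ACF_g"],
        "ACF_r": _replace_G(curves["ACF_r"], cov_rr_m / f_r_meas ** 2),
        "CCF": _replace_G(curves["CCF"], cov_gr_m / (f_g * f_r_meas)),
    }
    intensities = {"g": f_g, "r": f_r_meas}
    for c in out.values():
        c.mean_intensity = dict(intensities)
    return out, intensities


def _replace_G(curve: CorrelationCurve, G: np.ndarray) -> CorrelationCurve:
    return CorrelationCurve(lags=curve.lags.copy(), G=G, sigma=curve.sigma,
                            kind=curve.kind, mean_intensity=dict(curve.mean_intensity),
                            metadata=dict(curve.metadata))


def simulate_binding_ensemble(
    params: BindingEnsembleParams,
    output: str = "curves",
    lag_grid: Optional[np.ndarray] = None,
    trace_kwargs: Optional[dict] = None,
) -> list[DualColorCell]:
    """Simulate per-cell dual-color measurements at binding equilibrium.

    For each cell, total concentrations are drawn, the complex
    concentration follows from mass action (so the ground-truth triple
    satisfies C_free_g * C_free_r = Kd * C_complex exactly), and either
    noisy model curves (``output="curves"``, the fast path) or a
    dual-channel Brownian trace (``output="traces"``) are emitted with the
    complex co-diffusing in both channels.
    """
    if output not in ("curves", "traces"):
        raise InvalidParameterError("output must be 'curves' or 'traces'")
    p = params
    rng = spawn_rng(p.seed, 3)
    v_eff = effective_volume(p.w0, p.kappa)
    n_per_nM = molecules_in_focus(1.0, v_eff)
    tau_free = _tau_from_D(p.free_diffusion, p.w0)
    tau_cplx = _tau_from_D(p.complex_diffusion, p.w0)
    lags = default_lag_grid() if lag_grid is None else np.asarray(lag_grid, float)

    cells: list[DualColorCell] = []
    for i in range(p.n_cells):
        lo, hi = p.total_green_range
        cg_tot = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        lo, hi = p.total_red_range
        cr_tot = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        cc = solve_equilibrium(cg_tot, cr_tot, p.kd)
        truth = {
            "C_total_g": cg_tot, "C_total_r": cr_tot,
            "C_free_g": cg_tot - cc, "C_free_r": cr_tot - cc,
            "C_complex": cc, "kd": p.kd, "w0": p.w0, "kappa": p.kappa,
            "V_eff_fl": v_eff,
        }
        cell = DualColorCell(cell_id=f"cell{i:03d}", truth=truth)
        if output == "curves":
            cell.curves = _ensemble_cell_curves(
                p, cg_tot, cr_tot, cc, n_per_nM, tau_free, tau_cplx, lags,
                seed_stream=(3, i),
            )
        else:
            cell.trace = _ensemble_cell_trace(p, cg_tot, cr_tot, cc,
                                              trace_kwargs or {}, stream=i)
        cells.append(cell)
    return cells


def _ensemble_cell_curves(p, cg_tot, cr_tot, cc, n_per_nM, tau_free, tau_cplx,
                          lags, seed_stream):
    f_g = p.brightness * cg_tot * n_per_nM
    f_r = p.brightness * cr_tot * n_per_nM
    amp_g = 1.0 / (n_per_nM * cg_tot)
    amp_r = 1.0 / (n_per_nM * cr_tot)
    amp_x = cc / (n_per_nM * cg_tot * cr_tot)
    curves = {}
    specs = [
        ("ACF_g", amp_g, cc / cg_tot),
        ("ACF_r", amp_r, cc / cr_tot),
    ]
    for j, (kind, amp, f2) in enumerate(specs):
        mp = FcsModelParams(N=1.0 / amp, F2=f2, tauD1=tau_free, tauD2=tau_cplx,
                            alpha1=1.0, alpha2=1.0, kappa=p.kappa)
        curves[kind] = simulate_model_acf(
            mp, lags, noise_sd=0.0, kind=kind)
    if amp_x > 0:
        mx = FcsModelParams(N=1.0 / amp_x, F2=0.0, tauD1=tau_cplx, kappa=p.kappa)
        curves["CCF"] = simulate_model_acf(mx, lags, noise_sd=0.0, kind="CCF")
    else:
        curves["CCF"] = CorrelationCurve(lags=lags, G=np.zeros_like(lags),
                                         kind="CCF")
    # optional bleed-through mixing before the noise is drawn
    if p.crosstalk_coeff > 0:
        curves, intensities = apply_crosstalk_to_curves(
            curves, p.crosstalk_coeff, f_g, f_r)
    else:
        intensities = {"g": f_g, "r": f_r}
        for c in curves.values():
            c.mean_intensity = dict(intensities)
    # per-lag noise: shaped like the measured segment noise of the Brownian
    # pipeline (largest at short lags, small floor in the tail); the CCF
    # noise scale is set by the ACF amplitudes (photon noise), not by the
    # CCF amplitude, so a zero-complex CCF still carries realistic noise
    rng = spawn_rng(p.seed, *seed_stream)
    shape_g = curves["ACF_g"].G / max(float(curves["ACF_g"].G[0]), 1e-12)
    amp_scale = {"ACF_g": amp_g, "ACF_r": amp_r, "CCF": np.sqrt(amp_g * amp_r)}
    for kind, c in curves.items():
        g0 = float(c.G[0])
        shape = c.G / g0 if g0 > 1e-12 else shape_g
        sigma = amp_scale[kind] * (p.noise_sd_rel * shape + 5e-4)
        sigma = np.clip(sigma, 1e-12, None)
        c.G = c.G + rng.normal(0.0, 1.0, size=len(c.G)) * sigma
        c.sigma = sigma
    return curves


def _ensemble_cell_trace(p, cg_tot, cr_tot, cc, trace_kwargs, stream):
    box = trace_kwargs.get("box_size", 3.0)
    per_nM = NM_TO_PER_UM3 * box ** 3
    n_free_g = max(int(round((cg_tot - cc) * per_nM)), 0)
    n_free_r = max(int(round((cr_tot - cc) * per_nM)), 0)
    n_cplx = max(int(round(cc * per_nM)), 0)
    sp = SimTraceParams(
        duration=trace_kwargs.get("duration", 10.0),
        dt=trace_kwargs.get("dt", 1e-5),
        box_size=box,
        n_molecules_per_species=(n_free_g, n_free_r, n_cplx),
        diffusion_coeffs=(p.free_diffusion, p.free_diffusion, p.complex_diffusion),
        brightness_per_molecule=(p.brightness,) * 3,
        species_channels=("g", "r", "gr"),
        w0=p.w0, kappa=p.kappa,
        crosstalk_coeff=p.crosstalk_coeff,
        seed=_kernel_seed(p.seed, 4, stream),
        substeps=trace_kwargs.get("substeps", 5),
    )
    return simulate_brownian_trace(sp)


# ---------------------------------------------------------------------------
# TCSPC decays
# ---------------------------------------------------------------------------

@dataclass
class DecaySimParams:
    """Conditions for a synthetic TCSPC decay histogram.

    ``amplitude_fractions`` are pre-exponential amplitudes (sum to 1), so a
    component contributes photons in proportion to a_i * tau_i; this is the
    quantity the amplitude-derived binding percentage reports.
    """

    lifetimes: tuple = (2.30,)
    amplitude_fractions: tuple = (1.0,)
    total_counts: float = 1e6
    n_bins: int = 1250
    window: float = 25.0          # ns
    irf_fwhm: float = 0.3         # ns
    irf_shift: float = 2.0        # ns
    background_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(tau <= 0 for tau in self.lifetimes):
            raise InvalidParameterError("lifetimes must be positive")
        fr = np.asarray(self.amplitude_fractions, dtype=float)
        if len(fr) != len(self.lifetimes):
            raise InvalidParameterError("one amplitude fraction per lifetime")
        if np.any(fr < 0) or np.any(fr > 1) or abs(fr.sum() - 1.0) > 1e-9:
            raise InvalidParameterError("fractions must lie in [0,1] and sum to 1")
        if self.window <= max(self.lifetimes):
            raise InvalidParameterError("window must exceed the longest lifetime")
        if self.total_counts <= 0 or self.n_bins < 2:
            raise InvalidParameterError("need positive counts and >= 2 bins")
        if not 0.0 <= self.background_fraction < 1.0:
            raise InvalidParameterError("background_fraction must be in [0, 1)")


def simulate_tcspc_decay(params: DecaySimParams) -> DecayHistogram:
    """Poisson TCSPC histogram of an IRF-convolved exponential mixture.

    The expectation is the amplitude-fraction mixture convolved with a
    Gaussian IRF plus a flat background; expected total counts equal
    ``total_counts`` exactly.  A window shorter than 3x the longest
    lifetime triggers a truncation-bias warning.
    """
    p = params
    if p.window < 3.0 * max(p.lifetimes):
        warnings.warn("window < 3x longest lifetime: truncation bias likely",
                      stacklevel=2)
    bw = p.window / p.n_bins
    t = (np.arange(p.n_bins) + 0.5) * bw
    dens = decay_expectation(t, p.lifetimes, p.amplitude_fractions,
                             p.irf_fwhm, p.irf_shift)
    total_dens = dens.sum()
    signal = (1.0 - p.background_fraction) * p.total_counts
    mu = signal * dens / total_dens + p.background_fraction * p.total_counts / p.n_bins
    counts = spawn_rng(p.seed, 5).poisson(mu)
    return DecayHistogram(
        bin_time=bw, counts=counts,
        irf={"fwhm_ns": p.irf_fwhm, "shift_ns": p.irf_shift},
        metadata={"simulation": "tcspc", "truth": p},
    )
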