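"""Anomalous-diffusion model fitting of FCS correlation curves.

The forward model for a two-component anomalous-diffusion ACF through a 3D
Gaussian focus with structure parameter kappa = z0/w0 is

    G(tau) = G_inf + (1/N) * sum_i F_i * [1 + (tau/tauD_i)^alpha_i]^-1
                                   * [1 + (tau/tauD_i)^alpha_i / kappa^2]^-1/2

with F_1 + F_2 = 1.  N is the mean number of molecules in the effective
volume V_eff = pi^(3/2) w0^2 z0, so the absolute concentration is
C = N / (N_A V_eff) and the diffusion coefficients D_i = w0^2 / (4 tauD_i).
The slow fraction F_2 is reported as the DNA-bound fraction of the tagged
transcription factor; the anomaly exponents alpha_i < 1 capture
subdiffusion from transient chromatin interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
from scipy.constants import Avogadro
from scipy.optimize import minimize_scalar

from .correlation import CorrelationCurve, InvalidInputError, InvalidParameterError

# default parameter bounds: bracket free-GFP and chromatin-bound regimes.
# For known pure-diffusion samples (calibration dyes) pass
# bounds={"alpha": DYE_ALPHA_BOUNDS}: superdiffusive alpha is meaningless
# there and opens an alpha/tauD tradeoff that scatters the fitted decay time.
TAU1_BOUNDS = (10e-6, 50e-3)
TAU2_BOUNDS = (1e-3, 10.0)
ALPHA_BOUNDS = (0.2, 2.0)
DYE_ALPHA_BOUNDS = (0.2, 1.0)
MODEL_ALPHA_MAX = 2.0
DEFAULT_KAPPA = 5.0
# two-component fit collapses to one effective component when:
COLLAPSE_F2 = 0.05
COLLAPSE_TAU_RATIO = 3.0


@dataclass
class FcsModelParams:
    """Parameters of the (one- or) two-component anomalous-diffusion ACF."""

    N: float
    F2: float = 0.0
    tauD1: float = 1e-3
    tauD2: float = 30e-3
    alpha1: float = 1.0
    alpha2: float = 1.0
    G_inf: float = 0.0
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise InvalidParameterError("N must be positive")
        if not 0.0 <= self.F2 <= 1.0:
            raise InvalidParameterError("F2 must lie in [0, 1]")
        if self.tauD1 <= 0 or self.tauD2 <= 0:
            raise InvalidParameterError("diffusion times must be positive")
        if self.kappa < 1:
            raise InvalidParameterError("kappa must be >= 1")
        for a in (self.alpha1, self.alpha2):
            if not ALPHA_BOUNDS[0] < a <= MODEL_ALPHA_MAX:
                raise InvalidParameterError(
                    f"alpha must lie in ({ALPHA_BOUNDS[0]}, {MODEL_ALPHA_MAX}]"
                )

    @property
    def F1(self) -> float:
        return 1.0 - self.F2


@dataclass
class CalibrationResult:
    """Focal-volume calibration from a reference dye of known D."""

    w0: float              # µm, lateral 1/e^2 radius
    z0: float              # µm, axial 1/e^2 radius (kappa * w0)
    V_eff: float           # femtoliters (1 µm^3 == 1 fl)
    tauD_dye: float        # s
    dye_D: float           # µm^2/s
    channel: str = "g"

    def __post_init__(self) -> None:
        if self.w0 <= 0 or self.z0 < self.w0:
            raise InvalidParameterError("need w0 > 0 and z0 >= w0")

    @property
    def kappa(self) -> float:
        return self.z0 / self.w0


@dataclass
class AnomalousDiffusionFit:
    """Result of fitting a correlation curve.

    ``concentration`` (nM) and ``D1``/``D2`` (µm²/s) are populated by
    :func:`derive_physical` once a calibration is available.
    """

    params: FcsModelParams
    chi2_reduced: float
    se: dict = field(default_factory=dict)
    success: bool = True
    message: str = ""
    n_components_effective: int = 2
    model: str = "two"
    concentration: Optional[float] = None
    D1: Optional[float] = None
    D2: Optional[float] = None
    mean_intensity: dict = field(default_factory=dict)
    weighted: bool = False


@dataclass
class BrightnessQC:
    """Molecular-brightness quality control against a reference channel."""

    brightness: float      # counts/s per molecule
    reference: float
    ratio: float
    passed: bool


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _component(tau: np.ndarray, tauD: float, alpha: float, kappa: float) -> np.ndarray:
    x = (tau / tauD) ** alpha
    return 1.0 / (1.0 + x) / np.sqrt(1.0 + x / kappa ** 2)


def eval_acf_model(params: FcsModelParams, lags: Sequence[float]) -> np.ndarray:
    """Evaluate the anomalous-diffusion ACF model on a lag grid (seconds)."""
    tau = np.asarray(lags, dtype=float)
    if np.any(tau <= 0):
        raise InvalidParameterError("lags must be positive")
    g = params.F1 * _component(tau, params.tauD1, params.alpha1, params.kappa)
    if params.F2 > 0:
        g = g + params.F2 * _component(tau, params.tauD2, params.alpha2, params.kappa)
    return params.G_inf + g / params.N


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _initial_guess(curve: CorrelationCurve) -> dict:
    """Method-of-moments start: amplitude -> N, half-decay lag -> tauD."""
    G = curve.G
    tail = float(np.mean(G[-max(len(G) // 10, 3):]))
    amp = float(G[0]) - tail
    if amp <= 0:
        amp = max(float(np.max(G)) - tail, 1e-6)
    half = tail + 0.5 * amp
    below = np.nonzero(G < half)[0]
    tau_half = float(curve.lags[below[0]]) if len(below) else float(curve.lags[len(curve) // 2])
    return {"N": 1.0 / amp, "ginf": tail, "tau_half": tau_half, "amp": amp}


def _result_params(p: lmfit.Parameters, kappa: float, model: str) -> FcsModelParams:
    f2 = float(p["F2"].value) if model == "two" else 0.0
    tau1 = float(p["tauD1"].value)
    tau2 = float(p["tauD2"].value) if model == "two" else tau1 * 10
    a1 = float(p["alpha1"].value)
    a2 = float(p["alpha2"].value) if model == "two" else a1
    # ordering convention: tauD1 < tauD2 (relabel if the optimizer swapped)
    if model == "two" and tau1 > tau2:
        tau1, tau2 = tau2, tau1
        a1, a2 = a2, a1
        f2 = 1.0 - f2
    return FcsModelParams(
        N=float(p["N"].value), F2=f2, tauD1=tau1, tauD2=tau2,
        alpha1=a1, alpha2=a2, G_inf=float(p["G_inf"].value), kappa=kappa,
    )


def _make_parameters(
    curve: CorrelationCurve,
    model: str,
    kappa: float,
    init: Optional[dict],
    bounds: Optional[dict],
    fix_tauD1: Optional[float] = None,
    fix_alpha: Optional[float] = None,
) -> lmfit.Parameters:
    mom = _initial_guess(curve)
    b = {"tauD1": TAU1_BOUNDS, "tauD2": TAU2_BOUNDS, "alpha": ALPHA_BOUNDS}
    if bounds:
        b.update(bounds)
    init = dict(init or {})
    # normalize component labels in the start values (tauD1 < tauD2) so a
    # label-swapped init runs the identical optimization
    if init.get("tauD1") is not None and init.get("tauD2") is not None \
            and init["tauD1"] > init["tauD2"]:
        init["tauD1"], init["tauD2"] = init["tauD2"], init["tauD1"]
        if "F2" in init:
            init["F2"] = 1.0 - init["F2"]
        a1, a2 = init.get("alpha1"), init.get("alpha2")
        if a1 is not None or a2 is not None:
            init["alpha1"], init["alpha2"] = a2 or 1.0, a1 or 1.0
    for key, bb in (("tauD1", b["tauD1"]), ("tauD2", b["tauD2"])):
        if key in init:
            init[key] = float(np.clip(init[key], *bb))
    p = lmfit.Parameters()
    p.add("N", value=init.get("N", mom["N"]), min=1e-4, max=1e7)
    tau1_0 = init.get("tauD1", np.clip(mom["tau_half"] / 2, *b["tauD1"]))
    p.add("tauD1", value=tau1_0, min=b["tauD1"][0], max=b["tauD1"][1],
          vary=fix_tauD1 is None)
    if fix_tauD1 is not None:
        p["tauD1"].set(value=fix_tauD1)
    # start strictly inside the bounds: lmfit's bound transform has zero
    # gradient at the boundary and would freeze the parameter there
    def _inside(v, lo, hi):
        return float(np.clip(v, lo + 1e-3 * (hi - lo), hi - 1e-3 * (hi - lo)))

    a0 = init.get("alpha1", 1.0 if fix_alpha is None else fix_alpha)
    p.add("alpha1", value=_inside(a0, *b["alpha"]) if fix_alpha is None else a0,
          min=b["alpha"][0], max=b["alpha"][1], vary=fix_alpha is None)
    # baseline bounded to a fraction of the amplitude (fitted by default)
    gmax = 0.1 * max(mom["amp"], 1e-6)
    p.add("G_inf", value=np.clip(init.get("G_inf", mom["ginf"]), -gmax, gmax),
          min=-gmax, max=gmax)
    if model == "two":
        p.add("F2", value=init.get("F2", 0.3), min=0.0, max=1.0)
        p.add("tauD2", value=init.get("tauD2", np.clip(mom["tau_half"] * 20, *b["tauD2"])),
              min=b["tauD2"][0], max=b["tauD2"][1])
        a2_0 = init.get("alpha2", 1.0 if fix_alpha is None else fix_alpha)
        p.add("alpha2", value=_inside(a2_0, *b["alpha"]) if fix_alpha is None else a2_0,
              min=b["alpha"][0], max=b["alpha"][1], vary=fix_alpha is None)
    return p


def _residual_factory(curve: CorrelationCurve, kappa: float, model: str):
    lags = curve.lags
    G = curve.G
    use_sigma = curve.sigma is not None and np.all(curve.sigma > 0)
    sigma = curve.sigma if use_sigma else None

    def residual(p: lmfit.Parameters) -> np.ndarray:
        f2 = p["F2"].value if model == "two" else 0.0
        x1 = (lags / p["tauD1"].value) ** p["alpha1"].value
        g = (1.0 - f2) / (1.0 + x1) / np.sqrt(1.0 + x1 / kappa ** 2)
        if model == "two":
            x2 = (lags / p["tauD2"].value) ** p["alpha2"].value
            g = g + f2 / (1.0 + x2) / np.sqrt(1.0 + x2 / kappa ** 2)
        m = p["G_inf"].value + g / p["N"].value
        r = m - G
        return r / sigma if use_sigma else r

    return residual, use_sigma


def fit_acf(
    curve: CorrelationCurve,
    model: str = "two",
    init: Optional[dict] = None,
    bounds: Optional[dict] = None,
    kappa: float = DEFAULT_KAPPA,
    kappa_policy: str = "fixed",
    fix_tauD1: Optional[float] = None,
    fix_alpha: Optional[float] = None,
) -> AnomalousDiffusionFit:
    """Weighted least-squares fit of a correlation curve.

    Weights are 1/sigma^2 when the curve carries per-lag noise estimates,
    otherwise the fit is unweighted.  Non-convergence and non-positive
    amplitudes yield a flagged result (``success=False``), never an
    exception.  Components are relabelled after the fit so tauD1 < tauD2;
    the fit is declared effectively one-component when F2 < 0.05 or
    tauD2/tauD1 < 3.
    """
    if model not in ("one", "two"):
        raise InvalidParameterError("model must be 'one' or 'two'")
    if kappa_policy != "fixed":
        raise InvalidParameterError("only kappa_policy='fixed' is supported")
    if len(curve) < 30:
        raise InvalidInputError("curve must have >= 30 lags")
    if curve.lags[-1] / curve.lags[0] < 1e4:
        raise InvalidInputError("curve must span >= 4 decades of lag")

    mom = _initial_guess(curve)
    if mom["amp"] <= 1e-6 and float(np.max(curve.G)) <= 0:
        params = FcsModelParams(N=1e6, kappa=kappa)
        return AnomalousDiffusionFit(
            params=params, chi2_reduced=np.nan, success=False,
            message="no positive correlation amplitude", model=model,
            n_components_effective=0, mean_intensity=dict(curve.mean_intensity),
        )

    p = _make_parameters(curve, model, kappa, init, bounds, fix_tauD1, fix_alpha)
    residual, weighted = _residual_factory(curve, kappa, model)
    try:
        out = lmfit.minimize(residual, p, method="leastsq")
        success = bool(out.success)
        message = str(out.message)
    except Exception as exc:  # pragma: no cover - lmfit rarely raises here
        out = None
        success = False
        message = f"optimizer failure: {exc}"
    if out is None:
        params = FcsModelParams(N=mom["N"], kappa=kappa)
        return AnomalousDiffusionFit(
            params=params, chi2_reduced=np.nan, success=False, message=message,
            model=model, mean_intensity=dict(curve.mean_intensity),
        )

    params = _result_params(out.params, kappa, model)
    se = {k: (float(v.stderr) if v.stderr is not None else np.nan)
          for k, v in out.params.items() if v.vary}
    ndata = len(curve)
    nvary = sum(1 for v in out.params.values() if v.vary)
    chi2_red = float(np.sum(out.residual ** 2) / max(ndata - nvary, 1))
    n_eff = 2
    if model == "one":
        n_eff = 1
    elif params.F2 < COLLAPSE_F2 or params.tauD2 / params.tauD1 < COLLAPSE_TAU_RATIO:
        n_eff = 1
    return AnomalousDiffusionFit(
        params=params, chi2_reduced=chi2_red, se=se, success=success,
        message=message, n_components_effective=n_eff, model=model,
        mean_intensity=dict(curve.mean_intensity), weighted=weighted,
    )


def fit_acf_global(
    curves: Sequence[CorrelationCurve],
    model: str = "two",
    kappa: float = DEFAULT_KAPPA,
    tauD1_bounds: tuple = TAU1_BOUNDS,
) -> tuple[list[AnomalousDiffusionFit], float, float]:
    """Global fit with a single shared fast diffusion time tauD1.

    The shared tauD1 is profiled: for each candidate value every curve is
    refit with tauD1 pinned and all other parameters free, and the summed
    weighted residual is minimised over tauD1 (bounded scalar search on
    log tauD1).  With the free diffusion time fixed at the optimum, all
    remaining parameters are recalculated per curve.

    Returns ``(fits, tauD1_shared, tauD1_se)``; the standard error comes
    from the curvature of the profiled objective, scaled by the reduced
    chi-square for unweighted data.
    """
    if len(curves) < 1:
        raise InvalidInputError("need at least one curve")
    if len(curves) == 1:
        fit = fit_acf(curves[0], model=model, kappa=kappa)
        se = fit.se.get("tauD1", np.nan)
        return [fit], fit.params.tauD1, se

    def fits_at(tau1: float) -> list[AnomalousDiffusionFit]:
        # deterministic method-of-moments starts: warm-starting from the
        # free individual fits parks the optimizer on the F2/tauD2/alpha
        # ridge those fits wander along
        return [fit_acf(c, model=model, kappa=kappa, fix_tauD1=tau1)
                for c in curves]

    def total_chi2(log_tau1: float) -> float:
        fits = fits_at(float(np.exp(log_tau1)))
        ndata = sum(len(c) for c in curves)
        return sum(f.chi2_reduced * max(len(c) - _nvary(f), 1)
                   for f, c in zip(fits, curves)) / 1.0

    def _nvary(f: AnomalousDiffusionFit) -> int:
        return len(f.se)

    lo, hi = np.log(tauD1_bounds[0]), np.log(tauD1_bounds[1])
    res = minimize_scalar(total_chi2, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-3})
    tau1 = float(np.exp(res.x))
    fits = fits_at(tau1)

    # curvature-based SE on the profiled objective
    h = 0.02
    try:
        f0 = float(res.fun)
        fp = total_chi2(res.x + h)
        fm = total_chi2(res.x - h)
        d2 = (fp - 2 * f0 + fm) / h ** 2
        ndata = sum(len(c) for c in curves)
        nvary = sum(_nvary(f) for f in fits) + 1
        scale = f0 / max(ndata - nvary, 1)  # ~1 for correctly weighted data
        se = tau1 * np.sqrt(2.0 * scale / d2) if d2 > 0 else np.nan
    except Exception:  # pragma: no cover
        se = np.nan
    return fits, tau1, float(se)


# ---------------------------------------------------------------------------
# calibration and physical quantities
# ---------------------------------------------------------------------------

def calibrate_focus(
    dye_curve: CorrelationCurve,
    known_D: float,
    kappa: float = DEFAULT_KAPPA,
    channel: str = "g",
) -> CalibrationResult:
    """Calibrate the focal volume from a reference dye of known D.

    The dye curve is fit with a pure-diffusion one-component model
    (alpha fixed at 1); then w0 = sqrt(4 D tauD_dye) and
    V_eff = pi^(3/2) kappa w0^3.  A dye curve showing two-component
    structure triggers a warning and is fit with one component anyway.
    """
    if known_D <= 0:
        raise InvalidParameterError("known_D must be positive")
    probe = fit_acf(dye_curve, model="two", kappa=kappa)
    if probe.success and probe.n_components_effective == 2:
        warnings.warn("reference dye curve shows two-component structure; "
                      "fitting one component for calibration", stacklevel=2)
    fit = fit_acf(dye_curve, model="one", kappa=kappa, fix_alpha=1.0)
    if not fit.success:
        raise InvalidInputError(f"dye curve fit failed: {fit.message}")
    tauD = fit.params.tauD1
    w0 = float(np.sqrt(4.0 * known_D * tauD))
    z0 = kappa * w0
    v_eff = float(np.pi ** 1.5 * kappa * w0 ** 3)  # µm^3 == fl
    return CalibrationResult(w0=w0, z0=z0, V_eff=v_eff, tauD_dye=tauD,
                             dye_D=known_D, channel=channel)


def effective_volume(w0: float, kappa: float) -> float:
    """V_eff = pi^(3/2) w0^2 z0 in femtoliters (w0 in µm)."""
    return float(np.pi ** 1.5 * kappa * w0 ** 3)


def concentration_nM(N: float, v_eff_fl: float) -> float:
    """Convert molecules-in-focus to nanomolar: C = N / (N_A V_eff)."""
    return N / (Avogadro * v_eff_fl * 1e-15) * 1e9


def molecules_in_focus(c_nM: float, v_eff_fl: float) -> float:
    """Inverse of :func:`concentration_nM`."""
    return c_nM * 1e-9 * Avogadro * v_eff_fl * 1e-15


def derive_physical(fit: AnomalousDiffusionFit, calib: CalibrationResult) -> AnomalousDiffusionFit:
    """Fill concentration (nM) and diffusion coefficients (µm²/s) in place."""
    if calib is None:
        raise InvalidParameterError("calibration required")
    fit.concentration = concentration_nM(fit.params.N, calib.V_eff)
    fit.D1 = calib.w0 ** 2 / (4.0 * fit.params.tauD1)
    fit.D2 = calib.w0 ** 2 / (4.0 * fit.params.tauD2)
    return fit


def brightness_qc(
    mean_intensity: float,
    fitted_N: float,
    reference_brightness: float,
    window: float = 0.10,
) -> BrightnessQC:
    """Molecular-brightness QC: <I>/N within +-10% of the reference.

    Mean intensity is robust to optical aberrations while the fitted N is
    not, so their ratio flags measurements whose focal volume was distorted
    by refractive-index mismatch.
    """
    if fitted_N <= 0:
        raise InvalidParameterError("fitted N must be positive")
    if reference_brightness <= 0:
        raise InvalidParameterError("reference brightness must be positive")
    brightness = mean_intensity / fitted_N
    ratio = brightness / reference_brightness
    return BrightnessQC(brightness=brightness, reference=reference_brightness,
                        ratio=ratio, passed=abs(ratio - 1.0) <= window)
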