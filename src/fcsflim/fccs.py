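"""Dual-color cross-correlation: complex concentrations and Kd estimation.

For a cell expressing a GFP-tagged and an mCherry-tagged factor, the
zero-lag amplitudes of the two ACFs and the CCF give absolute
concentrations (V the effective/overlap volume, N_A Avogadro's number):

    C_total_g = 1 / (G_g0 N_A V_g)
    C_total_r = 1 / (G_r0 N_A V_r)
    C_complex = G_x0 / (G_g0 G_r0 N_A V_x)

Free concentrations are totals minus complex.  Across an ensemble of cells
in binding equilibrium, mass action gives C_free_g * C_free_r = Kd *
C_complex, so regressing the product of free concentrations on the complex
concentration through the origin yields Kd as the slope.  Cells with no
association show no linear relationship ("N.L").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .correlation import CorrelationCurve, InvalidInputError, InvalidParameterError
from .fcs import (
    AnomalousDiffusionFit,
    CalibrationResult,
    fit_acf,
    molecules_in_focus,
)

R2_LINEAR_THRESHOLD = 0.5


class CellRejected(InvalidInputError):
    """A cell failed amplitude QC and is excluded with a reason."""


@dataclass
class DualColorResult:
    """Per-cell free/complex concentrations and association fraction."""

    cell_id: str
    C_free_g: float           # nM
    C_free_r: float           # nM
    C_complex: float          # nM
    association_pct: float
    qc_pass: bool = True
    floored: bool = False     # free concentration was clipped at 0
    notes: str = ""

    @property
    def C_total_g(self) -> float:
        return self.C_free_g + self.C_complex

    @property
    def C_total_r(self) -> float:
        return self.C_free_r + self.C_complex


@dataclass
class KdEstimate:
    """Slope-of-the-line dissociation constant across a cell ensemble."""

    kd: Optional[float]       # nM; None when no linear relationship
    se: Optional[float]
    r_squared: float
    n_cells: int
    linear: bool

    def __str__(self) -> str:
        if not self.linear:
            return f"N.L (r^2={self.r_squared:.2f}, n={self.n_cells})"
        return f"Kd = {self.kd:.2f} +- {self.se:.2f} nM (n={self.n_cells})"


# ---------------------------------------------------------------------------
# spectral cross-talk
# ---------------------------------------------------------------------------

def correct_crosstalk(
    amp_g: float,
    amp_r: float,
    amp_x: float,
    bleedthrough: float,
    intensity_g: float,
    intensity_r: float,
) -> tuple[float, float, float]:
    """Correct red-channel and cross-correlation amplitudes for bleed-through.

    ``bleedthrough`` is the donor-only ratio of red to green detected
    intensity.  The measured red signal is r = r_true + k*g; undoing the
    mixing on the covariance amplitudes (cov = G * product of means):

        F_r_true    = F_r - k F_g
        cov_gr_true = cov_gr - k cov_gg
        cov_rr_true = cov_rr - 2 k cov_gr_true - k^2 cov_gg

    Returns ``(amp_r_corrected, amp_x_corrected, intensity_r_corrected)``;
    the green channel is unchanged.
    """
    if not 0.0 <= bleedthrough < 1.0:
        raise InvalidParameterError("bleedthrough must be in [0, 1)")
    if bleedthrough == 0.0:
        return amp_r, amp_x, intensity_r
    k = bleedthrough
    f_g, f_r = intensity_g, intensity_r
    f_r_true = f_r - k * f_g
    if f_r_true <= 0:
        raise CellRejected("red intensity fully explained by bleed-through")
    cov_gg = amp_g * f_g ** 2
    cov_gr = amp_x * f_g * f_r
    cov_rr = amp_r * f_r ** 2
    cov_gr_true = cov_gr - k * cov_gg
    cov_rr_true = cov_rr - 2 * k * cov_gr_true - k * k * cov_gg
    return (cov_rr_true / f_r_true ** 2,
            cov_gr_true / (f_g * f_r_true),
            f_r_true)


# ---------------------------------------------------------------------------
# amplitudes -> concentrations
# ---------------------------------------------------------------------------

def amplitudes_to_concentrations(
    G_g0: float,
    G_r0: float,
    G_x0: float,
    calib_g: CalibrationResult,
    calib_r: CalibrationResult,
    overlap_volume: Optional[float] = None,
    cell_id: str = "",
) -> DualColorResult:
    """Convert offset-subtracted, cross-talk-corrected amplitudes to nM.

    ``overlap_volume`` defaults to the green-channel V_eff.  Negative free
    concentrations (amplitude noise near full association) are floored at 0
    and flagged.  Non-positive ACF amplitudes reject the cell.
    """
    if G_g0 <= 0 or G_r0 <= 0:
        raise CellRejected(f"non-positive ACF amplitude (g={G_g0:g}, r={G_r0:g})")
    v_x = calib_g.V_eff if overlap_volume is None else overlap_volume
    total_g = 1.0 / (G_g0 * molecules_in_focus(1.0, calib_g.V_eff))
    total_r = 1.0 / (G_r0 * molecules_in_focus(1.0, calib_r.V_eff))
    c_complex = max(G_x0, 0.0) / (G_g0 * G_r0 * molecules_in_focus(1.0, v_x))
    free_g = total_g - c_complex
    free_r = total_r - c_complex
    floored = free_g < 0 or free_r < 0
    free_g = max(free_g, 0.0)
    free_r = max(free_r, 0.0)
    assoc = association_pct(c_complex, total_g, total_r)
    return DualColorResult(
        cell_id=cell_id, C_free_g=free_g, C_free_r=free_r,
        C_complex=c_complex, association_pct=assoc,
        qc_pass=not floored, floored=floored,
        notes="free concentration floored at 0" if floored else "",
    )


def association_pct(c_complex: float, total_g: float, total_r: float) -> float:
    """Fraction (%) of the limiting species diffusing in the complex."""
    lim = min(total_g, total_r)
    if lim <= 0:
        raise InvalidParameterError("zero total concentration: association undefined")
    return 100.0 * min(c_complex / lim, 1.0)


def association_fraction(result: DualColorResult) -> float:
    """Association percentage of a per-cell result."""
    return association_pct(result.C_complex, result.C_total_g, result.C_total_r)


# ---------------------------------------------------------------------------
# Kd regression
# ---------------------------------------------------------------------------

def estimate_kd(
    cells: Sequence[DualColorResult],
    r2_threshold: float = R2_LINEAR_THRESHOLD,
    exclude_floored: bool = True,
) -> KdEstimate:
    """Kd from the product-vs-complex regression through the origin.

    y = C_free_g * C_free_r regressed on x = C_complex without intercept;
    the slope is Kd (mass action makes the relation exact at equilibrium).
    Linearity is judged by the squared Pearson correlation of x and y;
    below ``r2_threshold`` the ensemble is reported as "N.L" (no
    association detected).  Cells whose free concentrations were floored
    are excluded by default (their amplitudes are noise-dominated).
    """
    if len(cells) < 3:
        raise InvalidInputError("need at least 3 cells for the Kd regression")
    use = [c for c in cells if not (exclude_floored and c.floored)]
    if len(use) < 3:
        raise InvalidInputError("fewer than 3 cells survive QC")
    x = np.array([c.C_complex for c in use])
    y = np.array([c.C_free_g * c.C_free_r for c in use])
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        return KdEstimate(kd=None, se=None, r_squared=0.0,
                          n_cells=len(use), linear=False)
    slope = float(np.dot(x, y)) / sxx
    resid = y - slope * x
    # heteroscedasticity-robust (HC1) slope SE: residuals of the mass-action
    # product grow with the complex concentration, so the homoscedastic
    # formula understates the uncertainty for the large-x cells
    dof = max(len(use) - 1, 1)
    se = float(np.sqrt(len(use) / dof * np.sum((x * resid) ** 2)) / sxx)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        r2 = 1.0 if np.allclose(resid, 0.0) else 0.0
    else:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    linear = bool(r2 >= r2_threshold and slope > 0)
    return KdEstimate(
        kd=slope if linear else None,
        se=se if linear else None,
        r_squared=r2, n_cells=len(use), linear=linear,
    )


# ---------------------------------------------------------------------------
# per-cell pipeline: curve triplet -> DualColorResult
# ---------------------------------------------------------------------------

def analyze_cell(
    curve_g: CorrelationCurve,
    curve_r: CorrelationCurve,
    curve_x: CorrelationCurve,
    calib_g: CalibrationResult,
    calib_r: CalibrationResult,
    bleedthrough: float = 0.0,
    model: str = "two",
    cell_id: str = "",
    kappa: float = 5.0,
) -> tuple[DualColorResult, dict[str, AnomalousDiffusionFit]]:
    """Fit a (ACF_g, ACF_r, CCF) triplet and derive per-cell concentrations.

    The ACFs are fit with the two-component anomalous-diffusion model, the
    CCF with one component (the complex); offset-subtracted zero-lag
    amplitudes 1/N are bleed-through corrected using the curves' recorded
    mean intensities, then converted to concentrations.
    """
    fits = {
        "ACF_g": fit_acf(curve_g, model=model, kappa=kappa),
        "ACF_r": fit_acf(curve_r, model=model, kappa=kappa),
        "CCF": fit_acf(curve_x, model="one", kappa=kappa),
    }
    for kind in ("ACF_g", "ACF_r"):
        if not fits[kind].success:
            raise CellRejected(f"{kind} fit failed: {fits[kind].message}")
    amp_g = 1.0 / fits["ACF_g"].params.N
    amp_r = 1.0 / fits["ACF_r"].params.N
    amp_x = 1.0 / fits["CCF"].params.N if fits["CCF"].success else 0.0
    if fits["CCF"].n_components_effective == 0:  # no positive CCF amplitude
        amp_x = 0.0
    if bleedthrough > 0:
        f_g = curve_g.mean_intensity.get("g")
        f_r = curve_r.mean_intensity.get("r")
        if f_g is None or f_r is None:
            raise InvalidInputError("cross-talk correction needs mean intensities")
        amp_r, amp_x, _ = correct_crosstalk(amp_g, amp_r, amp_x,
                                            bleedthrough, f_g, f_r)
        if amp_r <= 0:
            raise CellRejected("red amplitude non-positive after bleed-through correction")
    result = amplitudes_to_concentrations(amp_g, amp_r, amp_x, calib_g,
                                          calib_r, cell_id=cell_id)
    return result, fits
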