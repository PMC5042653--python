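import numpy as np
import pytest

from fcsflim.fcs import (
    CalibrationResult,
    FcsModelParams,
    effective_volume,
    molecules_in_focus,
)

W0 = 0.2      # µm, back-projected pinhole radius of the emulated instrument
KAPPA = 5.0


@pytest.fixture(scope="session")
def calib() -> CalibrationResult:
    """Ideal green-channel calibration at the instrument geometry."""
    return CalibrationResult(
        w0=W0, z0=KAPPA * W0, V_eff=effective_volume(W0, KAPPA),
        tauD_dye=25e-6, dye_D=400.0, channel="g",
    )


@pytest.fixture(scope="session")
def oct4_like_params() -> FcsModelParams:
    """Two-component model at blastula-stage GFP-Oct4 conditions."""
    v = effective_volume(W0, KAPPA)
    return FcsModelParams(
        N=molecules_in_focus(44.39, v), F2=0.27,
        tauD1=3.03e-3, tauD2=0.1, alpha1=1.0, alpha2=0.8, kappa=KAPPA,
    )


def poisson_trace(rate_cps: float, dt: float, n_bins: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.poisson(rate_cps * dt, size=n_bins)
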