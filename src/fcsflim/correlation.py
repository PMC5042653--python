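"""Intensity-trace containers, photobleaching correction and multi-tau correlation.

The correlator turns binned photon-count traces recorded in one or two
detection channels into auto- (ACF) or cross-correlation (CCF) curves

    G(tau) = <dI_a(t) dI_b(t+tau)> / (<I_a><I_b>),

estimated with the symmetric normalisation (per-lag monitor means over the
overlapping windows) on a quasi-logarithmic multi-tau lag grid: a linear
block of lags at the native bin width followed by successive factor-2
rebinning, the standard scheme of hardware correlators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d


class InvalidParameterError(ValueError):
    """Raised when an operation receives parameters outside its domain."""


class InvalidInputError(ValueError):
    """Raised when input data violate an operation's preconditions."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class IntensityTrace:
    """Binned photon-count time series in one or two detection channels.

    Parameters
    ----------
    dt : float
        Bin width in seconds.
    counts_g : ndarray
        Counts per bin, green (donor) channel. Float after detrending.
    counts_r : ndarray, optional
        Counts per bin, red (acceptor) channel; same length as ``counts_g``.
    metadata : dict
        Free-form provenance (simulation parameters, detrend settings, ...).
    """

    dt: float
    counts_g: np.ndarray
    counts_r: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        self.counts_g = np.asarray(self.counts_g)
        if self.counts_r is not None:
            self.counts_r = np.asarray(self.counts_r)
            if len(self.counts_r) != len(self.counts_g):
                raise InvalidInputError("channel lengths differ")

    @property
    def n_bins(self) -> int:
        return len(self.counts_g)

    @property
    def duration(self) -> float:
        return self.n_bins * self.dt

    @property
    def n_channels(self) -> int:
        return 1 if self.counts_r is None else 2

    def channel(self, name: str) -> np.ndarray:
        if name == "g":
            return self.counts_g
        if name == "r":
            if self.counts_r is None:
                raise InvalidInputError("trace has no red channel")
            return self.counts_r
        raise InvalidParameterError(f"unknown channel {name!r}")

    def mean_rate(self, name: str = "g") -> float:
        """Mean intensity of a channel in counts/s."""
        return float(np.mean(self.channel(name))) / self.dt


@dataclass
class CorrelationCurve:
    """Correlation estimate on a lag grid.

    ``kind`` is one of ``"ACF_g"``, ``"ACF_r"``, ``"CCF"``.
    ``mean_intensity`` maps channel name to counts/s and is required for
    spectral cross-talk correction downstream.
    """

    lags: np.ndarray
    G: np.ndarray
    sigma: Optional[np.ndarray] = None
    kind: str = "ACF_g"
    mean_intensity: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.ndim != 1 or self.G.shape != self.lags.shape:
            raise InvalidInputError("lags and G must be 1-d arrays of equal length")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise InvalidInputError("lags must be positive and strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.lags.shape:
                raise InvalidInputError("sigma length mismatch")
            if np.any(self.sigma < 0):
                raise InvalidParameterError("sigma must be non-negative")

    def __len__(self) -> int:
        return len(self.lags)


# ---------------------------------------------------------------------------
# photobleaching correction
# ---------------------------------------------------------------------------

def _smooth_trend(x: np.ndarray, window_bins: int, method: str) -> np.ndarray:
    if method == "moving-average":
        # normalized box average: the window shrinks symmetrically at the
        # edges instead of padding with (noisy) edge bins
        n = len(x)
        half = window_bins // 2
        csum = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
        idx = np.arange(n)
        lo = np.clip(idx - half, 0, n)
        hi = np.clip(idx + half + 1, 0, n)
        return (csum[hi] - csum[lo]) / (hi - lo)
    if method == "exponential":
        # forward-backward EWMA: zero-phase; time constant ~ window/4 so the
        # multiplicative bias (1 - (k/tau_b)^2)^-1 on an exponential trend
        # stays well below the moving-average residual
        alpha = 4.0 / (window_bins + 2.0)
        from scipy.signal import lfilter
        # warm-start each pass from a short boxcar mean, not a single bin
        k = max(window_bins // 4, 1)
        zi = np.array([(1 - alpha) * float(np.mean(x[:k]))])
        fwd, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], x.astype(float), zi=zi)
        zi = np.array([(1 - alpha) * float(np.mean(x[-k:]))])
        bwd, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], x[::-1].astype(float), zi=zi)
        return 0.5 * (fwd + bwd[::-1])
    raise InvalidParameterError(f"unknown detrend method {method!r}")


def detrend_trace(
    trace: IntensityTrace,
    method: str = "moving-average",
    window: float = 1.0,
) -> IntensityTrace:
    """Remove slow intensity drifts (photobleaching) from a trace.

    Applies the ratio-plus-offset correction

        I_corr(t) = I(t) * sqrt(<I>/f(t)) + <I> * (1 - sqrt(f(t)/<I>))

    where ``f`` is the trend smoothed over ``window`` seconds.  The square
    root preserves the shot-noise scaling of the fluctuations and the
    offset restores the local mean, so E[I_corr(t)] = <I> at every t.

    Raises
    ------
    InvalidParameterError
        If ``window`` is shorter than 100 bins or at least as long as the
        trace.
    """
    if window < 100 * trace.dt:
        raise InvalidParameterError("detrend window must span >= 100 bins")
    if window >= trace.duration:
        raise InvalidParameterError("detrend window must be shorter than the trace")
    window_bins = max(int(round(window / trace.dt)), 1)

    def _correct(x: np.ndarray) -> np.ndarray:
        mean = float(np.mean(x))
        if mean <= 0:
            return x.astype(float)
        f = np.clip(_smooth_trend(x, window_bins, method), 1e-12 * mean, None)
        ratio = np.sqrt(mean / f)
        return x * ratio + mean * (1.0 - 1.0 / ratio)

    counts_g = _correct(trace.counts_g)
    counts_r = _correct(trace.counts_r) if trace.counts_r is not None else None
    meta = dict(trace.metadata)
    meta["detrend"] = {"method": method, "window_s": window}
    return IntensityTrace(dt=trace.dt, counts_g=counts_g, counts_r=counts_r, metadata=meta)


# ---------------------------------------------------------------------------
# multi-tau correlation
# ---------------------------------------------------------------------------

MIN_TRACE_BINS = 2 ** 10


def _correlate_at_lags(a: np.ndarray, b: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Symmetric-normalised correlator at integer lags ``ks`` (brute force core)."""
    n = len(a)
    out = np.empty(len(ks))
    for i, k in enumerate(ks):
        head = a[: n - k]
        tail = b[k:]
        ma = head.mean()
        mb = tail.mean()
        denom = ma * mb
        if denom <= 0:
            out[i] = 0.0
        else:
            out[i] = float(np.dot(head, tail)) / (n - k) / denom - 1.0
    return out


def _rebin(x: np.ndarray) -> np.ndarray:
    n = (len(x) // 2) * 2
    return x[:n].reshape(-1, 2).mean(axis=1)


def multitau_correlate(
    trace: IntensityTrace,
    channel_a: str = "g",
    channel_b: str = "g",
    points_per_octave: int = 16,
    min_level_bins: int = 64,
) -> CorrelationCurve:
    """Multi-tau auto-/cross-correlation of a binned trace.

    The first ``2*m`` lags (``m = points_per_octave``) are evaluated at the
    native bin width; each subsequent level halves the time resolution by
    averaging adjacent bins and evaluates lags ``m+1 .. 2m`` in rebinned
    units.  Identical channels give the ACF, distinct channels the CCF.
    Lags are reported at bin centres, first lag = dt.
    """
    if trace.n_bins < MIN_TRACE_BINS:
        raise InvalidInputError(f"trace must have >= {MIN_TRACE_BINS} bins")
    if points_per_octave < 2:
        raise InvalidParameterError("points_per_octave must be >= 2")
    a = np.asarray(trace.channel(channel_a), dtype=float)
    b = np.asarray(trace.channel(channel_b), dtype=float)
    m = points_per_octave

    lags: list[np.ndarray] = []
    values: list[np.ndarray] = []
    # level 0: linear lags 1..2m at native resolution
    ks = np.arange(1, 2 * m + 1)
    ks = ks[ks < len(a)]
    lags.append(ks * trace.dt)
    values.append(_correlate_at_lags(a, b, ks))
    level_dt = trace.dt
    while True:
        a = _rebin(a)
        b = _rebin(b)
        level_dt *= 2.0
        if len(a) < max(min_level_bins, 2 * m + 1):
            break
        ks = np.arange(m + 1, 2 * m + 1)
        lags.append(ks * level_dt)
        values.append(_correlate_at_lags(a, b, ks))

    kind = "CCF" if channel_a != channel_b else ("ACF_r" if channel_a == "r" else "ACF_g")
    mean_int = {"g": trace.mean_rate("g")}
    if trace.counts_r is not None:
        mean_int["r"] = trace.mean_rate("r")
    return CorrelationCurve(
        lags=np.concatenate(lags),
        G=np.concatenate(values),
        kind=kind,
        mean_intensity=mean_int,
        metadata={"points_per_octave": m, "dt_s": trace.dt,
                  "channels": (channel_a, channel_b)},
    )


def estimate_curve_sigma(
    trace: IntensityTrace,
    n_segments: int = 10,
    channel_a: str = "g",
    channel_b: str = "g",
    points_per_octave: int = 16,
    smooth: bool = True,
) -> CorrelationCurve:
    """Correlate a trace and attach per-lag noise estimates.

    The trace is cut into ``n_segments`` equal pieces, each correlated
    independently; sigma(tau) is the across-segment standard deviation
    divided by sqrt(n_segments) (standard error of the full-trace mean).
    Because a raw std over ~10 segments carries ~30% sampling error and
    1/sigma^2 weighting amplifies it into fit bias, the sigma profile is
    smoothed over neighbouring lags by default (geometric moving average;
    the true noise varies smoothly with lag).  Lags not reachable within a
    single segment are dropped with a warning.
    """
    if n_segments < 3:
        raise InvalidParameterError("n_segments must be >= 3")
    full = multitau_correlate(trace, channel_a, channel_b, points_per_octave)
    seg_len = trace.n_bins // n_segments
    if seg_len < MIN_TRACE_BINS:
        raise InvalidInputError("segments too short for the correlator")
    seg_curves = []
    for i in range(n_segments):
        sl = slice(i * seg_len, (i + 1) * seg_len)
        seg = IntensityTrace(
            dt=trace.dt,
            counts_g=trace.counts_g[sl],
            counts_r=None if trace.counts_r is None else trace.counts_r[sl],
        )
        seg_curves.append(multitau_correlate(seg, channel_a, channel_b, points_per_octave))
    n_common = min(len(c) for c in seg_curves)
    if n_common < len(full):
        warnings.warn(
            f"dropping {len(full) - n_common} long lags not covered by segments",
            stacklevel=2,
        )
    seg_G = np.stack([c.G[:n_common] for c in seg_curves])
    sigma = seg_G.std(axis=0, ddof=1) / np.sqrt(n_segments)
    if smooth and np.all(sigma > 0):
        sigma = np.exp(uniform_filter1d(np.log(sigma), size=9, mode="nearest"))
    return replace(
        full,
        lags=full.lags[:n_common],
        G=full.G[:n_common],
        sigma=sigma,
        metadata={**full.metadata, "sigma_segments": n_segments},
    )
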