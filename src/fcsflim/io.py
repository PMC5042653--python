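"""Plain-text readers and writers for traces, curves, decays and calibrations.

Formats:

* trace: header ``# dt_s=<float> channels=<1|2>``, one or two whitespace-
  separated count columns; or an ``.npz`` container with the same fields.
* curve: ``# <json header>`` (kind, mean intensities, provenance) followed
  by CSV ``lag_s,G,sigma``.
* decay: ``# <json header>`` (bin_time_ns, irf, unit id) followed by CSV
  ``time_ns,counts``.
* calibration / ground truth: JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Union

import numpy as np

from .correlation import CorrelationCurve, IntensityTrace, InvalidInputError
from .fcs import CalibrationResult
from .flim import DecayHistogram

PathLike = Union[str, Path]


# --- traces ----------------------------------------------------------------

def write_trace(trace: IntensityTrace, path: PathLike) -> Path:
    path = Path(path)
    if path.suffix == ".npz":
        kw = {"dt_s": trace.dt, "counts_g": trace.counts_g}
        if trace.counts_r is not None:
            kw["counts_r"] = trace.counts_r
        np.savez_compressed(path, **kw)
        return path
    cols = [trace.counts_g] if trace.counts_r is None else [trace.counts_g, trace.counts_r]
    header = f"dt_s={trace.dt!r} channels={len(cols)}"
    np.savetxt(path, np.column_stack(cols), fmt="%d", header=header, comments="# ")
    return path


def read_trace(path: PathLike) -> IntensityTrace:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return IntensityTrace(dt=float(z["dt_s"]), counts_g=z["counts_g"],
                                  counts_r=z["counts_r"] if "counts_r" in z else None)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise InvalidInputError(f"{path}: missing trace header")
    fields = dict(tok.split("=") for tok in first.lstrip("# ").split())
    dt = float(fields["dt_s"])
    data = np.loadtxt(path)
    data = np.atleast_2d(data.T) if data.ndim == 1 else data.T
    counts_r = data[1] if int(fields.get("channels", 1)) == 2 else None
    return IntensityTrace(dt=dt, counts_g=data[0], counts_r=counts_r,
                          metadata={"source": str(path)})


# --- correlation curves ----------------------------------------------------

def write_curve(curve: CorrelationCurve, path: PathLike) -> Path:
    path = Path(path)
    header = {"kind": curve.kind, "mean_intensity": curve.mean_intensity,
              "provenance": {k: v for k, v in curve.metadata.items()
                             if isinstance(v, (str, int, float, bool))}}
    sigma = curve.sigma if curve.sigma is not None else np.full_like(curve.lags, np.nan)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("lag_s,G,sigma\n")
        for row in zip(curve.lags, curve.G, sigma):
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")
    return path


def read_curve(path: PathLike) -> CorrelationCurve:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise InvalidInputError(f"{path}: missing curve header")
        header = json.loads(first.lstrip("# "))
    data = np.loadtxt(path, delimiter=",", skiprows=2)
    sigma = data[:, 2]
    if np.all(np.isnan(sigma)):
        sigma = None
    return CorrelationCurve(lags=data[:, 0], G=data[:, 1], sigma=sigma,
                           kind=header.get("kind", "ACF_g"),
                           mean_intensity=header.get("mean_intensity", {}),
                           metadata={"source": str(path), **header.get("provenance", {})})


# --- TCSPC decays ----------------------------------------------------------

def write_decay(hist: DecayHistogram, path: PathLike, unit_id: str = "") -> Path:
    path = Path(path)
    header = {"bin_time_ns": hist.bin_time, "irf": hist.irf, "unit_id": unit_id}
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("time_ns,counts\n")
        for t, c in zip(hist.t, hist.counts):
            fh.write(f"{t:.6g},{int(c)}\n")
    return path


def read_decay(path: PathLike) -> DecayHistogram:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise InvalidInputError(f"{path}: missing decay header")
        header = json.loads(first.lstrip("# "))
    data = np.loadtxt(path, delimiter=",", skiprows=2)
    return DecayHistogram(bin_time=float(header["bin_time_ns"]),
                          counts=data[:, 1].astype(int),
                          irf=header.get("irf"),
                          metadata={"source": str(path),
                                    "unit_id": header.get("unit_id", "")})


# --- calibration & ground truth --------------------------------------------

def write_calibration(calib: CalibrationResult, path: PathLike) -> Path:
    path = Path(path)
    path.write_text(json.dumps(asdict(calib), indent=2))
    return path


def read_calibration(path: PathLike) -> CalibrationResult:
    return CalibrationResult(**json.loads(Path(path).read_text()))


def write_truth(truth: dict, path: PathLike) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth, indent=2, default=str))
    return path
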