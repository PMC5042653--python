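"""Group summaries, normality-gated significance tests, pipeline driver.

Group comparison follows the study's convention: Welch's unpaired
two-tailed t-test when both groups pass a normality check, Mann-Whitney U
otherwise; normal groups are summarised as mean +- SEM, non-normal groups
as median and interquartile range (both are always stored).  Normality is
assessed per group by Shapiro-Wilk at alpha = 0.05 (the procedure and
level are package choices, exposed in config).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import InvalidInputError, InvalidParameterError
from .fcs import (
    FcsModelParams,
    TAU1_BOUNDS,
    TAU2_BOUNDS,
    ALPHA_BOUNDS,
    concentration_nM,
    effective_volume,
    molecules_in_focus,
)

SHAPIRO_ALPHA = 0.05
SIGNIFICANCE_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class GroupSummary:
    """Per-group descriptive statistics with a normality flag."""

    group: str
    n: int
    mean: float
    sem: float
    median: float
    q1: float
    q3: float
    normal: bool
    shapiro_p: float


@dataclass
class TestResult:
    """Two-group comparison routed by normality."""

    test: str                 # "welch_t" | "mann_whitney"
    statistic: float
    p_value: float
    groups: tuple
    significance: str = "n.s."


def is_normal(values: Sequence[float], alpha: float = SHAPIRO_ALPHA) -> tuple[bool, float]:
    """Shapiro-Wilk normality check; returns (passed, p)."""
    v = np.asarray(values, dtype=float)
    if np.ptp(v) == 0:  # constant sample: Shapiro undefined, treat as normal
        return True, 1.0
    with np.errstate(all="ignore"):
        stat = stats.shapiro(v)
    return bool(stat.pvalue >= alpha), float(stat.pvalue)


def summarize_group(values: Sequence[float], group_label: str) -> GroupSummary:
    """Summarise one group; mean+-SEM if normal, median+IQR otherwise (both kept)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise InvalidInputError("need at least 2 values per group")
    normal, p = is_normal(v)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return GroupSummary(
        group=group_label, n=len(v),
        mean=float(np.mean(v)),
        sem=float(np.std(v, ddof=1) / np.sqrt(len(v))),
        median=float(med), q1=float(q1), q3=float(q3),
        normal=normal, shapiro_p=p,
    )


def significance_tier(p: float) -> str:
    for thr, stars in SIGNIFICANCE_TIERS:
        if p < thr:
            return stars
    return "n.s."


def compare_groups(
    a_values: Sequence[float],
    b_values: Sequence[float],
    labels: tuple = ("A", "B"),
) -> TestResult:
    """Welch t when BOTH groups pass normality, else Mann-Whitney (two-tailed)."""
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InvalidInputError("need at least 3 values per group")
    normal_a, _ = is_normal(a)
    normal_b, _ = is_normal(b)
    if normal_a and normal_b:
        res = stats.ttest_ind(a, b, equal_var=False)
        test = "welch_t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney"
    return TestResult(test=test, statistic=float(res.statistic),
                      p_value=float(res.pvalue), groups=tuple(labels),
                      significance=significance_tier(float(res.pvalue)))


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _fcs_group(block: dict, seed: int, gi: int) -> tuple[list[dict], dict]:
    """Simulate and fit one FCS group defined by a config block."""
    from .synthetic import STUDY_PRESETS, simulate_model_acf

    w0 = float(block.get("w0", STUDY_PRESETS["w0_um"]))
    kappa = float(block.get("kappa", STUDY_PRESETS["kappa"]))
    v_eff = effective_volume(w0, kappa)
    if "curves_dir" in block:       # measured curves from disk
        from .io import read_curve
        curves = [read_curve(p)
                  for p in sorted(Path(block["curves_dir"]).glob("*.csv"))]
        if not curves:
            raise InvalidInputError(f"no curve files in {block['curves_dir']}")
        cfg_extra = {"source": block["curves_dir"]}
    else:                           # simulation block
        n_cells = int(block["n_cells"])
        conc = float(block["concentration_nM"])
        truth = FcsModelParams(
            N=molecules_in_focus(conc, v_eff),
            F2=float(block["f2"]),
            tauD1=float(block.get("tauD1", STUDY_PRESETS["free_tauD_s"])),
            tauD2=float(block.get("tauD2", STUDY_PRESETS["bound_tauD_s"])),
            alpha1=float(block.get("alpha1", STUDY_PRESETS["alpha_free"])),
            alpha2=float(block.get("alpha2", STUDY_PRESETS["alpha_bound"])),
            kappa=kappa,
        )
        noise = block.get("noise_sd", "auto")
        curves = []
        for i in range(n_cells):
            cell_seed = int(np.random.SeedSequence([seed, 10, gi, i]).generate_state(1)[0] & 0x7FFFFFFF)
            curves.append(simulate_model_acf(truth, noise_sd=noise, seed=cell_seed))
        cfg_extra = {"truth_N": truth.N, "noise_sd": noise}
    # study workflow: shared fast diffusion time, per-cell rest
    from .fcs import fit_acf_global
    fits, tau1_shared, _ = fit_acf_global(curves, kappa=kappa)
    records = []
    for i, fit in enumerate(fits):
        rec = {
            "cell_id": f"{block['label']}_{i:03d}",
            "success": fit.success,
            "N": fit.params.N,
            "C_nM": concentration_nM(fit.params.N, v_eff),
            "F2": fit.params.F2,
            "tauD1": fit.params.tauD1,
            "tauD2": fit.params.tauD2,
            "alpha1": fit.params.alpha1,
            "alpha2": fit.params.alpha2,
            "chi2_reduced": fit.chi2_reduced,
        }
        records.append(rec)
    cfg = {**cfg_extra, "kappa": kappa, "tauD1_shared": tau1_shared,
           "tauD1_bounds": TAU1_BOUNDS, "tauD2_bounds": TAU2_BOUNDS,
           "alpha_bounds": ALPHA_BOUNDS}
    return records, cfg


def _fccs_group(block: dict, seed: int, gi: int) -> tuple[list[dict], dict]:
    from .fccs import CellRejected, analyze_cell, estimate_kd
    from .fcs import CalibrationResult
    from .synthetic import BindingEnsembleParams, STUDY_PRESETS, simulate_binding_ensemble

    w0 = float(block.get("w0", STUDY_PRESETS["w0_um"]))
    kappa = float(block.get("kappa", STUDY_PRESETS["kappa"]))
    params = BindingEnsembleParams(
        n_cells=int(block.get("n_cells", 15)),
        kd=float(block["kd"]),
        seed=int(np.random.SeedSequence([seed, 11, gi]).generate_state(1)[0] & 0x7FFFFFFF),
        w0=w0, kappa=kappa,
        crosstalk_coeff=float(block.get("bleedthrough", 0.0)),
    )
    cells = simulate_binding_ensemble(params)
    v = effective_volume(w0, kappa)
    calib = CalibrationResult(w0=w0, z0=kappa * w0, V_eff=v,
                              tauD_dye=25e-6, dye_D=STUDY_PRESETS["dye_D_um2_s"])
    results, records = [], []
    for cell in cells:
        try:
            res, _ = analyze_cell(cell.curves["ACF_g"], cell.curves["ACF_r"],
                                  cell.curves["CCF"], calib, calib,
                                  bleedthrough=params.crosstalk_coeff,
                                  cell_id=cell.cell_id, kappa=kappa)
            results.append(res)
            records.append({"cell_id": cell.cell_id, **asdict(res)})
        except CellRejected as exc:
            records.append({"cell_id": cell.cell_id, "error": str(exc)})
    kd = estimate_kd(results)
    return records, {"kd_estimate": asdict(kd), "generating_kd": params.kd}


def _flim_group(block: dict, seed: int, gi: int) -> tuple[list[dict], dict]:
    from .flim import fit_decay, lifetime_map
    from .synthetic import DecaySimParams, STUDY_PRESETS, simulate_tcspc_decay

    if "decays_dir" in block:       # measured decays from disk
        from .io import read_decay
        decays = {p.stem: read_decay(p)
                  for p in sorted(Path(block["decays_dir"]).glob("*.csv"))}
        if not decays:
            raise InvalidInputError(f"no decay files in {block['decays_dir']}")
        table = lifetime_map(decays, model=block.get("model", "auto"),
                             fix_tau1=block.get("fix_tau1"))
        records = table.rename(columns={"unit_id": "cell_id"}).to_dict("records")
        return records, {"source": block["decays_dir"]}

    n_units = int(block.get("n_units", 20))
    bound = float(block.get("bound_fraction", 0.0))
    tau1 = float(block.get("tau1", STUDY_PRESETS["donor_lifetime_ns"]))
    tau2 = float(block.get("tau2", STUDY_PRESETS["fret_lifetime_ns"]))
    counts = float(block.get("total_counts", 1e6))
    fix_tau1 = block.get("fix_tau1")
    records = []
    for i in range(n_units):
        s = int(np.random.SeedSequence([seed, 12, gi, i]).generate_state(1)[0] & 0x7FFFFFFF)
        if bound > 0:
            p = DecaySimParams(lifetimes=(tau1, tau2),
                               amplitude_fractions=(1 - bound, bound),
                               total_counts=counts, seed=s)
            fit = fit_decay(simulate_tcspc_decay(p), model="biexp",
                            fix_tau1=fix_tau1)
        else:
            p = DecaySimParams(lifetimes=(tau1,), amplitude_fractions=(1.0,),
                               total_counts=counts, seed=s)
            fit = fit_decay(simulate_tcspc_decay(p), model="mono")
        records.append({
            "cell_id": f"{block['label']}_{i:03d}",
            "model": fit.model, "tau1": fit.tau1, "tau2": fit.tau2,
            "binding_pct": fit.binding_pct,
            "amp_weighted_mean_ns": fit.amp_weighted_mean_ns,
            "chi2_reduced": fit.chi2_reduced, "success": fit.success,
        })
    return records, {"tau1": tau1, "tau2": tau2, "bound_fraction": bound}


_STAGES = {"fcs": (_fcs_group, "F2"), "fccs": (_fccs_group, "association_pct"),
           "flim": (_flim_group, "binding_pct")}


def run_pipeline(config: dict | str | Path) -> dict:
    """Run simulate -> fit -> summarise -> compare from a config mapping.

    Config layout (YAML or dict)::

        seed: 1
        fcs:                       # and/or fccs:, flim:
          groups:
            - {label: rescued, n_cells: 39, concentration_nM: 44.39, f2: 0.27}
            - {label: delta_hd, n_cells: 39, concentration_nM: 44.0, f2: 0.12}
          compare: [[rescued, delta_hd]]

    Per-cell failures are recorded and the pipeline continues; the report
    carries a completeness fraction per group.  The same config and seed
    produce an identical report body.
    """
    if isinstance(config, (str, Path)):
        import yaml
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise InvalidParameterError("config must be a mapping")
    seed = int(config.get("seed", 0))
    stages = [k for k in _STAGES if k in config]
    if not stages:
        raise InvalidParameterError("config defines no pipeline stage")
    for stage in stages:
        groups = config[stage].get("groups", [])
        if not groups:
            raise InvalidParameterError(f"stage {stage!r} has an empty group list")
        labels = [g.get("label") for g in groups]
        if None in labels or len(set(labels)) != len(labels):
            raise InvalidParameterError("every group needs a unique label")

    report: dict = {"seed": seed, "config": config, "stages": {}}
    for stage in stages:
        runner, metric = _STAGES[stage]
        stage_out: dict = {"metric": metric, "groups": {}, "tests": []}
        values_by_label: dict[str, list[float]] = {}
        for gi, block in enumerate(config[stage]["groups"]):
            records, extra = runner(block, seed, gi)
            ok = [r for r in records if r.get("success", True) and "error" not in r]
            vals = [float(r[metric]) for r in ok if r.get(metric) is not None
                    and np.isfinite(r.get(metric, np.nan))]
            values_by_label[block["label"]] = vals
            stage_out["groups"][block["label"]] = {
                "cells": records,
                "completeness": len(ok) / len(records) if records else 0.0,
                "summary": asdict(summarize_group(vals, block["label"]))
                if len(vals) >= 2 else None,
                **extra,
            }
        for pair in config[stage].get("compare", []):
            a, b = pair
            res = compare_groups(values_by_label[a], values_by_label[b], (a, b))
            stage_out["tests"].append(asdict(res))
        report["stages"][stage] = stage_out
    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write the JSON report and flat per-cell CSV tables; returns report path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stage, block in report["stages"].items():
        rows = []
        for label, grp in block["groups"].items():
            for rec in grp["cells"]:
                rows.append({"group": label, **rec})
        pd.DataFrame(rows).to_csv(out / f"{stage}_cells.csv", index=False)
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    return str(obj)
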