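"""Orchestration: one-call reproduction of the desk-scale table analyses and
an end-to-end synthetic pipeline with known ground truth."""
from __future__ import annotations

import json
import time
from dataclasses import asdict
from typing import Optional

import numpy as np

from . import __version__
from .asymmetry import session_hit_rates
from .datatypes import ChangeSide, Epoch, Structure
from .doseresponse import (classify_session_significance, fit_bayesian_logistic,
                           posterior_predictive, predictive_midpoint,
                           subsample_control)
from .io import load_fixture
from .regression import (binned_group_compare, bootstrap_slope_compare,
                         orthogonal_regression, session_points)
from .simulate import SimConfig, simulate_cohort

#: Published values the table analyses are checked against.
REFERENCE = {
    "sc_slope_latency": 0.31,
    "fef_slope_latency": 0.08,
    "sc_slope_se": 0.03,
    "fef_slope_se": 0.03,
    "subsample_sc_greater_of_1000": 999,
}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def reproduce_tables(out_path: Optional[str] = None, seed: int = 0,
                    n_iter: int = 1000, n_boot: int = 1000) -> dict:
    """Recompute every desk-scale statistic from the packaged tables.

    Runs the orthogonal (through-origin) regression with jackknife SE on
    both structures' session tables, the bootstrap slope comparison, the
    30-ms binned group tests, and the n-matched subsampling control, and
    checks each headline number against its published reference value.
    """
    t0 = time.time()
    sc = load_fixture(Structure.SC)
    fef = load_fixture(Structure.FEF)
    pts_sc = session_points(sc)
    pts_fef = session_points(fef)

    reg_sc = orthogonal_regression(pts_sc)
    reg_fef = orthogonal_regression(pts_fef)
    p_slope, _, _ = bootstrap_slope_compare(pts_sc, pts_fef, n_boot=n_boot,
                                            seed=seed)
    bins = binned_group_compare(pts_sc, pts_fef, bin_width=30.0)
    sub = subsample_control(pts_sc, pts_fef, n_iter=n_iter,
                            n_sub=len(pts_fef), n_boot=n_boot, seed=seed + 1)

    checks = {
        "sc_slope_latency": (reg_sc.slope, REFERENCE["sc_slope_latency"], 0.02),
        "fef_slope_latency": (reg_fef.slope, REFERENCE["fef_slope_latency"], 0.02),
        "sc_slope_se": (reg_sc.slope_se_jackknife, REFERENCE["sc_slope_se"], 0.01),
        "fef_slope_se": (reg_fef.slope_se_jackknife, REFERENCE["fef_slope_se"], 0.01),
        "subsample_sc_greater_of_1000": (
            sub["n_significant_sc_greater"] * 1000 / n_iter,
            REFERENCE["subsample_sc_greater_of_1000"], 30),
    }
    report = {
        "version": __version__,
        "seed": seed,
        "regression": {
            "SC": asdict(reg_sc),
            "FEF": asdict(reg_fef),
            "slope_compare_p": p_slope,
            "binned_latency_30ms": bins,
        },
        "subsample_control": sub,
        "checks": {name: {"computed": c, "reference": r, "tolerance": tol,
                          "pass": bool(abs(c - r) <= tol)}
                   for name, (c, r, tol) in checks.items()},
        "runtime_s": time.time() - t0,
    }
    report = _jsonable(report)
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def run_pipeline(config: SimConfig, out_path: Optional[str] = None,
                 classify_alpha: float = 0.001, include_scotoma: bool = False,
                 ) -> dict:
    """Simulate a cohort, then run the full analysis chain over it.

    simulate -> per-session asymmetries (already measured by the cohort
    generator through the analysis modules) -> significance classification
    -> coupling regression -> logistic dose-response.
    """
    t0 = time.time()
    summaries, trials, _, truth = simulate_cohort(config,
                                                  include_scotoma=include_scotoma)
    by_session = {}
    for tr in trials:
        by_session.setdefault(tr.session_id, []).append(tr)

    ys, p_class = [], []
    for i, s in enumerate(summaries):
        rates, counts = session_hit_rates(by_session[s.session_id])
        cell_counts = {
            (side.value, epoch.value): (
                int(round(rates[(side, epoch)] * counts[(side, epoch)])),
                counts[(side, epoch)])
            for side in (ChangeSide.IN, ChangeSide.OUT)
            for epoch in (Epoch.BEFORE, Epoch.DURING)}
        y, p, _ = classify_session_significance(cell_counts,
                                                alpha=classify_alpha,
                                                seed=config.seed + 10_000 + i)
        s.significant_deficit = y
        ys.append(y)
        p_class.append(p)

    pts = session_points(summaries)
    report = {
        "version": __version__,
        "config": {"structure": config.structure.value,
                   "n_sessions": config.n_sessions,
                   "coupling_slope": config.coupling_slope,
                   "seed": config.seed},
        "n_significant_sessions": int(sum(ys)),
        "classification_p_values": p_class,
        "truth": truth,
    }
    try:
        reg = orthogonal_regression(pts)
        report["regression"] = asdict(reg)
    except ValueError as exc:
        report["regression"] = {"error": str(exc)}
    if 0 < sum(ys) < len(ys):
        post = fit_bayesian_logistic(pts[:, 0], ys)
        grid = posterior_predictive(
            post, np.linspace(float(pts[:, 0].min()), float(pts[:, 0].max()), 61),
            seed=config.seed)
        report["doseresponse"] = {
            "w_map": post.w_map, "laplace_cov": post.laplace_cov,
            "predictive_grid": grid,
        }
        try:
            report["doseresponse"]["midpoint_x"] = predictive_midpoint(
                post, seed=config.seed)
        except ValueError as exc:
            report["doseresponse"]["midpoint_x"] = None
            report["doseresponse"]["midpoint_error"] = str(exc)
    else:
        report["doseresponse"] = {
            "skipped": "outcomes are all 0 or all 1; dose-response undefined"}
    report["runtime_s"] = time.time() - t0
    report = _jsonable(report)
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
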