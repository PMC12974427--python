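"""End-to-end report: recompute the pipeline's headline quantities.

Runs the calibrated synthetic regimes through every analysis stage and
returns the twelve summary statistics the pipeline is designed to
recover, each with the tolerance band it is expected to fall in.  All
randomness flows from one base seed; the three simulated replicates use
seed, seed+1, seed+2.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Optional

import numpy as np

from . import events as ev
from .alignment import dip_timing, segment_cycles
from .datamodel import AnalysisConfig, Cohort
from .periodicity import cohort_period_summary
from .simulate import calibrate_defaults, simulate_cohort, simulate_release_assay

__all__ = ["run_report", "compute_targets", "config_hash"]

#: (description, expected low, expected high) for the report table
EXPECTATIONS = {
    "t1": ("median circadian-isolated LSP period (h), upper bound", None, 25.0),
    "t2": ("median circadian-isolated LSP period (h), lower bound", 23.0, None),
    "t3": ("median ultradian-isolated LSP period (h), upper bound", None, 7.0),
    "t4": ("median ultradian-isolated LSP period (h), lower bound", 6.0, None),
    "t5": ("median dip lead before final mitosis (h), lower bound", 10.0, None),
    "t6": ("median dip lead before final mitosis (h), upper bound", None, 14.0),
    "t7": ("released cells with mitosis within 30 h of release (%)", 81.0, 89.0),
    "t8": ("mean release-dip fold-change", 2.05, 2.35),
    "t9": ("arrested/proliferative fold of median per-cell mean", 1.3, 1.5),
    "t10": ("dips preceding or coinciding with S-phase onset (%)", 85.0, 93.0),
    "t11": ("control cells dividing within 24 h assay (%)", 71.0, 79.0),
    "t12": ("misexpression cells dividing within 24 h assay (%)", 10.0, 18.0),
}


def _pooled(regime, n_cells, duration, dt, seeds, **kw) -> Cohort:
    """Pool one simulated replicate per seed into a single cohort."""
    traces = []
    for i, s in enumerate(seeds):
        c = simulate_cohort(regime, n_cells, 1, duration, dt, seed=s, **kw)
        for tr in c.traces:
            tr.replicate_id = f"R{i + 1}"
            tr.cell_id = f"R{i + 1}{tr.cell_id[2:]}"
            traces.append(tr)
    return Cohort(traces, dt, duration, {"seeds": list(seeds)})


def compute_targets(seed: int = 1, config: Optional[AnalysisConfig] = None) -> dict:
    """Compute the twelve report quantities from freshly simulated cohorts.

    Returns ``{name: {"value": float, "n": int}}``; values are on the
    scale the study reports (percentages as percentages).
    """
    config = config or AnalysisConfig()
    defaults = calibrate_defaults()
    seeds = [seed, seed + 1, seed + 2]
    dt = 0.25
    out: dict[str, dict] = {}

    # --- periodicity on the default proliferative cohort (3 x 90, 96 h)
    prolif = _pooled(defaults["proliferative"], 90, 96.0, dt, seeds)
    circ = cohort_period_summary(prolif, "circadian_isolated", config)
    ultr = cohort_period_summary(prolif, "ultradian_isolated", config)
    n_p = len(prolif)
    out["t1"] = {"value": circ["median"], "n": n_p}
    out["t2"] = {"value": circ["median"], "n": n_p}
    out["t3"] = {"value": ultr["median"], "n": n_p}
    out["t4"] = {"value": ultr["median"], "n": n_p}

    # --- dip timing on two-generation lineages (168 h)
    lineages = _pooled(defaults["proliferative"], 90, 168.0, dt, seeds)
    dips = dip_timing(lineages, config)
    lead = float(np.median(-dips.dip_times))
    out["t5"] = {"value": lead, "n": len(dips.dip_times)}
    out["t6"] = {"value": lead, "n": len(dips.dip_times)}

    # --- released regime: reentry, dip fold-change, dip vs S-phase
    released = _pooled(defaults["released"], 100, 96.0, dt, seeds)
    rs = ev.reentry_stats(released, window=30.0)
    out["t7"] = {"value": 100.0 * rs["fraction"], "n": rs["n_cells"]}
    folds = [ev.release_dip_foldchange(tr) for tr in released.traces]
    out["t8"] = {"value": float(np.mean(folds)), "n": len(folds)}
    pp = ev.phase_pairs(released, "dip", "sphase_onset",
                        tol=config.coincidence_tol)
    out["t10"] = {"value": 100.0 * pp["fractions"]["a_first_or_coincident"],
                  "n": pp["n_pairs"]}

    # --- arrest intensity levels vs proliferative reference
    arrested = _pooled(defaults["arrested"], 90, 96.0, dt, seeds)
    stats = ev.intensity_stats(arrested, prolif)
    out["t9"] = {"value": stats["folds"]["mean"], "n": len(arrested)}

    # --- 24 h misexpression release assay
    n_div_c = n_c = n_div_m = n_m = 0
    for i, s in enumerate(seeds):
        ctrl, tet = simulate_release_assay(150, 1, seed=s)
        rc = ev.reentry_stats(ctrl, window=24.0)
        rm = ev.reentry_stats(tet, window=24.0)
        n_div_c += round(rc["fraction"] * rc["n_cells"]); n_c += rc["n_cells"]
        n_div_m += round(rm["fraction"] * rm["n_cells"]); n_m += rm["n_cells"]
    out["t11"] = {"value": 100.0 * n_div_c / n_c, "n": n_c}
    out["t12"] = {"value": 100.0 * n_div_m / n_m, "n": n_m}
    return out


def config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_report(seed: int = 1, config: Optional[AnalysisConfig] = None) -> dict:
    """Full report bundle: target table with pass/fail plus a run manifest."""
    config = config or AnalysisConfig()
    targets = compute_targets(seed=seed, config=config)
    rows = []
    for key, res in targets.items():
        desc, lo, hi = EXPECTATIONS[key]
        ok = (lo is None or res["value"] >= lo) and (hi is None or res["value"] <= hi)
        rows.append({"id": key, "description": desc, "value": res["value"],
                     "n": res["n"], "expected_low": lo, "expected_high": hi,
                     "pass": bool(ok)})
    manifest = {"config_hash": config_hash(config),
                "seeds": [seed, seed + 1, seed + 2],
                "n_rows": len(rows)}
    return {"table": rows, "manifest": manifest}
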