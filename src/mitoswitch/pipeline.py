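"""End-to-end reproduction pipeline: signal-response sweeps, fold points,
population dose-response with IC50s, the prophase-capture scan and the
multistability census, for all four conditions, written as CSV/JSON with
a run manifest."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .bifurcation import count_stable_states_over_grid, fold_points, sweep_signal_response
from .config import RunConfig, RunManifest, load_config
from .model import STATE_VARS
from .params import Condition
from .population import (
    NoCrossingError,
    cycb_quantile_grid,
    default_dose_grid,
    ic50,
    population_dose_response,
)
from .simulate import run_prophase_protocol

__all__ = ["run_full_pipeline"]

log = logging.getLogger(__name__)


def _write_branch_csv(branches, path: Path) -> None:
    rows = []
    for br in branches:
        for v, y, st in zip(br.values, br.states, br.stable):
            row = {"param_value_uM": float(v), "branch_id": br.branch_id,
                   "stability": "stable" if st else "unstable"}
            row.update({name: float(x) for name, x in zip(STATE_VARS, y)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def run_full_pipeline(
    outdir: str | Path,
    config: RunConfig | None = None,
    seed: int = 1,
    sweep_doses: np.ndarray | None = None,
    dr_doses: np.ndarray | None = None,
    census_doses: np.ndarray | None = None,
    prophase_doses: tuple[float, ...] = (0.5, 1.0),
) -> dict:
    """Run every stage at default resolution and write one artifact per
    stage plus a manifest.  Returns the summary dict (also written as
    ``summary.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or load_config(None)
    params, pop, cfg = config.params, config.population, config.classification
    sweep_doses = default_dose_grid(31) if sweep_doses is None else sweep_doses
    dr_doses = default_dose_grid() if dr_doses is None else dr_doses
    census_doses = (np.concatenate([default_dose_grid(41), [2.0]])
                    if census_doses is None else census_doses)
    census_doses = np.unique(census_doses)

    manifest = RunManifest.create("pipeline", config, {"seed": seed})
    summary: dict = {"ic50_nM": {}, "fold_points_uM": {}, "max_stable_states": {},
                     "prophase_capture": {}, "hysteresis_ratio": {}}

    for cond in Condition:
        t0 = time.time()
        up = sweep_signal_response(params, cond, sweep_doses, "up")
        down = sweep_signal_response(params, cond, sweep_doses, "down")
        _write_branch_csv([up, down], outdir / f"sr_{cond.value}.csv")
        log.info("stage=sweep condition=%s doses=%d elapsed=%.1fs",
                 cond.value, len(sweep_doses), time.time() - t0)

        t0 = time.time()
        fp = fold_points(params, cond)
        summary["fold_points_uM"][cond.value] = {"entry": fp.entry, "exit": fp.exit}
        log.info("stage=folds condition=%s elapsed=%.1fs", cond.value, time.time() - t0)

        for protocol in ("entry", "exit"):
            t0 = time.time()
            curve = population_dose_response(params, cond, protocol, pop, dr_doses, cfg)
            pd.DataFrame({
                "dose_uM": curve.doses,
                "fraction_mitotic": curve.fraction_mitotic,
                "n_nodes": pop.n_quantiles,
            }).to_csv(outdir / f"dr_{cond.value}_{protocol}.csv", index=False)
            try:
                summary["ic50_nM"][f"{cond.value}_{protocol}"] = 1e3 * ic50(curve)
            except NoCrossingError:
                summary["ic50_nM"][f"{cond.value}_{protocol}"] = None
            log.info("stage=doseresponse condition=%s protocol=%s elapsed=%.1fs",
                     cond.value, protocol, time.time() - t0)

        e = summary["ic50_nM"].get(f"{cond.value}_entry")
        x = summary["ic50_nM"].get(f"{cond.value}_exit")
        summary["hysteresis_ratio"][cond.value] = (x / e) if e and x else None

        t0 = time.time()
        counts = count_stable_states_over_grid(params, cond, census_doses, seed=seed)
        summary["max_stable_states"][cond.value] = int(max(counts.values()))
        pd.DataFrame({"dose_uM": list(counts), "n_stable": list(counts.values())}
                     ).to_csv(outdir / f"census_{cond.value}.csv", index=False)
        log.info("stage=census condition=%s elapsed=%.1fs", cond.value, time.time() - t0)

    t0 = time.time()
    cells = cycb_quantile_grid(pop)
    for dose in prophase_doses:
        labels = [run_prophase_protocol(params, dose, cycb_tot=float(c), cfg=cfg)
                  for c in cells]
        summary["prophase_capture"][f"{dose}"] = {
            lab: labels.count(lab) / len(labels)
            for lab in ("back_to_interphase", "intermediate", "mitotic")
        }
    log.info("stage=prophase doses=%s elapsed=%.1fs", prophase_doses, time.time() - t0)

    with open(outdir / "ic50_table.json", "w") as fh:
        json.dump(summary["ic50_nM"], fh, indent=2, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest.write(outdir / "manifest.json")
    return summary
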