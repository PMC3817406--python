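#!/usr/bin/env python
"""Normalize the screen, apply quality control, and infer the interaction map.

Reads the raw readings written by 02_simulate_screen.py, runs blank
correction, log-scale median-polish detrending, control normalization, the
three QC filters, and the bootstrap/Fisher/cost-control inference.  Reports
how many runs survived QC and how many planted effects were recovered;
writes the QC report and the classified pair matrix to results/.
"""

import argparse
import importlib
import json
import sys
from pathlib import Path

import colsen as cs
from colsen.inference import TestConfig, write_matrix
from colsen.normalization import blank_correct, detrend_plate, normalize_to_controls
from colsen.pipeline import call_rates
from colsen.plates import read_readings

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "analysis"))
screen_mod = importlib.import_module("02_simulate_screen")

SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main(seed: int) -> None:
    design, truth, assay = screen_mod.build_screen(seed)
    path = SCRATCH / "screen_readings.csv"
    if path.exists():
        readings = read_readings(path)
    else:  # regenerate deterministically if 02 was not run
        readings = cs.generate_plate_readings(design, truth, assay, seed=seed + 3)
    corrected = blank_correct(readings)
    fitness = normalize_to_controls(detrend_plate(corrected), design)
    report = cs.apply_qc(corrected, fitness)
    t = report.table[report.table["condition"] != "none"]
    retained = t[t["status"] == "retained"].groupby("condition").size()
    print(f"QC: mean retained runs per condition = {retained.mean():.2f} of {design.n_runs}")
    calls = cs.infer_matrix(fitness, report, design, TestConfig(n_bootstrap=10_000, seed=seed + 4))
    oc = call_rates(calls, truth)
    n_cs = int((calls["classification"] == "collateral_sensitivity").sum())
    print(
        f"inference: {n_cs} collateral-sensitivity calls; recall of planted effects "
        f"{oc.n_recovered}/{oc.n_planted} = {oc.recall:.2f}; "
        f"false-call rate on null pairs {oc.false_call_rate:.4f} ({oc.n_null} pairs)"
    )
    RESULTS.mkdir(exist_ok=True)
    report.to_tsv(RESULTS / "qc_report.tsv")
    write_matrix(calls, RESULTS / "interaction_matrix.tsv")
    (RESULTS / "inference_summary.json").write_text(
        json.dumps(
            {
                "n_collateral_sensitivity_calls": n_cs,
                "recall_planted": oc.recall,
                "false_call_rate": oc.false_call_rate,
                "mean_retained_runs": float(retained.mean()),
            },
            indent=1,
        )
    )
    print(f"matrix -> {RESULTS / 'interaction_matrix.tsv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
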