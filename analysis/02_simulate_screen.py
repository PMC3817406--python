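#!/usr/bin/env python
"""Simulate the susceptibility screen for a 12-drug panel with planted truth.

The ground truth plants 30 cross-class collateral-sensitivity effects of -0.5
(evolved growth halved), per-line general fitness costs up to 10%,
within-class cross-resistance defaults, replicate noise (SD 5% of baseline),
within-plate spatial trends, and realistic QC failure events.  Raw readings
go to scratch/ (they are bulky intermediates); the truth's planted pair list
goes to results/.
"""

import argparse
import json
from pathlib import Path

import colsen as cs
from colsen.pipeline import choose_cross_class_pairs
from colsen.plates import AssayConfig, write_readings

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def build_screen(seed: int):
    table = cs.load_antibiotics()
    sub = table[table["gradient_flag"]].reset_index(drop=True)
    design = cs.build_design(sub, "fixed", 10, 10, n_runs=4)
    pairs = choose_cross_class_pairs(design, 30, seed=seed + 1)
    truth = cs.GroundTruth.with_planted_effects(
        design, {p: -0.5 for p in pairs}, cost_max=0.10, seed=seed + 2
    )
    assay = AssayConfig(contamination_prob=0.05, overdose_prob=0.10, high_cv_prob=0.08)
    return design, truth, assay


def main(seed: int) -> None:
    design, truth, assay = build_screen(seed)
    readings = cs.generate_plate_readings(design, truth, assay, seed=seed + 3)
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    write_readings(readings, SCRATCH / "screen_readings.csv")
    planted = sorted((a, b) for (a, b), e in truth.interaction_effect.items() if e < 0)
    (RESULTS / "planted_pairs.json").write_text(json.dumps([list(p) for p in planted], indent=1))
    print(
        f"simulated {len(readings)} readings: {len(design.lineages)} lines x "
        f"{len(design.conditions)} conditions x {design.n_runs} runs"
    )
    print(f"planted {len(planted)} collateral-sensitivity pairs at effect -0.5")
    print(f"readings -> {SCRATCH / 'screen_readings.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
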