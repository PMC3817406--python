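"""End-to-end convenience drivers: screen simulation through classification.

These helpers wire the stages together in their canonical order (generate ->
blank-correct -> detrend -> normalize -> QC -> infer) and provide the
operating-characteristic bookkeeping used to evaluate planted-truth
recoveries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .inference import TestConfig, infer_matrix
from .normalization import RelativeFitnessTable, blank_correct, detrend_plate, normalize_to_controls
from .plates import AssayConfig, GroundTruth, generate_plate_readings
from .qc import QcConfig, QcReport, apply_qc


@dataclass
class ScreenResult:
    readings: pd.DataFrame
    corrected: pd.DataFrame
    fitness: RelativeFitnessTable
    qc_report: QcReport


def run_screen(
    design: ExperimentDesign,
    truth: GroundTruth,
    assay_cfg: AssayConfig | None = None,
    qc_cfg: QcConfig | None = None,
    seed: int = 0,
    detrend_method: str = "median_polish",
) -> ScreenResult:
    """Simulate one full susceptibility screen and prepare it for inference."""
    readings = generate_plate_readings(design, truth, assay_cfg, seed=seed)
    corrected = blank_correct(readings)
    fitness = normalize_to_controls(detrend_plate(corrected, detrend_method), design)
    report = apply_qc(corrected, fitness, qc_cfg)
    return ScreenResult(readings, corrected, fitness, report)


def choose_cross_class_pairs(
    design: ExperimentDesign, n_pairs: int, seed: int = 0
) -> list[tuple[str, str]]:
    """Deterministically sample ordered cross-class (A, B) pairs of the design."""
    classes = dict(zip(design.antibiotics["abbreviation"], design.antibiotics["moa_class"]))
    candidates = [
        (a, b)
        for a in design.selection_antibiotics
        for b in design.antibiotics["abbreviation"]
        if a != b and classes[a] != classes[b]
    ]
    if n_pairs > len(candidates):
        raise ValueError(f"only {len(candidates)} cross-class pairs available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_pairs, replace=False)
    return [candidates[i] for i in sorted(idx)]


@dataclass
class OperatingCharacteristics:
    n_planted: int
    n_recovered: int
    n_null: int
    n_false_calls: int

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else float("nan")

    @property
    def false_call_rate(self) -> float:
        return self.n_false_calls / self.n_null if self.n_null else float("nan")


def call_rates(calls: pd.DataFrame, truth: GroundTruth) -> OperatingCharacteristics:
    """Recall over planted-sensitivity pairs and false-call rate over null pairs.

    A pair is planted when its true interaction effect is negative; null when
    exactly zero (same-class resistance defaults are neither).
    """
    planted = {p for p, e in truth.interaction_effect.items() if e < 0}
    null = {p for p, e in truth.interaction_effect.items() if e == 0 and p[0] != p[1]}
    idx = calls.set_index(["A", "B"])["classification"]
    n_rec = sum(1 for p in planted if p in idx.index and idx[p] == "collateral_sensitivity")
    testable_null = [p for p in null if p in idx.index and idx[p] != "untestable"]
    n_false = sum(1 for p in testable_null if idx[p] == "collateral_sensitivity")
    return OperatingCharacteristics(len(planted), n_rec, len(testable_null), n_false)


def infer_from_screen(
    screen: ScreenResult, design: ExperimentDesign, cfg: TestConfig | None = None
) -> pd.DataFrame:
    return infer_matrix(screen.fitness, screen.qc_report, design, cfg)
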