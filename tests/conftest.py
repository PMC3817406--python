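import numpy as np
import pandas as pd
import pytest

import colsen as cs
from colsen.normalization import blank_correct, detrend_plate, normalize_to_controls


@pytest.fixture(scope="session")
def antibiotics():
    return cs.load_antibiotics()


@pytest.fixture(scope="session")
def cross_class_table(antibiotics):
    """Four antibiotics from four different mode-of-action classes."""
    return antibiotics.iloc[[0, 4, 9, 14]].reset_index(drop=True)  # AMP LOM AMK TET


@pytest.fixture(scope="session")
def small_design(cross_class_table):
    return cs.build_design(cross_class_table, "fixed", n_replicate_lines=10, n_control_lines=10, n_runs=3)


@pytest.fixture(scope="session")
def planted_truth(small_design):
    return cs.GroundTruth.with_planted_effects(
        small_design,
        {("AMK", "TET"): -0.5, ("AMP", "TET"): -0.5},
        cost_max=0.10,
        seed=21,
    )


@pytest.fixture(scope="session")
def planted_pipeline(small_design, planted_truth):
    """Readings -> corrected -> fitness -> qc for the planted small campaign."""
    readings = cs.generate_plate_readings(small_design, planted_truth, seed=22)
    corrected = blank_correct(readings)
    fitness = normalize_to_controls(detrend_plate(corrected), small_design)
    report = cs.apply_qc(corrected, fitness)
    return readings, corrected, fitness, report
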