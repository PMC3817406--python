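"""Synthetic plate-reading generator for the susceptibility screen.

Emulates the screen's statistical structure: evolved and control lines arrayed
in technical replicates on shared plates, one plate set per (run, condition),
with blank and non-inoculated wells, smooth within-plate spatial trends,
run-to-run jitter of the applied dose strength, and optional QC failure events
(cross-contamination, overdosed conditions, noisy drug-free controls).

The generative model for an evolved line i (adapted to A) read in condition B:

    od = baseline * (1 - cost_i) * (1 + effect(A, B)) * inhibition(B, run)
         * spatial(row, col) + noise

with effect(A, B) < 0 encoding collateral sensitivity of A-adapted lines in B
and cost_i a condition-independent growth deficit.  Control lines have zero
cost and zero effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import CONTROL_REGIME, ExperimentDesign

READING_COLUMNS = (
    "run",
    "plate",
    "well_row",
    "well_col",
    "line_id",
    "condition",
    "content_type",
    "od600",
    "stage",
)

DRUG_FREE = "none"


class TruthError(ValueError):
    """Raised when the ground truth does not cover the design."""


@dataclass
class GroundTruth:
    """Planted interaction structure and noise model for the generator.

    interaction_effect
        Ordered-pair map (selection antibiotic A, test antibiotic B) ->
        relative growth change in [-1, inf); negative = collateral
        sensitivity, positive = cross-resistance.
    general_cost
        Per-line relative drug-free growth deficit in [0, 1).
    replicate_sd
        Replicate noise SD as a fraction of the baseline OD.
    spatial_amplitude
        Maximal relative amplitude of the separable row x column trend.
    run_jitter_sd
        SD of the run-to-run jitter of each condition's inhibition strength.
    """

    interaction_effect: dict[tuple[str, str], float]
    general_cost: dict[str, float] = field(default_factory=dict)
    replicate_sd: float = 0.05
    spatial_amplitude: float = 0.05
    run_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        for pair, eff in self.interaction_effect.items():
            if eff < -1:
                raise TruthError(f"effect for {pair} below -1")
        for lid, c in self.general_cost.items():
            if not 0 <= c < 1:
                raise TruthError(f"general_cost for {lid} outside [0,1)")

    @classmethod
    def null(cls, design: ExperimentDesign, **kwargs) -> "GroundTruth":
        """No interactions, no costs: every downstream call should be negative."""
        effects = {
            (a, b): 0.0
            for a in design.selection_antibiotics
            for b in design.antibiotics["abbreviation"]
        }
        return cls(interaction_effect=effects, general_cost={}, **kwargs)

    @classmethod
    def with_planted_effects(
        cls,
        design: ExperimentDesign,
        planted: dict[tuple[str, str], float],
        self_resistance: float = 0.5,
        same_class_resistance: float = 0.2,
        cost_max: float = 0.0,
        seed: int | None = None,
        **kwargs,
    ) -> "GroundTruth":
        """Null background plus planted pair effects and within-class resistance.

        Pairs within the selection antibiotic's own class default to
        cross-resistance (non-negative effects); ``planted`` overrides any
        pair.  With ``cost_max > 0`` each evolved line draws a uniform
        drug-free growth deficit on [0, cost_max].
        """
        classes = dict(
            zip(design.antibiotics["abbreviation"], design.antibiotics["moa_class"])
        )
        effects: dict[tuple[str, str], float] = {}
        for a in design.selection_antibiotics:
            for b in design.antibiotics["abbreviation"]:
                if a == b:
                    effects[(a, b)] = self_resistance
                elif classes.get(a) == classes.get(b):
                    effects[(a, b)] = same_class_resistance
                else:
                    effects[(a, b)] = 0.0
        for pair, eff in planted.items():
            if pair[0] == pair[1] or classes.get(pair[0]) == classes.get(pair[1]):
                raise TruthError(f"planted effect {pair} conflicts with same-class default")
            effects[pair] = eff
        costs: dict[str, float] = {}
        if cost_max > 0:
            rng = np.random.default_rng(seed)
            for l in design.evolved:
                costs[l.line_id] = float(rng.uniform(0.0, cost_max))
        return cls(interaction_effect=effects, general_cost=costs, **kwargs)


@dataclass(frozen=True)
class AssayConfig:
    """Geometry and nuisance parameters of the susceptibility screen."""

    plate_shape: tuple[int, int] = (16, 24)  # 384-well
    n_blank: int = 8
    n_non_inoculated: int = 8
    baseline_od: float = 0.5
    blank_od: float = 0.04
    blank_sd: float = 0.003
    target_inhibition: float = 0.5  # conditions applied at ~half-maximal effect
    contamination_prob: float = 0.0  # per plate
    overdose_prob: float = 0.0  # per (run, condition)
    high_cv_prob: float = 0.0  # per run; inflates drug-free control noise
    high_cv_factor: float = 8.0


def _well_labels(shape: tuple[int, int]) -> list[tuple[str, int]]:
    rows = [chr(ord("A") + i) for i in range(shape[0])]
    return [(r, c) for r in rows for c in range(1, shape[1] + 1)]


def _spatial_factors(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth separable multiplicative trend, unit-mean per axis."""
    nr, nc = shape
    if amplitude == 0:
        return np.ones((nr, nc))
    amp_r = rng.uniform(-amplitude, amplitude)
    amp_c = rng.uniform(-amplitude, amplitude)
    row = 1.0 + amp_r * np.linspace(-1.0, 1.0, nr)
    col = 1.0 + amp_c * np.linspace(-1.0, 1.0, nc)
    return np.outer(row, col)


def generate_plate_readings(
    design: ExperimentDesign,
    truth: GroundTruth,
    cfg: AssayConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate raw long-format OD600 readings for the full screen.

    Every line is read in every condition (all panel antibiotics plus
    drug-free) in ``design.n_tech_replicates`` adjacent wells, replicated over
    ``design.n_runs`` independent runs.  Returns a DataFrame with columns
    ``run, plate, well_row, well_col, line_id, condition, content_type, od600,
    stage`` (stage ``raw``).
    """
    cfg = cfg or AssayConfig()
    conditions = design.conditions
    abbrs = set(design.antibiotics["abbreviation"])
    for a in design.selection_antibiotics:
        for b in abbrs:
            if (a, b) not in truth.interaction_effect:
                raise TruthError(f"ground truth missing interaction_effect for pair ({a}, {b})")

    nr, nc = cfg.plate_shape
    wells = _well_labels(cfg.plate_shape)
    n_wells = nr * nc
    reserved = cfg.n_blank + cfg.n_non_inoculated
    capacity = (n_wells - reserved) // design.n_tech_replicates
    if capacity < 1:
        raise ValueError("plate too small for one line at the requested replication")

    root = np.random.SeedSequence(seed)
    run_seeds = root.spawn(design.n_runs)
    records: list[tuple] = []
    # One fixed re-array of the roster for the whole screen: scattering lines
    # (and spreading their replicates across plate blocks) decouples strain
    # identity from plate geometry, so spatial detrending cannot absorb the
    # biology of a contiguous strain block.
    layout_rng = np.random.default_rng(np.random.SeedSequence([seed, 1201]))
    order = np.arange(len(design.lineages))
    layout_rng.shuffle(order)
    lines = [design.lineages[i] for i in order]

    for run_idx in range(1, design.n_runs + 1):
        run_rng = np.random.default_rng(run_seeds[run_idx - 1])
        high_cv_run = run_rng.random() < cfg.high_cv_prob
        for condition in conditions:
            if condition == DRUG_FREE:
                inhibition = 1.0
                overdosed = False
            else:
                overdosed = run_rng.random() < cfg.overdose_prob
                if overdosed:
                    inhibition = float(run_rng.uniform(0.01, 0.08))
                else:
                    inhibition = float(
                        np.clip(
                            cfg.target_inhibition
                            + run_rng.normal(0.0, truth.run_jitter_sd),
                            0.15,
                            1.0,
                        )
                    )
            n_plates = math.ceil(len(lines) / capacity)
            for p in range(n_plates):
                plate_id = f"{condition}_p{p + 1}"
                plate_lines = lines[p * capacity : (p + 1) * capacity]
                spatial = _spatial_factors(cfg.plate_shape, truth.spatial_amplitude, run_rng)
                contaminated = run_rng.random() < cfg.contamination_prob
                for li, line in enumerate(plate_lines):
                    if line.regime == CONTROL_REGIME:
                        cost, effect = 0.0, 0.0
                    else:
                        cost = truth.general_cost.get(line.line_id, 0.0)
                        effect = (
                            0.0
                            if condition == DRUG_FREE
                            else truth.interaction_effect[(line.selection_antibiotic, condition)]
                        )
                    expected = cfg.baseline_od * (1.0 - cost) * (1.0 + effect) * inhibition
                    for rep in range(design.n_tech_replicates):
                        # replicate blocks: copy r of every line sits in the
                        # r-th quadrant of the sample area
                        w = rep * capacity + li
                        row, col = wells[w]
                        sd = truth.replicate_sd * cfg.baseline_od
                        if high_cv_run and condition == DRUG_FREE and line.regime == CONTROL_REGIME:
                            sd *= cfg.high_cv_factor
                        grid_r, grid_c = w // nc, w % nc
                        od = (
                            cfg.blank_od
                            + expected * spatial[grid_r, grid_c]
                            + run_rng.normal(0.0, sd)
                        )
                        records.append(
                            (run_idx, plate_id, row, col, line.line_id, condition, "sample", max(od, 0.0))
                        )
                # blanks then non-inoculated wells fill the tail of the plate
                for k in range(cfg.n_blank):
                    row, col = wells[n_wells - reserved + k]
                    od = cfg.blank_od + run_rng.normal(0.0, cfg.blank_sd)
                    records.append((run_idx, plate_id, row, col, "", condition, "blank", max(od, 0.0)))
                for k in range(cfg.n_non_inoculated):
                    row, col = wells[n_wells - cfg.n_non_inoculated + k]
                    od = cfg.blank_od + run_rng.normal(0.0, cfg.blank_sd)
                    if contaminated and k == 0:
                        od += float(run_rng.uniform(0.15, 0.5))
                    records.append(
                        (run_idx, plate_id, row, col, "", condition, "non_inoculated", max(od, 0.0))
                    )
    out = pd.DataFrame.from_records(
        records,
        columns=[c for c in READING_COLUMNS if c != "stage"],
    )
    out["stage"] = "raw"
    return out


def write_readings(readings: pd.DataFrame, path) -> None:
    readings.to_csv(path, index=False)


def read_readings(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = [c for c in READING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"readings file missing columns: {missing}")
    df["od600"] = df["od600"].astype(float)
    df["run"] = df["run"].astype(int)
    return df


def simulate_growth_curves(
    n_curves: int = 200,
    seed: int = 0,
    read_time_h: float = 14.0,
    dt_h: float = 0.25,
    rate_range: tuple[float, float] = (0.9, 1.05),
    capacity_range: tuple[float, float] = (0.05, 1.0),
    n0: float = 1e-3,
) -> pd.DataFrame:
    """Logistic growth-curve ensemble linking endpoint OD to growth-curve AUC.

    Sublethal inhibition in this system acts mainly on the attainable yield,
    with comparatively uniform exponential rates, so the ensemble varies the
    carrying capacity widely (log-uniform) and the rate narrowly.  Returns one
    row per curve with the single-timepoint OD at ``read_time_h`` and the
    trapezoidal area under the full curve.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, read_time_h + dt_h / 2, dt_h)
    rows = []
    for i in range(n_curves):
        k = float(np.exp(rng.uniform(np.log(capacity_range[0]), np.log(capacity_range[1]))))
        r = float(rng.uniform(*rate_range))
        od = k / (1.0 + ((k - n0) / n0) * np.exp(-r * t))
        rows.append((i, od[-1], float(np.trapezoid(od, t)), k, r))
    return pd.DataFrame(rows, columns=["curve", "od_at_read", "auc", "capacity", "rate"])
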