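"""Raw OD to relative fitness: blank correction, detrending, control scaling.

The pipeline is staged and order-enforced:

1. ``blank_correct`` subtracts each plate's blank-well mean (clamping at 0).
2. ``detrend_plate`` removes smooth within-plate trends by iterative median
   polish on the log scale (multiplicative row x column effects).
3. ``normalize_to_controls`` divides by the per-run mean of drug-free
   adapted-control wells, then summarizes each line x condition x run by the
   median over technical replicates.

Each function checks the incoming stage and refuses to re-apply itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CONTROL_REGIME, ExperimentDesign
from .plates import DRUG_FREE

STAGES = ("raw", "blank_corrected", "detrended", "normalized")


class StageError(RuntimeError):
    """Raised when a normalization stage is applied out of order."""


class NormalizationError(ValueError):
    pass


def _check_stage(readings: pd.DataFrame, expected: str) -> None:
    stages = readings["stage"].unique()
    if len(stages) != 1 or stages[0] != expected:
        raise StageError(f"expected stage {expected!r}, found {sorted(map(str, stages))}")


def blank_correct(readings: pd.DataFrame) -> pd.DataFrame:
    """Subtract each (run, plate)'s blank-well mean OD; clamp negatives to 0."""
    _check_stage(readings, "raw")
    out = readings.copy()
    blanks = out[out["content_type"] == "blank"]
    have = set(map(tuple, blanks[["run", "plate"]].drop_duplicates().itertuples(index=False)))
    need = set(map(tuple, out[["run", "plate"]].drop_duplicates().itertuples(index=False)))
    missing = sorted(need - have)
    if missing:
        raise NormalizationError(f"plates without blank wells: {missing}")
    blank_mean = blanks.groupby(["run", "plate"])["od600"].mean()
    correction = pd.MultiIndex.from_frame(out[["run", "plate"]]).map(blank_mean)
    out["od600"] = np.maximum(out["od600"].to_numpy() - correction.to_numpy(), 0.0)
    out["stage"] = "blank_corrected"
    return out


def median_polish(
    matrix: np.ndarray, max_iter: int = 20, tol: float = 1e-10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D array (NaN-aware).

    Decomposes ``matrix ~ overall + row + col + residual`` by alternately
    sweeping out row and column medians, moving the median of each effect
    vector into the overall term.  Returns (overall, row_effects,
    col_effects, residuals).
    """
    resid = np.asarray(matrix, dtype=float).copy()
    if resid.ndim != 2:
        raise ValueError("median_polish expects a 2-D array")
    nr, nc = resid.shape
    overall = 0.0
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    for _ in range(max_iter):
        with np.errstate(all="ignore"):
            rmed = np.nanmedian(resid, axis=1)
        rmed = np.where(np.isnan(rmed), 0.0, rmed)
        resid -= rmed[:, None]
        row_eff += rmed
        shift = np.median(row_eff)
        row_eff -= shift
        overall += shift
        with np.errstate(all="ignore"):
            cmed = np.nanmedian(resid, axis=0)
        cmed = np.where(np.isnan(cmed), 0.0, cmed)
        resid -= cmed[None, :]
        col_eff += cmed
        shift = np.median(col_eff)
        col_eff -= shift
        overall += shift
        change = max(np.max(np.abs(rmed)), np.max(np.abs(cmed)))
        if change < tol:
            break
    return overall, row_eff, col_eff, resid


def detrend_plate(readings: pd.DataFrame, method: str = "median_polish") -> pd.DataFrame:
    """Remove multiplicative within-plate row/column trends from sample wells.

    Positive sample ODs are log-transformed and median-polished per (run,
    plate); the fitted row and column effects are divided out.  Zero wells and
    blank/non-inoculated wells pass through unchanged.
    """
    _check_stage(readings, "blank_corrected")
    if method not in ("median_polish", "none"):
        raise NormalizationError(f"unknown detrend method {method!r}")
    out = readings.copy()
    if method == "none":
        out["stage"] = "detrended"
        return out
    od = out["od600"].to_numpy().copy()
    for (_, _), idx in out.groupby(["run", "plate"]).groups.items():
        sub = out.loc[idx]
        mask = (sub["content_type"] == "sample") & (sub["od600"] > 0)
        sample = sub[mask]
        if len(sample) < 2:
            continue
        rows = sorted(sample["well_row"].unique())
        cols = sorted(sample["well_col"].unique())
        ri = {r: i for i, r in enumerate(rows)}
        ci = {c: j for j, c in enumerate(cols)}
        mat = np.full((len(rows), len(cols)), np.nan)
        for r, c, v in zip(sample["well_row"], sample["well_col"], sample["od600"]):
            mat[ri[r], ci[c]] = np.log(v)
        _, row_eff, col_eff, _ = median_polish(mat)
        pos = sample.index.to_numpy()
        trend = np.array(
            [row_eff[ri[r]] + col_eff[ci[c]] for r, c in zip(sample["well_row"], sample["well_col"])]
        )
        locs = out.index.get_indexer(pos)
        od[locs] = np.exp(np.log(sample["od600"].to_numpy()) - trend)
    out["od600"] = od
    out["stage"] = "detrended"
    return out


@dataclass
class RelativeFitnessTable:
    """Well-level relative fitness plus per-line median summaries.

    wells
        Long table with every corrected sample well and its
        ``relative_fitness`` (corrected OD over the run's drug-free
        adapted-control mean).
    summary
        One row per (run, condition, line_id) with the median over technical
        replicates, the line's group (evolved/control) and selection drug.
    reference
        Per-run drug-free control mean used as denominator.
    """

    wells: pd.DataFrame
    summary: pd.DataFrame
    reference: pd.Series


def normalize_to_controls(
    readings: pd.DataFrame, design: ExperimentDesign
) -> RelativeFitnessTable:
    """Scale corrected ODs to per-run drug-free adapted-control means."""
    _check_stage(readings, "detrended")
    samples = readings[readings["content_type"] == "sample"].copy()
    control_ids = {l.line_id for l in design.controls}
    ref_rows = samples[
        (samples["condition"] == DRUG_FREE) & samples["line_id"].isin(control_ids)
    ]
    refs = ref_rows.groupby("run")["od600"].mean()
    missing = sorted(set(samples["run"].unique()) - set(refs.index))
    if missing:
        raise NormalizationError(f"runs without drug-free adapted-control wells: {missing}")
    if (refs <= 0).any():
        bad = refs[refs <= 0].index.tolist()
        raise NormalizationError(f"non-positive control reference in runs: {bad}")
    samples["relative_fitness"] = samples["od600"].to_numpy() / samples["run"].map(refs).to_numpy()
    samples["stage"] = "normalized"
    selection = {l.line_id: l.selection_antibiotic for l in design.lineages}
    group = {l.line_id: ("control" if l.regime == CONTROL_REGIME else "evolved") for l in design.lineages}
    samples["group"] = samples["line_id"].map(group)
    samples["selection_antibiotic"] = samples["line_id"].map(selection)
    summary = (
        samples.groupby(["run", "condition", "line_id"], as_index=False)
        .agg(fitness=("relative_fitness", "median"), n_replicates=("relative_fitness", "size"))
    )
    summary["group"] = summary["line_id"].map(group)
    summary["selection_antibiotic"] = summary["line_id"].map(selection)
    return RelativeFitnessTable(wells=samples, summary=summary, reference=refs)
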