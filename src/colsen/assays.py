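"""Phenotype assay computations: MIC, IC50, dye accumulation, membrane potential.

- MIC from linear broth dilution: the lowest concentration whose replicate-mean
  OD falls below a cutoff of blank mean + 2 SD.
- IC50 from a dose-response series by linear interpolation at half the
  drug-free growth.
- Hoechst 33342 accumulation: area under the smoothed fluorescence/OD ratio
  curve (first 15 kinetic points dropped), relative to wild-type controls.
- Membrane potential: red/green fluorescence ratios relative to wild-type
  controls, compared between groups with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import RankSumResult, rank_sum_test

log = logging.getLogger(__name__)


class AssayError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Dose-response: MIC and IC50


@dataclass
class DoseSeries:
    """Replicate OD readings over a ladder of increasing concentrations.

    ``od`` has shape (n_steps, n_replicates).  ``drug_free_od`` holds
    replicate ODs without drug (required for IC50, not for MIC).
    """

    concentrations: np.ndarray
    od: np.ndarray
    blank_od: np.ndarray
    drug_free_od: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.od = np.atleast_2d(np.asarray(self.od, dtype=float))
        self.blank_od = np.asarray(self.blank_od, dtype=float)
        if np.any(np.diff(self.concentrations) <= 0):
            raise AssayError("concentrations must be strictly increasing")
        if self.od.shape[0] != len(self.concentrations):
            raise AssayError("od must have one row per concentration step")

    def step_means(self) -> np.ndarray:
        return self.od.mean(axis=1)


@dataclass(frozen=True)
class MicResult:
    value: float  # concentration; the highest tested one when above range
    above_range: bool

    def __float__(self) -> float:
        return self.value


def call_mic(series: DoseSeries) -> MicResult:
    """MIC = lowest concentration with replicate-mean OD strictly below
    blank mean + 2 blank SD; above-range flag when growth persists at the top
    concentration."""
    if len(series.blank_od) < 2:
        raise AssayError("need >= 2 blank wells to define the MIC cutoff")
    cutoff = float(series.blank_od.mean() + 2.0 * series.blank_od.std(ddof=1))
    means = series.step_means()
    below = np.flatnonzero(means < cutoff)
    if len(below) == 0:
        return MicResult(float(series.concentrations[-1]), above_range=True)
    return MicResult(float(series.concentrations[below[0]]), above_range=False)


@dataclass(frozen=True)
class FoldChange:
    value: float
    lower_bound: bool  # evolved MIC censored above range: true fold is >= value

    def __float__(self) -> float:
        return self.value


def fold_mic(mic_evolved: MicResult, mic_ancestor: MicResult) -> FoldChange:
    """Fold change of MIC; an above-range numerator yields a flagged lower bound."""
    if mic_ancestor.above_range:
        raise AssayError("ancestor MIC above tested range; fold change undefined")
    if mic_ancestor.value <= 0:
        raise AssayError("ancestor MIC must be positive")
    return FoldChange(mic_evolved.value / mic_ancestor.value, mic_evolved.above_range)


@dataclass(frozen=True)
class Ic50Result:
    value: float
    flag: str  # "", "below_range", "above_range"


def ic50(series: DoseSeries, monotone_tol: float = 0.05) -> Ic50Result:
    """Concentration at half of the drug-free OD, by linear interpolation.

    The replicate-averaged series must be monotone non-increasing within
    ``monotone_tol`` (as a fraction of the drug-free mean).  Flags are raised
    when the half-maximal point lies outside the tested range.
    """
    if series.drug_free_od is None:
        raise AssayError("IC50 requires drug-free replicate ODs")
    free = float(np.mean(series.drug_free_od))
    if free <= 0:
        raise AssayError("drug-free OD must be positive")
    means = series.step_means()
    if np.any(np.diff(means) > monotone_tol * free):
        raise AssayError("dose-response series is not monotone non-increasing")
    frac = means / free
    half = 0.5
    if frac[0] < half:
        return Ic50Result(float(series.concentrations[0]), "below_range")
    crossing = np.flatnonzero(frac < half)
    if len(crossing) == 0:
        return Ic50Result(float(series.concentrations[-1]), "above_range")
    i = int(crossing[0])
    c0, c1 = series.concentrations[i - 1], series.concentrations[i]
    f0, f1 = frac[i - 1], frac[i]
    if f0 == half:
        return Ic50Result(float(c0), "")
    value = c0 + (f0 - half) / (f0 - f1) * (c1 - c0)
    return Ic50Result(float(value), "")


# ---------------------------------------------------------------------------
# Hoechst accumulation


@dataclass
class KineticCurve:
    """Paired OD600 and fluorescence kinetics for one well (75-s cadence)."""

    time_s: np.ndarray
    od600: np.ndarray
    fluorescence: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if not (len(self.time_s) == len(self.od600) == len(self.fluorescence)):
            raise AssayError("time, OD and fluorescence series must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise AssayError("time points must be strictly increasing")


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; window shrinks symmetrically at the edges
    (so constants and straight lines pass through unchanged)."""
    half = window // 2
    n = len(values)
    out = np.empty(n, dtype=float)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = values[i - h : i + h + 1].mean()
    return out


def ratio_curve_auc(
    curve: KineticCurve, drop_first: int = 15, smooth_window: int = 5
) -> float:
    """Trapezoidal AUC of the smoothed fluorescence/OD ratio curve."""
    t = curve.time_s[drop_first:]
    od = _smooth(curve.od600[drop_first:], smooth_window)
    fl = _smooth(curve.fluorescence[drop_first:], smooth_window)
    if len(t) < 2:
        raise AssayError("fewer than 2 retained kinetic points")
    keep = od > 0
    if not keep.all():
        log.warning(
            "curve %s: excluding %d points with non-positive OD",
            curve.replicate_id,
            int((~keep).sum()),
        )
    t, od, fl = t[keep], od[keep], fl[keep]
    if len(t) < 2:
        raise AssayError("fewer than 2 positive-OD kinetic points")
    return float(np.trapezoid(fl / od, t))


def hoechst_relative_accumulation(
    curves: list[KineticCurve],
    wild_type_curves: list[KineticCurve],
    drop_first: int = 15,
    smooth_window: int = 5,
) -> np.ndarray:
    """Per-curve ratio-curve AUC divided by the mean wild-type AUC."""
    if not curves or not wild_type_curves:
        raise AssayError("need >= 1 sample and >= 1 wild-type curve")
    wt = np.mean([ratio_curve_auc(c, drop_first, smooth_window) for c in wild_type_curves])
    if wt <= 0:
        raise AssayError("wild-type AUC must be positive")
    return np.array([ratio_curve_auc(c, drop_first, smooth_window) / wt for c in curves])


# ---------------------------------------------------------------------------
# Membrane potential (DiOC2(3) red/green ratio)

WILD_TYPE_GROUP = "wild_type"


@dataclass(frozen=True)
class PotentialComparison:
    ratios: pd.DataFrame  # population, group, relative_ratio
    test: RankSumResult
    groups: tuple[str, str]


def potential_ratio_comparison(
    measurements: pd.DataFrame,
    group_a: str = "aminoglycoside",
    group_b: str = "other",
) -> PotentialComparison:
    """Relative red/green ratios and a two-sided rank-sum group comparison.

    ``measurements`` needs columns population, group, red, green; the
    ``wild_type`` group (>= 3 populations) anchors the relative ratios.
    """
    required = {"population", "group", "red", "green"}
    if not required.issubset(measurements.columns):
        raise AssayError(f"measurements need columns {sorted(required)}")
    if (measurements["green"] <= 0).any():
        raise AssayError("green fluorescence must be positive")
    wt = measurements[measurements["group"] == WILD_TYPE_GROUP]
    if len(wt) < 3:
        raise AssayError("need >= 3 wild-type control populations")
    wt_mean = float((wt["red"] / wt["green"]).mean())
    out = measurements.copy()
    out["relative_ratio"] = (out["red"] / out["green"]) / wt_mean
    a = out.loc[out["group"] == group_a, "relative_ratio"].to_numpy()
    b = out.loc[out["group"] == group_b, "relative_ratio"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise AssayError("both comparison groups must be non-empty")
    res = rank_sum_test(a, b, alternative="two-sided")
    return PotentialComparison(
        ratios=out[["population", "group", "relative_ratio"]],
        test=res,
        groups=(group_a, group_b),
    )


# ---------------------------------------------------------------------------
# Synthetic assay inputs


def simulate_dose_series(
    ic50_true: float,
    concentrations: np.ndarray | None = None,
    hill: float = 2.0,
    max_od: float = 0.6,
    noise_sd: float = 0.0,
    n_replicates: int = 4,
    seed: int = 0,
) -> DoseSeries:
    """Logistic dose-response series over 12 linear dilution steps."""
    rng = np.random.default_rng(seed)
    if concentrations is None:
        concentrations = np.linspace(1.0, 12.0, 12)
    conc = np.asarray(concentrations, dtype=float)
    mean = max_od / (1.0 + (conc / ic50_true) ** hill)
    od = mean[:, None] + rng.normal(0.0, noise_sd, size=(len(conc), n_replicates))
    blanks = 0.03 + rng.normal(0.0, 0.002, size=4)
    free = max_od + rng.normal(0.0, noise_sd, size=n_replicates)
    return DoseSeries(conc, np.maximum(od, 0.0), blanks, drug_free_od=free)


def simulate_kinetic_curve(
    ratio_fn,
    n_points: int = 49,
    dt_s: float = 75.0,
    od_level: float = 0.3,
    seed: int = 0,
    noise_sd: float = 0.0,
    replicate_id: str = "sim",
) -> KineticCurve:
    """Kinetic curve whose true fluorescence/OD ratio follows ``ratio_fn(t)``."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt_s
    od = np.full(n_points, od_level) + rng.normal(0.0, noise_sd, n_points)
    fl = np.array([ratio_fn(ti) for ti in t]) * od
    return KineticCurve(t, od, fl, replicate_id)
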