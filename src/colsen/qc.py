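"""Run/condition exclusion filters applied before interaction inference.

Three rules, mirroring the screen's quality-control procedure:

- contamination: growth in any non-inoculated well of a plate excludes every
  condition measured on that plate in that run (threshold on blank-corrected
  OD, inclusive);
- high CV: a run whose drug-free adapted-control wells have coefficient of
  variation strictly above the limit is excluded entirely;
- overdose: a (run, condition) in which the adapted-control group's mean
  fitness falls strictly below (1 - limit) times its drug-free mean is
  excluded (the dose was too strong to reveal collateral sensitivity).

Boundary conventions (>= for contamination, > for CV, < for overdose) are
fixed here and unit-tested; tightening any threshold can only shrink the
retained set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .normalization import RelativeFitnessTable
from .plates import DRUG_FREE

REASONS = ("contamination", "high_cv", "overdose")


class QcError(ValueError):
    pass


@dataclass(frozen=True)
class QcConfig:
    cv_limit: float = 0.20
    overdose_inhibition_limit: float = 0.90
    contamination_od: float = 0.05

    def __post_init__(self) -> None:
        for name in ("cv_limit", "overdose_inhibition_limit", "contamination_od"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise QcError(f"{name} must lie in (0, 1]")


@dataclass
class QcReport:
    """Per (run, condition) retention decision with supporting statistics."""

    table: pd.DataFrame  # run, condition, status, reasons, cv, control_mean, max_non_inoculated

    def retained(self) -> set[tuple[int, str]]:
        keep = self.table[self.table["status"] == "retained"]
        return set(zip(keep["run"], keep["condition"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def check_contamination(
    readings: pd.DataFrame, cfg: QcConfig | None = None
) -> pd.DataFrame:
    """Flag (run, condition) pairs measured on plates showing growth in
    non-inoculated wells.  Expects blank-corrected readings."""
    cfg = cfg or QcConfig()
    ni = readings[readings["content_type"] == "non_inoculated"]
    if len(ni) == 0:
        import warnings

        warnings.warn("layout has no non-inoculated wells; contamination check skipped")
        out = readings[["run", "condition"]].drop_duplicates().reset_index(drop=True)
        out["contaminated"] = False
        out["max_non_inoculated"] = np.nan
        return out
    plate_max = ni.groupby(["run", "plate"])["od600"].max()
    flagged_plates = set(plate_max[plate_max >= cfg.contamination_od].index)
    cond = readings[["run", "plate", "condition"]].drop_duplicates()
    cond["plate_flag"] = [
        (r, p) in flagged_plates for r, p in zip(cond["run"], cond["plate"])
    ]
    out = (
        cond.groupby(["run", "condition"], as_index=False)
        .agg(contaminated=("plate_flag", "any"))
    )
    stat = ni.groupby(["run", "condition"])["od600"].max().rename("max_non_inoculated")
    return out.merge(stat.reset_index(), on=["run", "condition"], how="left")


def check_control_cv(fitness: RelativeFitnessTable, cfg: QcConfig | None = None) -> pd.DataFrame:
    """Per-run CV of drug-free adapted-control wells; strict > excludes."""
    cfg = cfg or QcConfig()
    wells = fitness.wells
    ctrl = wells[(wells["condition"] == DRUG_FREE) & (wells["group"] == "control")]
    if "group" not in wells.columns:
        raise QcError("fitness wells lack group annotation")
    rows = []
    for run, sub in ctrl.groupby("run"):
        vals = sub["relative_fitness"].to_numpy()
        if len(vals) < 2:
            raise QcError(f"run {run}: fewer than 2 drug-free control wells")
        cv = float(np.std(vals, ddof=1) / np.mean(vals))
        rows.append((run, cv, cv > cfg.cv_limit))
    return pd.DataFrame(rows, columns=["run", "cv", "high_cv"])


def check_overdose(fitness: RelativeFitnessTable, cfg: QcConfig | None = None) -> pd.DataFrame:
    """Flag conditions that suppress the adapted-control group too strongly."""
    cfg = cfg or QcConfig()
    summary = fitness.summary
    ctrl = summary[summary["group"] == "control"]
    if len(ctrl) == 0:
        raise QcError("no adapted-control measurements available")
    means = ctrl.groupby(["run", "condition"])["fitness"].mean().rename("control_mean")
    free = means.unstack("condition")
    if DRUG_FREE not in free.columns:
        raise QcError("no drug-free control measurements available")
    rows = []
    for (run, condition), m in means.items():
        ref = free.loc[run, DRUG_FREE]
        if condition == DRUG_FREE:
            rows.append((run, condition, m, ref, False))
            continue
        threshold = (1.0 - cfg.overdose_inhibition_limit) * ref
        rows.append((run, condition, m, ref, bool(m < threshold)))
    return pd.DataFrame(
        rows, columns=["run", "condition", "control_mean", "control_free_mean", "overdose"]
    )


def apply_qc(
    readings_blank_corrected: pd.DataFrame,
    fitness: RelativeFitnessTable,
    cfg: QcConfig | None = None,
) -> QcReport:
    """Combine the three filters; a (run, condition) is retained iff no flag."""
    cfg = cfg or QcConfig()
    contam = check_contamination(readings_blank_corrected, cfg)
    cv = check_control_cv(fitness, cfg)
    over = check_overdose(fitness, cfg)
    merged = contam.merge(over, on=["run", "condition"], how="outer").merge(cv, on="run", how="left")
    merged["contaminated"] = merged["contaminated"].fillna(False)
    merged["overdose"] = merged["overdose"].fillna(False)
    merged["high_cv"] = merged["high_cv"].fillna(False)
    reasons = []
    for _, r in merged.iterrows():
        rs = []
        if r["contaminated"]:
            rs.append("contamination")
        if r["high_cv"]:
            rs.append("high_cv")
        if r["overdose"]:
            rs.append("overdose")
        reasons.append(",".join(rs))
    merged["reasons"] = reasons
    merged["status"] = np.where(merged["reasons"] == "", "retained", "excluded")
    cols = [
        "run",
        "condition",
        "status",
        "reasons",
        "cv",
        "control_mean",
        "control_free_mean",
        "max_non_inoculated",
    ]
    return QcReport(table=merged[cols].sort_values(["run", "condition"]).reset_index(drop=True))
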