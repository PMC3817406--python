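"""Experimental design for serial-transfer evolution and susceptibility screens.

Two selection regimes are modelled.  Under the fixed regime, replicate lines
evolve at a constant sublethal dose (around the ancestral IC50) of each panel
antibiotic.  Under the gradient regime, dose escalates 1.5-fold every fourth
transfer, and only the flagged subset of antibiotics is used.  Drug-free
"adapted control" lines propagated for the same duration provide the reference
group for all downstream comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .antibiotics import validate_antibiotics

CONTROL_REGIME = "control"
REGIMES = ("fixed", "gradient")


class DesignError(ValueError):
    """Raised for invalid experimental-design requests."""


@dataclass(frozen=True)
class EvolutionParams:
    """Parameters of the serial-transfer protocol.

    dilution_factor
        Daily dilution into fresh medium; 100-fold allows log2(100) ~ 6.6
        doublings per transfer.
    dose_multiplier, transfer_interval_for_ramp
        Under the gradient regime the dose is multiplied by ``dose_multiplier``
        every ``transfer_interval_for_ramp`` transfers.
    extinction_od
        A population failing to reach this OD600 at the end of a transfer is
        scored extinct.
    start_dose
        Starting dose in multiples of the ancestral IC50.
    survivor_stop_count
        The escalation campaign for an antibiotic stops once at most this many
        populations still grow.
    solubility_limit
        Upper dose bound (same IC50 units as ``start_dose``).
    """

    dilution_factor: float = 100.0
    dose_multiplier: float = 1.5
    transfer_interval_for_ramp: int = 4
    extinction_od: float = 0.05
    start_dose: float = 1.0
    survivor_stop_count: int = 10
    solubility_limit: float = math.inf

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise DesignError("dilution_factor must exceed 1")
        if self.dose_multiplier <= 1:
            raise DesignError("dose_multiplier must exceed 1")
        if self.extinction_od <= 0:
            raise DesignError("extinction_od must be positive")
        if self.transfer_interval_for_ramp < 1:
            raise DesignError("transfer_interval_for_ramp must be >= 1")

    @property
    def generations_per_transfer(self) -> float:
        return math.log2(self.dilution_factor)


@dataclass(frozen=True)
class LineageRecord:
    """One evolving population: its regime, selection drug, and replicate index."""

    line_id: str
    regime: str
    selection_antibiotic: str | None
    replicate_index: int

    def __post_init__(self) -> None:
        if (self.regime == CONTROL_REGIME) != (self.selection_antibiotic is None):
            raise DesignError(
                f"line {self.line_id}: regime=control iff selection_antibiotic is None"
            )


@dataclass
class ExperimentDesign:
    """Roster of evolved and control lineages plus screen replication settings."""

    antibiotics: pd.DataFrame
    lineages: list[LineageRecord]
    regime: str
    n_runs: int = 4
    n_tech_replicates: int = 4
    params: EvolutionParams = field(default_factory=EvolutionParams)

    @property
    def evolved(self) -> list[LineageRecord]:
        return [l for l in self.lineages if l.regime != CONTROL_REGIME]

    @property
    def controls(self) -> list[LineageRecord]:
        return [l for l in self.lineages if l.regime == CONTROL_REGIME]

    @property
    def selection_antibiotics(self) -> list[str]:
        seen: list[str] = []
        for l in self.evolved:
            if l.selection_antibiotic not in seen:
                seen.append(l.selection_antibiotic)  # type: ignore[arg-type]
        return seen

    @property
    def conditions(self) -> list[str]:
        """Assay conditions: every panel antibiotic plus drug-free medium."""
        return list(self.antibiotics["abbreviation"]) + ["none"]

    def selection_of(self, line_id: str) -> str | None:
        for l in self.lineages:
            if l.line_id == line_id:
                return l.selection_antibiotic
        raise KeyError(line_id)

    def roster(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "line_id": [l.line_id for l in self.lineages],
                "regime": [l.regime for l in self.lineages],
                "selection_antibiotic": [l.selection_antibiotic for l in self.lineages],
                "replicate_index": [l.replicate_index for l in self.lineages],
            }
        )


def build_design(
    antibiotics: pd.DataFrame,
    regime: str,
    n_replicate_lines: int = 10,
    n_control_lines: int = 10,
    n_runs: int = 4,
    n_tech_replicates: int = 4,
    params: EvolutionParams | None = None,
) -> ExperimentDesign:
    """Construct the lineage roster for one selection regime.

    Under ``regime="fixed"`` every antibiotic in the table is used; under
    ``"gradient"`` only rows with ``gradient_flag``.  The lineage count is
    (#antibiotics used x n_replicate_lines) + n_control_lines, deterministically
    ordered.
    """
    if regime not in REGIMES:
        raise DesignError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    table = validate_antibiotics(antibiotics)
    if regime == "gradient":
        # no flagged rows yields a control-only design
        table = table[table["gradient_flag"]].reset_index(drop=True)
    lineages: list[LineageRecord] = []
    if n_replicate_lines > 0:
        for abbr in table["abbreviation"]:
            for i in range(1, n_replicate_lines + 1):
                lineages.append(
                    LineageRecord(
                        line_id=f"{abbr}_{i:02d}",
                        regime=regime,
                        selection_antibiotic=abbr,
                        replicate_index=i,
                    )
                )
    for i in range(1, n_control_lines + 1):
        lineages.append(
            LineageRecord(
                line_id=f"CTRL_{i:02d}",
                regime=CONTROL_REGIME,
                selection_antibiotic=None,
                replicate_index=i,
            )
        )
    return ExperimentDesign(
        antibiotics=validate_antibiotics(antibiotics),
        lineages=lineages,
        regime=regime,
        n_runs=n_runs,
        n_tech_replicates=n_tech_replicates,
        params=params or EvolutionParams(),
    )
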