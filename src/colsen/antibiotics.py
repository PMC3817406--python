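"""Antibiotic annotation table: names, class labels, and selection-regime flags.

The packaged default table lists the 24 antibiotics of the screening panel with
their mode-of-action class, cidality, and a flag marking the 12-member subset
used for the dose-escalation selection regime.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = ("name", "abbreviation", "moa_class", "cidality", "gradient_flag")

AMINOGLYCOSIDE_CLASS = "Aminoglycoside"


class AntibioticTableError(ValueError):
    """Raised when an antibiotic annotation table violates its invariants."""


def validate_antibiotics(table: pd.DataFrame) -> pd.DataFrame:
    """Validate an antibiotic annotation table and coerce column dtypes.

    Parameters
    ----------
    table
        DataFrame with columns ``name``, ``abbreviation``, ``moa_class``,
        ``cidality`` and ``gradient_flag``.

    Returns
    -------
    A validated copy with ``gradient_flag`` as bool.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise AntibioticTableError(f"antibiotic table missing columns: {missing}")
    out = table.loc[:, list(REQUIRED_COLUMNS)].copy()
    if len(out) == 0:
        raise AntibioticTableError("antibiotic table is empty")
    dup = out["abbreviation"][out["abbreviation"].duplicated()].tolist()
    if dup:
        raise AntibioticTableError(f"duplicate abbreviations: {sorted(set(dup))}")
    if out["moa_class"].isna().any() or (out["moa_class"].astype(str).str.len() == 0).any():
        raise AntibioticTableError("moa_class must be non-empty for every antibiotic")
    out["gradient_flag"] = out["gradient_flag"].astype(bool)
    out["abbreviation"] = out["abbreviation"].astype(str)
    return out.reset_index(drop=True)


def load_antibiotics(path: str | Path | None = None) -> pd.DataFrame:
    """Load an antibiotic annotation TSV; defaults to the packaged 24-drug panel."""
    if path is None:
        source = resources.files("colsen").joinpath("data/antibiotics.tsv")
        with resources.as_file(source) as p:
            raw = pd.read_csv(p, sep="\t")
    else:
        raw = pd.read_csv(path, sep="\t")
    return validate_antibiotics(raw)


def class_map(table: pd.DataFrame) -> dict[str, str]:
    """Map abbreviation -> mode-of-action class."""
    return dict(zip(table["abbreviation"], table["moa_class"]))
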