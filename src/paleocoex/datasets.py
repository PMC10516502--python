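"""Loaders for the packaged region-level summary tables.

Three fixture tables ship with the package, transcribed verbatim from the
published region summaries: productivity/CC statistics per region, and the
region chronologies under the two chronometric filtering tiers.  Ages are
ka BP; NPP is kg/m^2/yr; CC columns are kg/km^2/yr.

The published no-coexistence partition (regions where the NAI end predates
the SAI start) is shipped as data because it cannot be rederived from the
printed chronology tables alone.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .coexistence import BoundaryEstimate

__all__ = [
    "load_productivity_table",
    "load_chronology_table",
    "chronology_boundaries",
    "NO_COEXISTENCE_REGIONS",
]

#: regions without NAI/SAI temporal overlap, as published
NO_COEXISTENCE_REGIONS = ("R_2", "R_3", "R_13", "R_16")


def _read(name: str) -> pd.DataFrame:
    with resources.files("paleocoex.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_productivity_table() -> pd.DataFrame:
    """Region-level NPP and size-class CC summary (indexed by region id)."""
    return _read("table1_productivity.csv").set_index("region")


def load_chronology_table(criteria: int | str = 1) -> pd.DataFrame:
    """Region chronology under filtering tier 1 or 2 (indexed by region id).

    Columns: nai_mode, nai_hpd68_young/old, nai_hpd95_young/old and the
    same for sai; NaN where a phase is not represented under the tier.
    """
    tier = str(criteria).lstrip("fc") or "1"
    if tier not in ("1", "2"):
        raise ValueError("criteria must be 1/2 (or 'fc1'/'fc2')")
    return _read(f"table{int(tier) + 1}_chronology_fc{tier}.csv").set_index("region")


def chronology_boundaries(
    criteria: int | str = 1,
) -> dict[str, dict[str, BoundaryEstimate | None]]:
    """Fixture chronology as BoundaryEstimate pairs per region."""
    df = load_chronology_table(criteria)
    out: dict[str, dict[str, BoundaryEstimate | None]] = {}
    for region, row in df.iterrows():
        entry = {}
        for side in ("nai", "sai"):
            if pd.isna(row[f"{side}_mode"]):
                entry[side] = None
                continue
            entry[side] = BoundaryEstimate(
                mode=float(row[f"{side}_mode"]),
                hpd68=(float(row[f"{side}_hpd68_young"]), float(row[f"{side}_hpd68_old"])),
                hpd95=(float(row[f"{side}_hpd95_young"]), float(row[f"{side}_hpd95_old"])),
            )
        out[region] = entry
    return out
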