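"""Quality filtering and techno-complex attribution of chronometric dates.

Two filtering tiers are applied throughout the package:

* FC1 — keep every date that passes the laboratory quality bar: AMS
  (ultrafiltration or not) and ABOx-SC radiocarbon plus luminescence and
  U-series; drop conventional radiocarbon, dates flagged for contamination,
  low collagen yield or burnt bone, and dates whose relative error
  (error/age) is 0.05 or larger.
* FC2 — additionally keep only dates measured on material brought or
  modified by humans (anthropic flag).

Techno-complexes are mapped onto the two species proxies: NAI
(Neanderthal-associated industries) and SAI (H. sapiens-associated
industries).  The Szeletian, Bohunician and LRJ lack diagnostic human
fossils and are always excluded.  The debated Chatelperronian/Uluzzian
attributions are exposed as toggles for sensitivity runs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .calibration import NON_RADIOCARBON_METHODS, RADIOCARBON_METHODS, VALID_METHODS

__all__ = [
    "DEFAULT_ATTRIBUTION",
    "ALWAYS_EXCLUDED",
    "DATE_COLUMNS",
    "filter_dates",
    "read_dates",
    "write_dates",
]

logger = logging.getLogger(__name__)

DEFAULT_ATTRIBUTION: dict[str, str] = {
    "Mousterian": "NAI",
    "Micoquian": "NAI",
    "Chatelperronian": "NAI",
    "Aurignacian": "SAI",
    "Initial Upper Paleolithic": "SAI",
    "Neronian": "SAI",
    "Uluzzian": "SAI",
    "paleontological": "excluded",
}
ALWAYS_EXCLUDED = frozenset({"Szeletian", "Bohunician", "LRJ"})

#: canonical columns of a date table (the 'units' column is mandatory)
DATE_COLUMNS = [
    "site",
    "latitude",
    "longitude",
    "level",
    "techno_complex",
    "method",
    "material",
    "anthropic",
    "marine",
    "age",
    "error",
    "units",
    "contamination",
    "low_collagen",
    "burnt_bone",
    "same_sample",
]

MAX_RELATIVE_ERROR = 0.05


def read_dates(path) -> pd.DataFrame:
    """Read a delimited date table and normalize every age to ka BP.

    The file must carry the documented header including a ``units`` column
    ('yr' or 'ka') declaring the scale of ``age`` and ``error`` per row.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("age", "error", "units", "method", "techno_complex") if c not in df.columns]
    if missing:
        raise ValueError(f"date table missing required columns: {missing}")
    return normalize_units(df)


def normalize_units(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    bad = ~df["units"].isin(["yr", "ka"])
    if bad.any():
        raise ValueError(f"unknown units in rows {list(df.index[bad])}")
    in_yr = df["units"] == "yr"
    df.loc[in_yr, "age"] = df.loc[in_yr, "age"] / 1000.0
    df.loc[in_yr, "error"] = df.loc[in_yr, "error"] / 1000.0
    df["units"] = "ka"
    if (df["error"] <= 0).any() or (df["age"] <= 0).any():
        raise ValueError("ages and errors must be positive")
    return df


def write_dates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.fillna(False).astype(bool)


def filter_dates(
    dates: pd.DataFrame,
    criteria: str = "fc1",
    attribution_toggles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Apply one filtering tier and the NAI/SAI attribution.

    Parameters
    ----------
    dates : DataFrame
        Date table with ages already in ka BP (see :func:`read_dates`).
    criteria : {'fc1', 'fc2'}
    attribution_toggles : mapping, optional
        Overrides of the default techno-complex -> class mapping, e.g.
        ``{"Uluzzian": "NAI"}`` or ``{"Chatelperronian": "excluded"}``.
        The fossil-free techno-complexes (Szeletian, Bohunician, LRJ)
        cannot be re-included.

    Returns
    -------
    DataFrame with a ``species_class`` column in {'NAI', 'SAI', 'excluded'};
    rows failing the quality bar are dropped, rows with an excluded or
    unknown techno-complex are kept but classed 'excluded'.
    """
    criteria = criteria.lower()
    if criteria not in ("fc1", "fc2"):
        raise ValueError("criteria must be 'fc1' or 'fc2'")
    df = dates.copy()
    if "units" in df.columns and (df["units"] == "yr").any():
        df = normalize_units(df)

    unknown_methods = set(df["method"]) - VALID_METHODS
    if unknown_methods:
        raise ValueError(f"unknown dating methods: {sorted(unknown_methods)}")

    keep = df["method"] != "radiocarbon-conventional"
    for flag in ("contamination", "low_collagen", "burnt_bone"):
        if flag in df.columns:
            keep &= ~_as_bool(df[flag])
    keep &= (df["error"] / df["age"]) < MAX_RELATIVE_ERROR
    if criteria == "fc2":
        if "anthropic" not in df.columns:
            raise ValueError("FC2 filtering needs an 'anthropic' column")
        keep &= _as_bool(df["anthropic"])
    df = df.loc[keep].copy()

    mapping = dict(DEFAULT_ATTRIBUTION)
    for tc, cls in (attribution_toggles or {}).items():
        if cls not in ("NAI", "SAI", "excluded"):
            raise ValueError(f"toggle for {tc!r} must be NAI, SAI or excluded")
        if tc in ALWAYS_EXCLUDED and cls != "excluded":
            raise ValueError(f"{tc} lacks diagnostic fossils and stays excluded")
        mapping[tc] = cls
    for tc in ALWAYS_EXCLUDED:
        mapping[tc] = "excluded"

    classes = []
    for tc in df["techno_complex"]:
        cls = mapping.get(tc)
        if cls is None:
            logger.warning("unknown techno-complex %r excluded from analysis", tc)
            cls = "excluded"
        classes.append(cls)
    df["species_class"] = classes
    df["criteria"] = criteria
    return df.reset_index(drop=True)
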