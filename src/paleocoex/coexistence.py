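"""Regional overlap between the NAI end and the SAI start, and group summaries.

Ages are ka BP (larger = older).  Two overlap measures are computed per
region: the *minimal* overlap — the youngest 95% bound of the SAI start
minus the oldest 95% bound of the NAI end, i.e. the overlap that holds even
under the least favourable reading of both credibility intervals — and the
*central* overlap, the difference of the posterior modes.  A region is
classed as a coexistence region when the minimal overlap is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BoundaryEstimate",
    "OverlapResult",
    "temporal_overlap",
    "GroupComparison",
    "group_percent_difference",
    "coefficient_of_variation",
]


@dataclass
class BoundaryEstimate:
    """Posterior mode with HPD envelopes for one phase boundary (ka BP)."""

    mode: float
    hpd68: tuple[float, float]  # (young, old)
    hpd95: tuple[float, float]

    @classmethod
    def from_phase(cls, est) -> "BoundaryEstimate":
        return cls(
            mode=est.mode,
            hpd68=(est.hpd68_young, est.hpd68_old),
            hpd95=(est.hpd95_young, est.hpd95_old),
        )

    def bound(self, which: str, level: int = 95) -> float:
        lo, hi = self.hpd95 if level == 95 else self.hpd68
        return lo if which == "young" else hi


@dataclass
class OverlapResult:
    region_id: str
    minimal_ka: float
    central_ka: float
    coexistence: bool
    level: int = 95


def temporal_overlap(
    nai_end: BoundaryEstimate | None,
    sai_start: BoundaryEstimate | None,
    region_id: str = "",
    level: int = 95,
) -> OverlapResult | None:
    """Minimal and central NAI/SAI overlap for one region.

    Overlap is positive when the SAI start is older than the NAI end.
    Returns None when the SAI phase is absent in the region (as happens
    under the stricter filtering tier in some regions).
    """
    if nai_end is None or sai_start is None:
        return None
    for name, est in (("NAI end", nai_end), ("SAI start", sai_start)):
        if est.hpd95 is None or any(not np.isfinite(b) for b in est.hpd95):
            raise ValueError(f"missing HPD bounds for {name} in region {region_id}")
    minimal = sai_start.bound("young", level) - nai_end.bound("old", level)
    central = sai_start.mode - nai_end.mode
    return OverlapResult(
        region_id=region_id,
        minimal_ka=float(minimal),
        central_ka=float(central),
        coexistence=bool(minimal > 0),
        level=level,
    )


@dataclass
class GroupComparison:
    metric: str
    mean_coexistence: float
    mean_no_coexistence: float
    percent_difference: float  # 100 * (1 - mean_no / mean_co)

    @property
    def percent_difference_rounded(self) -> int:
        return int(round(self.percent_difference))


def group_percent_difference(
    values: pd.Series,
    no_coexistence_ids,
    metric: str = "",
) -> GroupComparison:
    """How much lower a metric is in no-coexistence regions, on average.

    ``values`` is indexed by region id; ``no_coexistence_ids`` names the
    regions without NAI/SAI temporal overlap.  Group means are unweighted.
    """
    nc = list(no_coexistence_ids)
    missing = [r for r in nc if r not in values.index]
    if missing:
        raise ValueError(f"metric missing for regions {missing}")
    if values.isna().any():
        bad = list(values.index[values.isna()])
        raise ValueError(f"metric missing for regions {bad}")
    co = values.drop(nc)
    if co.empty or not nc:
        raise ValueError("both groups must be non-empty")
    mean_co = float(co.mean())
    mean_nc = float(values.loc[nc].mean())
    if mean_co <= 0:
        raise ValueError("percent difference undefined for non-positive denominator")
    return GroupComparison(
        metric=metric,
        mean_coexistence=mean_co,
        mean_no_coexistence=mean_nc,
        percent_difference=100.0 * (1.0 - mean_nc / mean_co),
    )


def coefficient_of_variation(values) -> float:
    """100 * sample SD / mean; the mean must be positive."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least two values")
    m = x.mean()
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * x.std(ddof=1) / m)
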