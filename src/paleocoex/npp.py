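"""Net-primary-productivity time series container.

NPP trajectories over MIS3 are the common currency of the package: the
biogeographic clustering compares them, the carrying-capacity model consumes
them, and the synthetic-data generator produces them.  A series is a regular
grid of calendar ages (ka BP, oldest first) with one NPP value (kg/m^2/yr)
per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NPPSeries", "read_npp_table", "write_npp_table"]


@dataclass
class NPPSeries:
    """One site's or region's NPP trajectory on a regular time grid.

    Parameters
    ----------
    id : str
        Site or region identifier.
    times_ka : array of float
        Calendar ages in ka BP, strictly decreasing or increasing with a
        constant step (stored oldest-first).
    values : array of float
        NPP in kg/m^2/yr, non-negative, no missing values.
    """

    id: str
    times_ka: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.times_ka = np.asarray(self.times_ka, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_ka.ndim != 1 or self.times_ka.shape != self.values.shape:
            raise ValueError("times_ka and values must be 1-D and equal length")
        if self.times_ka.size < 2:
            raise ValueError("an NPP series needs at least two time steps")
        steps = np.diff(self.times_ka)
        if not (np.all(steps > 0) or np.all(steps < 0)):
            raise ValueError("time grid must be strictly monotonic")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be regular")
        # store oldest (largest ka BP) first
        if steps[0] > 0:
            self.times_ka = self.times_ka[::-1].copy()
            self.values = self.values[::-1].copy()
        if np.any(~np.isfinite(self.values)):
            raise ValueError("NPP values contain missing entries")
        if np.any(self.values < 0):
            raise ValueError("NPP values must be non-negative")

    @property
    def step_ka(self) -> float:
        return abs(float(self.times_ka[1] - self.times_ka[0]))

    def mean(self) -> float:
        return float(np.mean(self.values))

    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    def cv_percent(self) -> float:
        """Coefficient of variation, 100 * sample SD / mean."""
        m = self.mean()
        if m <= 0:
            raise ValueError("CV undefined for non-positive mean NPP")
        return 100.0 * self.sd() / m

    def window(self, old_ka: float, young_ka: float) -> "NPPSeries":
        """Restrict the series to [young_ka, old_ka] (inclusive)."""
        keep = (self.times_ka <= old_ka) & (self.times_ka >= young_ka)
        if keep.sum() < 2:
            raise ValueError("window leaves fewer than two time steps")
        return NPPSeries(self.id, self.times_ka[keep], self.values[keep])


def read_npp_table(path) -> dict[str, NPPSeries]:
    """Read a wide-form NPP table: first column ``time_ka``, one column per id."""
    df = pd.read_csv(path)
    if "time_ka" not in df.columns:
        raise ValueError("NPP table must have a 'time_ka' column")
    t = df["time_ka"].to_numpy(float)
    return {
        c: NPPSeries(c, t, df[c].to_numpy(float))
        for c in df.columns
        if c != "time_ka"
    }


def write_npp_table(series: dict[str, NPPSeries], path) -> None:
    ids = sorted(series)
    t = series[ids[0]].times_ka
    out = pd.DataFrame({"time_ka": t})
    for sid in ids:
        s = series[sid]
        if not np.allclose(s.times_ka, t):
            raise ValueError("all series must share one time grid")
        out[sid] = s.values
    out.to_csv(path, index=False)
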