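"""Radiocarbon calibration against an IntCal-dialect curve.

A calibration curve maps calendar age theta (cal BP) to a conventional
radiocarbon age mu(theta) with a curve error sigma(theta).  Calibrating a
measurement m +/- s places, on a regular calendar grid, the normalized density

    p(theta) ~ Normal(m - DeltaR; mu(theta), sqrt(s^2 + sigma(theta)^2 + sR^2))

where DeltaR is the marine reservoir offset (0 for terrestrial samples and,
following the study conventions for MIS3 marine shell, 0 for marine samples
too) and sR its error.  Luminescence and U-series ages bypass the curve and
enter as normal densities on the calendar axis directly.

All public ages are in ka cal BP (present = 1950, larger = older); curve
files keep the field's native yr BP dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationCurve",
    "CalibratedDensity",
    "CalibrationError",
    "calibrate",
    "combine_same_sample",
    "RADIOCARBON_METHODS",
    "NON_RADIOCARBON_METHODS",
]

RADIOCARBON_METHODS = frozenset(
    {
        "radiocarbon-AMS-ultrafiltration",
        "radiocarbon-AMS",
        "radiocarbon-ABOx",
        "radiocarbon-conventional",
    }
)
NON_RADIOCARBON_METHODS = frozenset({"OSL", "TL", "U-Th"})
VALID_METHODS = RADIOCARBON_METHODS | NON_RADIOCARBON_METHODS


class CalibrationError(ValueError):
    """Raised when a measurement cannot be calibrated against a curve."""


@dataclass
class CalibrationCurve:
    """Calibration curve knots in yr BP, sorted by calendar age.

    ``cal_bp``, ``c14_age`` and ``error`` are parallel arrays in years;
    ``delta_r``/``delta_r_error`` hold the marine reservoir offset in years.
    """

    cal_bp: np.ndarray = field(repr=False)
    c14_age: np.ndarray = field(repr=False)
    error: np.ndarray = field(repr=False)
    name: str = "curve"
    delta_r: float = 0.0
    delta_r_error: float = 0.0
    marine: bool = False

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_age = np.asarray(self.c14_age, dtype=float)
        self.error = np.asarray(self.error, dtype=float)
        order = np.argsort(self.cal_bp)
        self.cal_bp = self.cal_bp[order]
        self.c14_age = self.c14_age[order]
        self.error = self.error[order]
        if np.any(np.diff(self.cal_bp) <= 0):
            raise ValueError("calibration curve has duplicate calendar knots")
        if np.any(self.error <= 0):
            raise ValueError("curve errors must be positive")

    @property
    def support_ka(self) -> tuple[float, float]:
        """(young, old) calendar support in ka BP."""
        return float(self.cal_bp[0] / 1000.0), float(self.cal_bp[-1] / 1000.0)

    def mu(self, cal_bp: np.ndarray) -> np.ndarray:
        """Radiocarbon age (yr BP) at calendar age(s) in yr BP."""
        return np.interp(cal_bp, self.cal_bp, self.c14_age)

    def sigma(self, cal_bp: np.ndarray) -> np.ndarray:
        return np.interp(cal_bp, self.cal_bp, self.error)

    @classmethod
    def from_file(cls, path, name: str | None = None, **kw) -> "CalibrationCurve":
        """Read an IntCal-dialect text file.

        Comment lines start with ``#`` (or any non-numeric token); data lines
        carry at least three comma- or whitespace-separated columns:
        cal BP, 14C age (yr BP), curve error (yr).
        """
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "%", "//")):
                    continue
                parts = line.replace(",", " ").split()
                try:
                    vals = [float(p) for p in parts[:3]]
                except ValueError:
                    continue
                if len(vals) == 3:
                    rows.append(vals)
        if not rows:
            raise ValueError(f"no curve knots found in {path}")
        arr = np.asarray(rows)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], name=name or str(path), **kw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.name}\n# cal BP, 14C age (BP), error (yr)\n")
            for c, m, e in zip(self.cal_bp[::-1], self.c14_age[::-1], self.error[::-1]):
                fh.write(f"{c:.1f},{m:.1f},{e:.1f}\n")


@dataclass
class CalibratedDensity:
    """Probability mass on a regular calendar grid (ka BP, ascending)."""

    grid_ka: np.ndarray = field(repr=False)
    mass: np.ndarray = field(repr=False)
    label: str = ""

    def __post_init__(self) -> None:
        self.grid_ka = np.asarray(self.grid_ka, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if np.any(self.mass < 0):
            raise ValueError("probability masses must be non-negative")
        tot = self.mass.sum()
        if tot <= 0:
            raise ValueError("density has zero total mass")
        if abs(tot - 1.0) > 1e-9:
            self.mass = self.mass / tot

    @property
    def step_ka(self) -> float:
        return float(self.grid_ka[1] - self.grid_ka[0])

    def mode(self) -> float:
        return float(self.grid_ka[int(np.argmax(self.mass))])

    def mean(self) -> float:
        return float(np.sum(self.grid_ka * self.mass))

    def sd(self) -> float:
        m = self.mean()
        return float(np.sqrt(np.sum((self.grid_ka - m) ** 2 * self.mass)))

    def hpd(self, level: float = 0.95) -> list[tuple[float, float]]:
        """Highest-density set as a list of (young, old) intervals in ka BP."""
        order = np.argsort(self.mass)[::-1]
        csum = np.cumsum(self.mass[order])
        n_in = int(np.searchsorted(csum, level)) + 1
        inside = np.zeros(self.mass.size, dtype=bool)
        inside[order[:n_in]] = True
        intervals = []
        i = 0
        while i < inside.size:
            if inside[i]:
                j = i
                while j + 1 < inside.size and inside[j + 1]:
                    j += 1
                intervals.append((float(self.grid_ka[i]), float(self.grid_ka[j])))
                i = j + 1
            else:
                i += 1
        return intervals

    def mass_between(self, young_ka: float, old_ka: float) -> float:
        sel = (self.grid_ka >= young_ka) & (self.grid_ka < old_ka)
        return float(self.mass[sel].sum())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ages from the density (grid sampling with within-cell jitter)."""
        idx = rng.choice(self.mass.size, size=n, p=self.mass)
        jitter = rng.uniform(-0.5, 0.5, size=n) * self.step_ka
        return self.grid_ka[idx] + jitter


def _normal_density(age_ka: float, error_ka: float, grid_step_ka: float,
                    label: str) -> CalibratedDensity:
    lo = age_ka - 5 * error_ka
    hi = age_ka + 5 * error_ka
    grid = np.arange(lo, hi + grid_step_ka / 2, grid_step_ka)
    mass = np.exp(-0.5 * ((grid - age_ka) / error_ka) ** 2)
    return CalibratedDensity(grid, mass / mass.sum(), label=label)


def calibrate(
    age: float,
    error: float,
    curve: CalibrationCurve | None = None,
    method: str = "radiocarbon-AMS-ultrafiltration",
    grid_step_ka: float = 0.005,
    units: str = "yr",
    label: str = "",
) -> CalibratedDensity:
    """Calibrate one chronometric measurement onto the calendar axis.

    Parameters
    ----------
    age, error : float
        Measurement and its 1-sigma error, in ``units`` ('yr' or 'ka') BP.
        For radiocarbon methods this is the conventional radiocarbon age;
        for OSL/TL/U-Th it is already a calendar age.
    curve : CalibrationCurve
        Required for radiocarbon methods.
    grid_step_ka : float
        Calendar grid step; default 0.005 ka (5 yr).
    """
    if method not in VALID_METHODS:
        raise ValueError(f"unknown dating method {method!r}")
    if units == "yr":
        age, error = age / 1000.0, error / 1000.0
    elif units != "ka":
        raise ValueError("units must be 'yr' or 'ka'")
    if error <= 0:
        raise ValueError("error must be positive")

    if method in NON_RADIOCARBON_METHODS:
        return _normal_density(age, error, grid_step_ka, label)

    if curve is None:
        raise ValueError("radiocarbon calibration requires a curve")
    m_yr = age * 1000.0 - curve.delta_r
    s_yr = np.hypot(error * 1000.0, curve.delta_r_error)
    young, old = curve.support_ka
    grid = np.arange(young, old + grid_step_ka / 2, grid_step_ka)
    mu = curve.mu(grid * 1000.0)
    tau = np.sqrt(s_yr**2 + curve.sigma(grid * 1000.0) ** 2)
    z = (m_yr - mu) / tau
    inside = np.abs(z) <= 5.0
    if not np.any(inside):
        raise CalibrationError(
            f"measurement {label or age} lies outside the support of curve "
            f"{curve.name} at 5 sigma"
        )
    grid = grid[inside]
    logd = -0.5 * z[inside] ** 2 - np.log(tau[inside])
    mass = np.exp(logd - logd.max())
    return CalibratedDensity(grid, mass / mass.sum(), label=label)


def combine_same_sample(ages, errors, methods=None):
    """Pool repeat radiocarbon measurements on one physical sample.

    Inverse-variance weighted mean with pooled error, plus a chi-square
    consistency statistic (the classic R_Combine test).

    Returns
    -------
    dict with keys ``mean``, ``error``, ``chi2``, ``df``, ``p_value``,
    ``consistent`` (True when the 5% chi-square test does not reject).
    """
    ages = np.asarray(ages, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if ages.size < 2:
        raise ValueError("need at least two measurements to combine")
    if np.any(errors <= 0):
        raise ValueError("errors must be positive")
    if methods is not None:
        methods = set(methods)
        if not methods <= RADIOCARBON_METHODS:
            raise ValueError(
                "same-sample combination is defined for radiocarbon "
                f"measurements only, got {sorted(methods)}"
            )
        if len(methods) > 1:
            raise ValueError(
                f"mixed methods on one sample cannot be pooled: {sorted(methods)}"
            )
    w = 1.0 / errors**2
    mean = float(np.sum(w * ages) / np.sum(w))
    err = float(np.sqrt(1.0 / np.sum(w)))
    chi2 = float(np.sum(w * (ages - mean) ** 2))
    df = ages.size - 1
    from scipy.stats import chi2 as chi2_dist

    p = float(chi2_dist.sf(chi2, df))
    return {
        "mean": mean,
        "error": err,
        "chi2": chi2,
        "df": df,
        "p_value": p,
        "consistent": p >= 0.05,
    }
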