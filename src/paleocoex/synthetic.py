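"""Synthetic world generator: ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes,
without any climate- or vegetation-model emulation: regions scattered over
a Europe-sized lat/lon box; per-region NPP trajectories built from a
square-wave stadial/interstadial signal with jittered change-points plus
autocorrelated noise; regional herbivore guilds drawn from a master pool
with a realistic body-mass spectrum; per-site occupation intervals for the
NAI and SAI techno-complexes whose true regional overlap is *constructed*
to be linear in the region's true medium-size carrying capacity (slope
``overlap_effect``) plus spatially autocorrelated noise — the very effect
the downstream correlation tests try to recover; and noisy chronometric
measurements pushed through a toy calibration curve.

Every generated date keeps its true age in a hidden ``_true_age_ka``
column so recovery tests can score the estimators without leaking truth
into the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .carrying_capacity import CCParams, HerbivoreSpecies, PCOM, estimate_cc
from .chronology.calibration import CalibrationCurve
from .chronology.kde import haversine_km
from .npp import NPPSeries

__all__ = [
    "WorldConfig",
    "TrueHistory",
    "WorldData",
    "generate_toy_calibration_curve",
    "generate_npp_series",
    "generate_fauna",
    "generate_chronometric_dates",
    "generate_world",
    "default_species_pool",
]


@dataclass
class WorldConfig:
    """Study conditions for one synthetic world.

    Defaults mirror the real study's scale: 16 regions, ~20 sites per
    region, a 55-30 ka BP window, stadial cycles of ~1.5 ka
    (Dansgaard-Oeschger pacing), NPP around 0.28 +/- 0.08 kg/m^2/yr, and a
    positive overlap_effect of 0.02 ka of NAI/SAI overlap per kg/km^2/yr
    of medium-size herbivore CC (the sign and rough magnitude of the
    association the analysis is designed to detect).
    """

    n_regions: int = 16
    sites_per_region: int = 20
    window: tuple[float, float] = (55.0, 30.0)   # (old, young) ka BP
    stadial_cycle_ka: float = 1.5
    npp_base: float = 0.28                        # kg/m^2/yr
    npp_amplitude: float = 0.08
    noise_sd: float = 0.02
    overlap_effect: float = 0.02                  # ka per (kg/km^2/yr)
    overlap_noise_sd_ka: float = 0.75
    spatial_noise_range_km: float = 500.0
    mean_lab_error_ka: float = 0.35
    detection_prob: float = 0.35
    levels_per_region: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        old, young = self.window
        if old <= young:
            raise ValueError("window must satisfy old_ka > young_ka")
        if min(self.n_regions, self.sites_per_region) < 1:
            raise ValueError("counts must be at least 1")
        for name in ("npp_amplitude", "noise_sd", "overlap_noise_sd_ka",
                     "spatial_noise_range_km", "stadial_cycle_ka"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TrueHistory:
    """Per-region truth: NAI end, SAI start (ka BP) and their overlap."""

    table: pd.DataFrame = field(repr=False)  # region, nai_end, sai_start, overlap, cc_medium

    def __post_init__(self) -> None:
        t = self.table
        if not np.allclose(
            t["true_overlap_ka"], t["sai_start_ka"] - t["nai_end_ka"],
            atol=1e-9, equal_nan=True,
        ):
            raise ValueError("overlap must equal SAI start - NAI end")


@dataclass
class WorldData:
    config: WorldConfig
    history: TrueHistory
    regions: pd.DataFrame
    sites: pd.DataFrame
    npp: dict[str, NPPSeries]
    site_npp: dict[str, NPPSeries]
    occupations: pd.DataFrame
    dates: pd.DataFrame
    fauna: dict[str, pd.DataFrame]
    species_pool: pd.DataFrame
    modern_densities: pd.DataFrame
    curve: CalibrationCurve

    def write(self, outdir) -> None:
        """Write the tabular dialects the pipeline reads, plus a manifest."""
        from pathlib import Path

        from .npp import write_npp_table

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.dates.to_csv(out / "dates.csv", index=False)
        write_npp_table(self.npp, out / "npp_regions.csv")
        self.sites.to_csv(out / "sites.csv")
        self.species_pool.to_csv(out / "species_pool.csv", index=False)
        self.modern_densities.to_csv(out / "modern_densities.csv", index=False)
        for rid, inc in self.fauna.items():
            inc.to_csv(out / f"fauna_{rid}.csv")
        self.curve.to_file(out / "toy_curve.csv")
        manifest = {"config": asdict(self.config), "seed": self.config.seed}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def generate_toy_calibration_curve(
    window: tuple[float, float] = (60.0, 0.0),
    wiggle_amplitude: float = 300.0,
    seed: int = 0,
) -> CalibrationCurve:
    """Strictly monotonic stand-in calibration curve over ``window`` (ka BP).

    The radiocarbon age is the calendar age plus smooth sinusoidal wiggles
    of the given amplitude (yr); wiggle periods are kept >= 8x the
    amplitude so the slope stays positive.  ``wiggle_amplitude = 0`` gives
    the identity line with a constant error.
    """
    old, young = max(window), min(window)
    if young < 0 or old > 60 or old <= young:
        raise ValueError("window must lie within 0-60 ka BP with old > young")
    rng = np.random.default_rng(seed)
    cal = np.arange(young * 1000.0, old * 1000.0 + 5.0, 5.0)
    if wiggle_amplitude > 0:
        period = max(4000.0, 8.0 * wiggle_amplitude)
        phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
        wiggle = wiggle_amplitude * (
            0.7 * np.sin(2 * np.pi * cal / period + phase1)
            + 0.3 * np.sin(2 * np.pi * cal / (2.7 * period) + phase2)
        )
    else:
        wiggle = np.zeros_like(cal)
    c14 = cal + wiggle
    if np.any(np.diff(c14) <= 0):  # guaranteed by the period bound, but verify
        raise RuntimeError("toy curve lost monotonicity")
    err = np.full_like(cal, max(20.0, wiggle_amplitude / 5.0))
    return CalibrationCurve(cal, c14, err, name=f"toy-curve-seed{seed}")


def _stadial_phase(times_ka: np.ndarray, cycle_ka: float, rng) -> np.ndarray:
    """0/1 interstadial indicator: square wave with jittered change-points."""
    old, young = times_ka.max(), times_ka.min()
    if cycle_ka <= 0:
        return np.ones_like(times_ka)
    edges = [old]
    t = old
    while t > young:
        t -= cycle_ka * rng.uniform(0.6, 1.4)
        edges.append(max(t, young))
    phase = np.zeros_like(times_ka)
    state = rng.integers(0, 2)
    for a, b in zip(edges[:-1], edges[1:]):
        phase[(times_ka <= a) & (times_ka >= b)] = state
        state = 1 - state
    return phase


def generate_npp_series(
    config: WorldConfig, region_id: str, rng: np.random.Generator | None = None,
    step_ka: float = 0.1, base: float | None = None,
) -> NPPSeries:
    """One region's NPP trajectory: square-wave stadial signal + AR(1) noise."""
    if rng is None:
        import zlib

        rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, zlib.crc32(region_id.encode())))
        )
    old, young = config.window
    times = np.arange(old, young - step_ka / 2, -step_ka)
    phase = _stadial_phase(times, config.stadial_cycle_ka, rng)
    base = config.npp_base if base is None else base
    signal = base + config.npp_amplitude * (phase - 0.5)
    noise = np.zeros_like(times)
    rho = 0.8
    innov_sd = config.noise_sd * np.sqrt(1 - rho**2)
    e = rng.normal(0, 1, size=times.size)
    for i in range(1, times.size):
        noise[i] = rho * noise[i - 1] + innov_sd * e[i]
    noise[0] = config.noise_sd * e[0]
    return NPPSeries(region_id, times, np.clip(signal + noise, 0.0, None))


DEFAULT_POOL_MASSES = {
    # body masses (kg, two-sex means) spanning the three size classes
    "lagomorph_sm": 2.0, "marmot_sm": 5.5, "beaver_sm": 18.0, "roe_deer_sm": 19.5,
    "chamois_md": 32.0, "saiga_md": 40.0, "ibex_md": 55.0, "fallow_deer_md": 60.0,
    "reindeer_md": 90.0, "boar_md": 95.0, "red_deer_md": 160.0, "horse_md": 250.0,
    "hydruntine_md": 220.0, "musk_ox_md": 290.0,
    "steppe_bison_lg": 600.0, "aurochs_lg": 700.0, "giant_deer_lg": 450.0,
    "woolly_rhino_lg": 1900.0, "mammoth_lg": 3900.0, "elk_lg": 420.0,
}


def default_species_pool() -> pd.DataFrame:
    rows = [
        {"species": n, "mass_kg": m} for n, m in sorted(DEFAULT_POOL_MASSES.items())
    ]
    return pd.DataFrame(rows)


def generate_fauna(
    region_id: str,
    pool: pd.DataFrame,
    detection_prob: float,
    n_levels: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Presence/absence incidence table (levels x species) for one region."""
    if not 0 <= detection_prob <= 1:
        raise ValueError("detection_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if pool.empty:
        return pd.DataFrame(index=[f"{region_id}_L{i+1}" for i in range(n_levels)])
    inc = rng.random((n_levels, len(pool))) < detection_prob
    return pd.DataFrame(
        inc.astype(int),
        index=[f"{region_id}_L{i+1}" for i in range(n_levels)],
        columns=list(pool["species"]),
    )


def _spatial_noise(lats, lons, range_km, sd, rng) -> np.ndarray:
    """Gaussian noise with exponential-decay covariance over great-circle km."""
    n = lats.size
    if sd == 0 or n == 1:
        return np.zeros(n)
    d = haversine_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
    cov = sd**2 * np.exp(-d / max(range_km, 1e-6))
    cov += np.eye(n) * 1e-10
    chol = np.linalg.cholesky(cov)
    return chol @ rng.normal(size=n)


def generate_chronometric_dates(
    occupations: pd.DataFrame,
    curve: CalibrationCurve,
    mean_lab_error_ka: float = 0.35,
    dates_per_interval: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample noisy chronometric dates from true occupation intervals.

    ``occupations`` needs columns site, latitude, longitude, region,
    techno_complex, start_ka (old), end_ka (young).  Each interval yields
    1 + Poisson(dates_per_interval - 1) dates with true ages uniform in
    the interval; radiocarbon measurements are the curve value at the true
    age plus lab noise.  A small share of records is made deliberately
    unreliable (conventional method, QC flags, inflated errors) to
    exercise the filtering stage.  The hidden ``_true_age_ka`` column
    carries the truth for recovery tests.
    """
    young_sup, old_sup = curve.support_ka
    bad = (occupations["start_ka"] > old_sup) | (occupations["end_ka"] < young_sup)
    if bad.any():
        raise ValueError(
            f"occupation intervals outside curve support: rows {list(occupations.index[bad])}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for _, occ in occupations.iterrows():
        n = 1 + rng.poisson(max(dates_per_interval - 1.0, 0.0))
        for i in range(n):
            true_ka = rng.uniform(occ["end_ka"], occ["start_ka"])
            u = rng.random()
            if u < 0.80:
                method = "radiocarbon-AMS-ultrafiltration"
            elif u < 0.87:
                method = "radiocarbon-ABOx"
            elif u < 0.92:
                method = "radiocarbon-conventional"
            else:
                method = rng.choice(["OSL", "TL"])
            if mean_lab_error_ka > 0:
                err_ka = rng.lognormal(np.log(mean_lab_error_ka), 0.3)
                if rng.random() < 0.03:
                    err_ka *= 8.0  # occasional imprecise date, caught by the CV filter
            else:
                err_ka = 0.0
            if method.startswith("radiocarbon"):
                meas_ka = (
                    curve.mu(true_ka * 1000.0)
                    + (rng.normal(0.0, err_ka * 1000.0) if err_ka > 0 else 0.0)
                ) / 1000.0
            else:
                meas_ka = true_ka + (rng.normal(0.0, err_ka) if err_ka > 0 else 0.0)
                err_ka *= 1.8  # luminescence errors run larger
            rows.append(
                {
                    "site": occ["site"],
                    "latitude": occ["latitude"],
                    "longitude": occ["longitude"],
                    "region": occ["region"],
                    "level": f"{occ['site']}_{occ['techno_complex'][:3]}{i+1}",
                    "techno_complex": occ["techno_complex"],
                    "method": method,
                    "material": "bone" if rng.random() < 0.7 else "charcoal",
                    "anthropic": bool(rng.random() < 0.65),
                    "marine": False,
                    "age": max(meas_ka, 0.1),
                    "error": max(err_ka, 0.02),
                    "units": "ka",
                    "contamination": bool(rng.random() < 0.04),
                    "low_collagen": bool(rng.random() < 0.04),
                    "burnt_bone": bool(rng.random() < 0.02),
                    "same_sample": "",
                    "_true_age_ka": true_ka,
                }
            )
    return pd.DataFrame(rows)


def generate_world(config: WorldConfig) -> WorldData:
    """Build a complete synthetic world with known ground truth.

    The true NAI/SAI overlap of each region is linear in its true
    medium-size CC (slope ``config.overlap_effect``) plus spatially
    autocorrelated noise, so the downstream regression stage has a planted
    effect to recover (or, with ``overlap_effect = 0``, a null).
    """
    rng = np.random.default_rng(config.seed)
    old, young = config.window
    n = config.n_regions

    # region centroids on a jittered Europe-like lattice
    ncol = int(np.ceil(np.sqrt(n * 2)))
    lons = np.linspace(-9.0, 28.0, ncol)
    lats = np.linspace(37.0, 53.0, int(np.ceil(n / ncol)))
    grid = [(la, lo) for la in lats for lo in lons][:n]
    reg_lat = np.array([g[0] for g in grid]) + rng.uniform(-1, 1, n)
    reg_lon = np.array([g[1] for g in grid]) + rng.uniform(-1.5, 1.5, n)
    region_ids = [f"SR_{i+1}" for i in range(n)]
    regions = pd.DataFrame(
        {"region": region_ids, "latitude": reg_lat, "longitude": reg_lon}
    ).set_index("region")

    # NPP: regional base values vary smoothly in space
    base_shift = _spatial_noise(reg_lat, reg_lon, config.spatial_noise_range_km,
                                0.25 * config.npp_base, rng)
    npp = {}
    site_npp = {}
    for i, rid in enumerate(region_ids):
        base = max(config.npp_base + base_shift[i], 0.05)
        npp[rid] = generate_npp_series(config, rid, rng=rng, base=base)

    # guilds: regional subsets of the master pool
    pool = default_species_pool()
    fauna = {}
    pcoms = {}
    for rid in region_ids:
        k = rng.integers(int(0.6 * len(pool)), len(pool) + 1)
        members = pool.sample(n=int(k), random_state=int(rng.integers(2**31)))
        fauna[rid] = generate_fauna(
            rid, members, config.detection_prob, config.levels_per_region,
            seed=int(rng.integers(2**31)),
        )
        pcoms[rid] = PCOM(
            region_id=rid,
            species=[HerbivoreSpecies(r.species, r.mass_kg) for r in members.itertuples()],
            n_levels=config.levels_per_region,
        )

    # true medium-size CC drives the true overlap
    cc_params = CCParams(n_draws=1)
    cc_medium = np.array(
        [estimate_cc(npp[rid], pcoms[rid], cc_params).class_mean("medium") for rid in region_ids]
    )
    eta = _spatial_noise(reg_lat, reg_lon, config.spatial_noise_range_km,
                         config.overlap_noise_sd_ka, rng)
    overlap = (
        1.5
        + config.overlap_effect * (cc_medium - cc_medium.mean())
        + eta
    )
    nai_end = rng.uniform(young + 7.0, young + 11.0, size=n)
    sai_start = nai_end + overlap
    sai_start = np.clip(sai_start, young + 1.0, old - 1.0)
    overlap = sai_start - nai_end
    history = TrueHistory(
        pd.DataFrame(
            {
                "region": region_ids,
                "nai_end_ka": nai_end,
                "sai_start_ka": sai_start,
                "true_overlap_ka": overlap,
                "true_cc_medium": cc_medium,
            }
        ).set_index("region")
    )

    # sites and occupation intervals
    site_rows, occ_rows = [], []
    for i, rid in enumerate(region_ids):
        for s in range(config.sites_per_region):
            sid = f"{rid}_S{s+1}"
            slat = np.clip(reg_lat[i] + rng.normal(0, 0.6), 34.2, 54.8)
            slon = np.clip(reg_lon[i] + rng.normal(0, 0.8), -10.8, 29.8)
            site_rows.append(
                {"site": sid, "region": rid, "latitude": slat, "longitude": slon}
            )
            site_npp[sid] = NPPSeries(
                sid,
                npp[rid].times_ka,
                np.clip(npp[rid].values + rng.normal(0, 0.3 * config.noise_sd + 1e-4, npp[rid].values.size), 0, None),
            )
            u = rng.random()
            has_nai = u < 0.75
            has_sai = u > 0.35
            if has_nai:
                # the first site in each region ends exactly at the true NAI end,
                # so the youngest NAI evidence coincides with the extinction
                end = nai_end[i] if s == 0 else nai_end[i] + rng.exponential(1.2)
                end = min(end, old - 0.5)
                start = min(end + rng.uniform(2.0, 6.0), old)
                occ_rows.append(
                    {"site": sid, "region": rid, "latitude": slat, "longitude": slon,
                     "techno_complex": "Mousterian", "start_ka": start, "end_ka": end}
                )
            if has_sai:
                start = sai_start[i] if s == config.sites_per_region - 1 else max(
                    sai_start[i] - rng.exponential(1.2), young + 0.5
                )
                start = max(start, young + 0.5)
                end = max(start - rng.uniform(2.0, 6.0), young)
                occ_rows.append(
                    {"site": sid, "region": rid, "latitude": slat, "longitude": slon,
                     "techno_complex": "Aurignacian", "start_ka": start, "end_ka": end}
                )
    sites = pd.DataFrame(site_rows).set_index("site")
    occupations = pd.DataFrame(occ_rows)

    curve = generate_toy_calibration_curve(
        window=(min(60.0, old + 3.0), max(0.0, young - 3.0)),
        wiggle_amplitude=300.0,
        seed=int(rng.integers(2**31)),
    )
    dates = generate_chronometric_dates(
        occupations,
        curve,
        mean_lab_error_ka=config.mean_lab_error_ka,
        seed=int(rng.integers(2**31)),
    )

    # modern densities for CC validation: allometry + lognormal noise
    parks = []
    for p in range(30):
        members = pool.sample(n=10, random_state=int(rng.integers(2**31)))
        for r in members.itertuples():
            parks.append(
                {
                    "park": f"park_{p+1}",
                    "species": r.species,
                    "mass_kg": r.mass_kg,
                    "density": cc_params.a * r.mass_kg**cc_params.b
                    * rng.lognormal(0.0, 0.5),
                }
            )
    modern = pd.DataFrame(parks)

    return WorldData(
        config=config,
        history=history,
        regions=regions,
        sites=sites,
        npp=npp,
        site_npp=site_npp,
        occupations=occupations,
        dates=dates,
        fauna=fauna,
        species_pool=pool,
        modern_densities=modern,
        curve=curve,
    )
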