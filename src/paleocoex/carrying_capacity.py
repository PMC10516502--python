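"""Macroecological herbivore carrying-capacity model.

The model converts a region's net primary productivity into the sustainable
standing biomass of each herbivore species in its guild (kg/km^2/yr):

* total supportable herbivore biomass per time step is a transfer fraction
  ``f`` of NPP (converted to kg/km^2/yr), optionally with a scaling
  exponent ``beta``:  B_tot(t) = f * (NPP(t) * 1e6)^beta;
* the guild partitions B_tot in proportion to each species' allometric
  expected biomass density, a Damuth-style power law: individual density
  a * M^b (ind/km^2) times body mass M gives a biomass share proportional
  to M^(b+1) — heavier species hold a larger share of standing biomass
  even though their numeric density is lower;
* a species' carrying capacity is its share averaged over the analysis
  window, and size-class CC is the exact sum over member species.

Parameter uncertainty (a, b, f) is propagated by Monte-Carlo draws over
their 95% CIs; the central estimate is computed at the central parameters
so that degenerate cases have closed forms.

The default parameters are this package's own documented calibration
(Damuth-style a = 91.2 ind/km^2, b = -0.73; f set so a reference NPP of
0.3 kg/m^2/yr supports ~800 kg/km^2/yr of herbivore biomass); they are
configuration, not values fitted to any published dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .npp import NPPSeries

__all__ = [
    "HerbivoreSpecies",
    "CCParams",
    "CCEstimate",
    "PCOM",
    "assign_size_class",
    "delta_bias_correct",
    "estimate_cc",
    "predicted_density",
    "validate_cc",
    "rarefy_richness",
    "NPP_KG_M2_TO_KG_KM2",
]

#: kg/m^2/yr -> kg/km^2/yr
NPP_KG_M2_TO_KG_KM2 = 1.0e6

SIZE_CLASS_BOUNDS = {"small": (1.0, 20.0), "medium": (20.0, 300.0), "large": (300.0, np.inf)}


def assign_size_class(mass_kg: float) -> str:
    """Small (< 20 kg), medium (20-300 kg inclusive), large (> 300 kg).

    Species below 1 kg are outside the analysis and rejected.
    """
    if mass_kg < 1.0:
        raise ValueError("species below 1 kg are excluded from the analysis")
    if mass_kg < 20.0:
        return "small"
    if mass_kg <= 300.0:
        return "medium"
    return "large"


@dataclass(frozen=True)
class HerbivoreSpecies:
    name: str
    mass_kg: float
    size_class: str = ""

    def __post_init__(self) -> None:
        cls = assign_size_class(self.mass_kg)
        if self.size_class and self.size_class != cls:
            raise ValueError(
                f"{self.name}: declared class {self.size_class!r} conflicts "
                f"with mass {self.mass_kg} kg ({cls})"
            )
        object.__setattr__(self, "size_class", cls)


@dataclass
class PCOM:
    """Paleocommunity: the species pool of one region over the window."""

    region_id: str
    species: list[HerbivoreSpecies]
    n_levels: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("a PCOM needs a non-empty species set for CC estimation")


@dataclass
class CCParams:
    """Allometric and trophic-transfer parameters with 95% CIs."""

    a: float = 91.2                 # ind/km^2 at M = 1 kg
    b: float = -0.73                # allometric exponent
    f: float = 0.0027               # NPP -> herbivore biomass transfer fraction
    beta: float = 1.0               # NPP scaling exponent
    a_ci: tuple[float, float] = (57.0, 146.0)
    b_ci: tuple[float, float] = (-0.85, -0.61)
    f_ci: tuple[float, float] = (0.0020, 0.0034)
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1:
            raise ValueError("transfer fraction f must be in (0, 1]")
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")


@dataclass
class CCEstimate:
    """Per-species and per-size-class CC (kg/km^2/yr) with 95% bounds."""

    region_id: str
    species: pd.DataFrame = field(repr=False)      # name, mass, class, mean, ll, ul
    size_classes: pd.DataFrame = field(repr=False)  # class, mean, ll, ul

    def class_mean(self, size_class: str) -> float:
        return float(self.size_classes.loc[size_class, "mean"])


def delta_bias_correct(past, sim_reference, obs_reference, kind: str = "additive"):
    """Delta-method bias correction of simulated paleoclimate values.

    additive (temperatures): past + (obs - sim);
    multiplicative (precipitation): past * obs / max(sim, eps), so a zero
    past value stays zero.
    """
    past = np.asarray(past, dtype=float)
    sim = np.asarray(sim_reference, dtype=float)
    obs = np.asarray(obs_reference, dtype=float)
    if kind == "additive":
        return past + (obs - sim)
    if kind == "multiplicative":
        if np.any(obs <= 0):
            raise ValueError("multiplicative correction needs positive observed reference")
        eps = 1e-6
        return past * obs / np.maximum(sim, eps)
    raise ValueError("kind must be 'additive' or 'multiplicative'")


def _species_cc_timeseries(npp_values, masses, a, b, f, beta):
    """Species x time CC matrix for one parameter set."""
    total = f * np.power(npp_values * NPP_KG_M2_TO_KG_KM2, beta)
    share = np.power(masses, b + 1.0)
    share = share / share.sum()
    return np.outer(share, total)


def estimate_cc(
    npp: NPPSeries,
    pcom: PCOM,
    params: CCParams | None = None,
    window: tuple[float, float] | None = None,
) -> CCEstimate:
    """Carrying capacity of every species in a paleocommunity.

    The central estimate uses the central parameters; the 95% CI comes from
    ``params.n_draws`` Monte-Carlo draws of (a, b, f) over their CIs
    (normal with sd = CI width / 3.92, truncated to the physical range).
    """
    params = params or CCParams()
    series = npp.window(*window) if window is not None else npp
    masses = np.array([sp.mass_kg for sp in pcom.species])
    names = [sp.name for sp in pcom.species]
    classes = [sp.size_class for sp in pcom.species]

    central = _species_cc_timeseries(
        series.values, masses, params.a, params.b, params.f, params.beta
    ).mean(axis=1)

    rng = np.random.default_rng(params.seed)
    draws = np.empty((params.n_draws, masses.size))
    sd_a = (params.a_ci[1] - params.a_ci[0]) / 3.92
    sd_b = (params.b_ci[1] - params.b_ci[0]) / 3.92
    sd_f = (params.f_ci[1] - params.f_ci[0]) / 3.92
    for d in range(params.n_draws):
        a = max(rng.normal(params.a, sd_a), 1e-6)
        b = min(rng.normal(params.b, sd_b), -1e-6)
        f = min(max(rng.normal(params.f, sd_f), 1e-9), 1.0)
        draws[d] = _species_cc_timeseries(
            series.values, masses, a, b, f, params.beta
        ).mean(axis=1)

    ll = np.percentile(draws, 2.5, axis=0)
    ul = np.percentile(draws, 97.5, axis=0)
    ll = np.minimum(ll, central)
    ul = np.maximum(ul, central)
    species_df = pd.DataFrame(
        {
            "name": names,
            "mass_kg": masses,
            "size_class": classes,
            "mean": central,
            "ll": ll,
            "ul": ul,
        }
    ).set_index("name")

    rows = []
    for cls in ("small", "medium", "large"):
        member = np.array([c == cls for c in classes])
        if not member.any():
            rows.append({"size_class": cls, "mean": 0.0, "ll": 0.0, "ul": 0.0})
            continue
        class_draws = draws[:, member].sum(axis=1)
        mean = float(central[member].sum())  # exact additivity over members
        c_ll = float(min(np.percentile(class_draws, 2.5), mean))
        c_ul = float(max(np.percentile(class_draws, 97.5), mean))
        rows.append({"size_class": cls, "mean": mean, "ll": c_ll, "ul": c_ul})
    class_df = pd.DataFrame(rows).set_index("size_class")
    return CCEstimate(region_id=pcom.region_id, species=species_df, size_classes=class_df)


def predicted_density(mass_kg, params: CCParams | None = None) -> np.ndarray:
    """Allometric individual density a * M^b (ind/km^2)."""
    params = params or CCParams()
    return params.a * np.power(np.asarray(mass_kg, dtype=float), params.b)


def validate_cc(predicted: pd.DataFrame, observed: pd.DataFrame) -> dict:
    """Correlate predicted vs observed densities per park and pooled.

    Both frames need columns ``park``, ``species`` and ``density``; parks
    with fewer than three matched species are skipped with a warning.

    Returns a dict with ``per_park`` (DataFrame: r, p, n), ``pooled_r``,
    ``pooled_p`` and ``fraction_significant`` (parks with p < 0.05).
    """
    import logging

    log = logging.getLogger(__name__)
    merged = predicted.merge(
        observed, on=["park", "species"], suffixes=("_pred", "_obs")
    )
    if merged.empty:
        raise ValueError("no matched park/species pairs between tables")
    rows = []
    for park, sub in merged.groupby("park"):
        if len(sub) < 3:
            log.warning("park %s skipped: fewer than 3 matched species", park)
            continue
        if sub["density_pred"].nunique() < 2 or sub["density_obs"].nunique() < 2:
            log.warning("park %s skipped: constant densities", park)
            continue
        r, p = stats.pearsonr(sub["density_pred"], sub["density_obs"])
        rows.append({"park": park, "r": r, "p": p, "n": len(sub)})
    per_park = pd.DataFrame(rows).set_index("park") if rows else pd.DataFrame()
    pooled_r, pooled_p = stats.pearsonr(merged["density_pred"], merged["density_obs"])
    frac = float((per_park["p"] < 0.05).mean()) if len(per_park) else float("nan")
    return {
        "per_park": per_park,
        "pooled_r": float(pooled_r),
        "pooled_p": float(pooled_p),
        "n_pairs": int(len(merged)),
        "fraction_significant": frac,
    }


def _incidence_richness_at(counts: np.ndarray, n_units: int, target: int) -> float:
    """Expected sample-based rarefaction/extrapolation richness.

    ``counts`` are per-species incidence frequencies out of ``n_units``
    sampling units.  Interpolation uses the classic hypergeometric form;
    extrapolation adds the Chao2-style estimate of undetected species.
    """
    counts = counts[counts > 0]
    s_obs = counts.size
    if s_obs == 0:
        return 0.0
    t = n_units
    if target <= t:
        # E[S(target)] = sum_sp 1 - C(t - Y, target) / C(t, target)
        from scipy.special import gammaln

        def log_choose(n, k):
            return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

        miss = np.zeros(s_obs)
        can = (t - counts) >= target
        if can.any():
            miss[can] = np.exp(
                log_choose(t - counts[can], target) - log_choose(t, target)
            )
        return float(np.sum(1.0 - miss))
    q1 = int(np.sum(counts == 1))
    q2 = int(np.sum(counts == 2))
    if q2 > 0:
        q0 = (t - 1) / t * q1 * q1 / (2.0 * q2)
    else:
        q0 = (t - 1) / t * q1 * (q1 - 1) / 2.0
    m = target - t
    if q0 <= 0 or q1 == 0:
        return float(s_obs)
    extra = q0 * (1.0 - (1.0 - q1 / (q1 + t * q0)) ** m)
    return float(s_obs + extra)


def rarefy_richness(
    incidence: pd.DataFrame,
    target_units: int = 100,
    n_bootstrap: int = 500,
    seed: int = 0,
) -> dict:
    """Observed and extrapolated species richness with a bootstrap 95% CI.

    ``incidence`` is a levels x species 0/1 table.  Bootstrap resamples
    levels with replacement (n = 500 by default).  The returned dict flags
    whether the observed richness lies inside the extrapolated CI — i.e.
    whether sampling another ``target_units`` levels would be expected to
    add materially more species.
    """
    inc = (incidence.to_numpy() > 0).astype(int)
    if inc.shape[0] < 1:
        raise ValueError("need at least one sampling unit (level)")
    t = inc.shape[0]
    counts = inc.sum(axis=0)
    s_obs = int(np.sum(counts > 0))
    est = _incidence_richness_at(counts, t, target_units)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        rows = rng.integers(0, t, size=t)
        boot[i] = _incidence_richness_at(inc[rows].sum(axis=0), t, target_units)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return {
        "observed_richness": s_obs,
        "extrapolated_richness": float(max(est, s_obs)),
        "ci": ci,
        "observed_within_ci": ci[0] <= s_obs <= ci[1],
        "n_units": t,
        "target_units": target_units,
    }
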