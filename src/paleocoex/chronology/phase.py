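"""Hierarchical Bayesian phase model for techno-complex boundaries.

A phase groups the dated events of one techno-complex in one region.  Each
event i has an unknown true age theta_i with a uniform prior over the study
window; its likelihood is the calibrated density of the measurement widened
by an event-level extra error under a half-normal shrinkage prior (scale
proportional to the event's own measurement spread).  The extra error
absorbs palimpsest scatter and unmodelled lab offsets and reproduces the
wider credibility intervals that event-level models yield compared with
phase-boundary priors that shrink toward the best-dated event.

Because one event corresponds to one date (same-sample repeats are pooled
beforehand), the theta_i are conditionally independent given the window, so
their marginal posteriors are computed exactly on the calibration grid (the
shrinkage prior is marginalized by quadrature) and the phase start/end
posteriors — the per-draw maximum/minimum of the member theta_i — are
summarized from iid Monte Carlo draws.  Draws are organized in seeded
chains and a split-chain R-hat diagnostic is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde, norm

from .calibration import CalibratedDensity

__all__ = ["BAMSettings", "PhaseEstimate", "PhaseFit", "fit_bam", "hpd_interval"]


@dataclass
class BAMSettings:
    """Sampler settings for the phase model.

    ``extra_error_scale`` is the shrinkage-prior scale expressed as a
    multiple of each event's posterior SD (0 disables the widening);
    ``n_quad`` is the number of quadrature nodes used to marginalize it.
    """

    n_chains: int = 3
    n_draws: int = 4000
    burn: int = 0
    seed: int = 0
    extra_error_scale: float = 1.0
    n_quad: int = 5
    rhat_threshold: float = 1.05


@dataclass
class PhaseEstimate:
    """Posterior summary for a phase boundary (ages in ka BP)."""

    kind: str  # 'start' | 'end'
    mode: float
    hpd68: list[tuple[float, float]]
    hpd95: list[tuple[float, float]]
    ess: int
    criteria: str = ""
    samples: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        lo95 = min(a for a, _ in self.hpd95)
        hi95 = max(b for _, b in self.hpd95)
        if not (lo95 - 1e-9 <= self.mode <= hi95 + 1e-9):
            raise ValueError("posterior mode must lie inside the HPD95 envelope")
        lo68 = min(a for a, _ in self.hpd68)
        hi68 = max(b for _, b in self.hpd68)
        if lo68 < lo95 - 1e-9 or hi68 > hi95 + 1e-9:
            raise ValueError("HPD68 must lie inside the HPD95 envelope")

    @property
    def hpd95_young(self) -> float:
        return min(a for a, _ in self.hpd95)

    @property
    def hpd95_old(self) -> float:
        return max(b for _, b in self.hpd95)

    @property
    def hpd68_young(self) -> float:
        return min(a for a, _ in self.hpd68)

    @property
    def hpd68_old(self) -> float:
        return max(b for _, b in self.hpd68)


@dataclass
class PhaseFit:
    start: PhaseEstimate
    end: PhaseEstimate
    rhat: dict[str, float]
    converged: bool


def hpd_interval(samples: np.ndarray, level: float) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    k = max(1, int(np.ceil(level * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman-Rubin)."""
    m, n = chains.shape
    half = n // 2
    sub = chains[:, : 2 * half].reshape(2 * m, half)
    means = sub.mean(axis=1)
    variances = sub.var(axis=1, ddof=1)
    w = variances.mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def _event_posterior(
    density: CalibratedDensity,
    window: tuple[float, float],
    settings: BAMSettings,
) -> CalibratedDensity:
    """Exact marginal posterior of one event's true age on the grid."""
    old, young = max(window), min(window)
    grid = density.grid_ka
    scale = settings.extra_error_scale * density.sd()
    if scale > 0 and settings.n_quad > 1:
        # quadrature over the half-normal shrinkage prior on the extra error
        qs = (np.arange(settings.n_quad) + 0.5) / settings.n_quad
        sigmas = scale * norm.ppf(0.5 + qs / 2.0)  # half-normal quantiles
        from scipy.ndimage import gaussian_filter1d

        step = density.step_ka
        mixed = np.zeros_like(density.mass)
        for s in sigmas:
            if s < step / 2:
                mixed += density.mass
            else:
                mixed += gaussian_filter1d(density.mass, s / step, mode="constant")
        mass = mixed / settings.n_quad
    else:
        mass = density.mass.copy()
    inside = (grid >= young) & (grid <= old)
    if not inside.any() or mass[inside].sum() <= 0:
        raise ValueError(
            f"event {density.label or '<unnamed>'} has no posterior support "
            f"inside the window [{young}, {old}] ka BP"
        )
    mass = np.where(inside, mass, 0.0)
    return CalibratedDensity(grid, mass / mass.sum(), label=density.label)


def fit_bam(
    events: list[CalibratedDensity],
    window: tuple[float, float] = (55.0, 30.0),
    settings: BAMSettings | None = None,
    criteria: str = "",
) -> PhaseFit:
    """Fit the phase model and summarize the start/end boundary posteriors.

    Parameters
    ----------
    events : list of CalibratedDensity
        One calibrated density per event (same-sample repeats pooled first).
    window : (old_ka, young_ka)
        Uniform study-window prior for every event.
    """
    if not events:
        raise ValueError("a phase needs at least one event")
    settings = settings or BAMSettings()
    posteriors = [_event_posterior(d, window, settings) for d in events]

    root = np.random.SeedSequence(settings.seed)
    chain_seeds = root.spawn(settings.n_chains)
    starts = np.empty((settings.n_chains, settings.n_draws))
    ends = np.empty((settings.n_chains, settings.n_draws))
    for c, seq in enumerate(chain_seeds):
        rng = np.random.default_rng(seq)
        draws = np.column_stack(
            [p.sample(settings.n_draws, rng) for p in posteriors]
        )
        starts[c] = draws.max(axis=1)  # start of the phase is the oldest event
        ends[c] = draws.min(axis=1)

    rhat = {"start": _split_rhat(starts), "end": _split_rhat(ends)}
    keep = slice(settings.burn, None)
    start_s = starts[:, keep].ravel()
    end_s = ends[:, keep].ravel()

    def summarize(samples: np.ndarray, kind: str) -> PhaseEstimate:
        h95 = hpd_interval(samples, 0.95)
        h68 = hpd_interval(samples, 0.68)
        h68 = (max(h68[0], h95[0]), min(h68[1], h95[1]))
        if np.ptp(samples) < 1e-12:
            mode = float(samples[0])
        else:
            kde = gaussian_kde(samples)
            grid = np.linspace(h95[0], h95[1], 512)
            mode = float(grid[int(np.argmax(kde(grid)))])
        return PhaseEstimate(
            kind=kind,
            mode=mode,
            hpd68=[h68],
            hpd95=[h95],
            ess=samples.size,
            criteria=criteria,
            samples=samples,
        )

    fit = PhaseFit(
        start=summarize(start_s, "start"),
        end=summarize(end_s, "end"),
        rhat=rhat,
        converged=max(rhat.values()) < settings.rhat_threshold,
    )
    return fit
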