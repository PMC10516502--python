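# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `paleocoex`. Ages are everywhere in ka cal BP
(present = 1950, larger = older); NPP is kg/m²/yr; carrying capacity (CC)
is kg/km²/yr.

## Chronometric filtering and calibration

Two filtering tiers are applied throughout. FC1 keeps dates from reliable
protocols only: AMS (with or without ultrafiltration) and ABOx-SC
radiocarbon, OSL/TL and U-series; it always drops conventional
radiocarbon, records flagged for contamination, low collagen yield or
burnt bone, and dates whose relative error (1σ/age) is ≥ 0.05. FC2
additionally requires the dated material to be human-brought or
-modified. Techno-complexes map to the NAI/SAI species proxies with the
Chatelperronian/Uluzzian attributions exposed as toggles; complexes
without diagnostic human fossils (Szeletian, Bohunician, LRJ) are always
excluded. Unknown labels are excluded with a logged warning, not an error,
so a compilation with unexpected industries still runs.

Calibration places the density
`p(θ) ∝ N(m − ΔR; μ(θ), √(s² + σ(θ)² + s_R²))` on a regular calendar grid.
The grid step is 0.005 ka (5 yr) by default — fine enough that the
round-trip error through a curve is below one step — and the support is
truncated at ±5σ. Marine samples use a marine-flagged curve with ΔR = 0
(the convention for MIS3, where reservoir offsets are unknown and
proportionally small). Luminescence and U-series ages bypass the curve as
normal densities. Same-sample repeats are pooled by inverse-variance
weighting with a 1-df-per-extra-date chi-square consistency test before
entering any phase model. Calibration curves are read and written in the
field's three-column text dialect (cal BP, ¹⁴C age, σ; comment lines
allowed), so a user-supplied IntCal20/Marine20 file drops in directly;
no curve is redistributed with the package.

## Bayesian phase model

A phase groups the dated events of one techno-complex in one region; one
event is one date (same-sample repeats pooled first). Each event's true
age θᵢ has a uniform prior over the study window and a likelihood equal to
its calibrated density widened by an event-level extra error under a
half-normal shrinkage prior whose scale is the event's own posterior SD
(`extra_error_scale` × SD; 1.0 by default, 0 disables it). The extra
variance absorbs palimpsest scatter and unmodelled inter-lab offsets and
reproduces the behaviour of event-level chronological models, which yield
wider credibility intervals than phase-boundary priors that shrink toward
the best-dated event.

Because the θᵢ are conditionally independent given the window, the
implementation computes each marginal posterior exactly on the calendar
grid (the shrinkage prior is marginalized by 5-node quantile quadrature
over the half-normal) and obtains the phase start/end posteriors — the
per-draw maximum/minimum of the member θᵢ — from iid Monte-Carlo draws.
Draws are organized into three seeded chains (4000 draws each by default)
and a split-chain R-hat is reported with an acceptance threshold of 1.05;
with iid draws it sits at 1 by construction, and the diagnostic exists to
catch regressions if a dependent sampler is ever substituted. This
replaces a Metropolis MCMC with an exactly convergent computation of the
same posterior; it is faster and removes tuning concerns.

Summaries: the HPD at each level is the shortest interval over sorted
pooled samples; the mode is the argmax of a Gaussian-KDE smooth (Silverman
bandwidth) evaluated inside the HPD95, which guarantees the mode lies in
the 95% envelope even for skewed boundary posteriors.

The phase minimum/maximum underestimates how far the true boundary
extends beyond the dated record (the archaeological Signor–Lipps effect),
so phase-end estimates are biased slightly old and starts slightly young.
This bias is shared across regions and cancels in cross-region
comparisons; OLE (below) provides the extrapolation-based counterpart.
On synthetic worlds the two methods' regional endpoints agree with a
regression slope within [0.8, 1.2].

## Optimal linear estimation

The Solow–Roberts estimator uses the k most extreme sightings (5 ≤ k ≤ 10,
default 5; regions with fewer than five dates are refused). The joint
Weibull shape is `v̂ = (k−1)⁻¹ Σ log[(t₁−t_k)/(t₁−t_{i+1})]` and the
endpoint is the weight vector `Λ⁻¹e/(e'Λ⁻¹e)` applied to the extremes,
with Λ the extreme-order covariance built from gamma functions in log
space for numerical stability. First appearances reflect the time axis.
The point estimate is clamped to lie at or beyond the most extreme
sighting, and ties across all k sightings return the common value.

Measurement uncertainty is propagated by resampling: each age is redrawn
from a normal with its 1σ error and the estimator re-applied (10,000
resamples by default). The reported point estimate is the median of the
resampled estimates. The reported 95% CI aggregates the analytic
Roberts–Solow interval across resamples (2.5th percentile of lower
bounds, 97.5th of upper bounds): the analytic interval carries the
sighting-gap uncertainty that pure measurement resampling misses, and the
aggregation adds the measurement component. In simulation (10 sightings
uniform over 7 ka, 0.35-ka errors) this CI covers the true endpoint ~96%
of the time, whereas raw resample percentiles cover only ~74%; the raw
percentiles remain available as `OLEResult.resample_ci`. When v̂ is small
the analytic far bound can be very wide — that is the honest statement of
how weakly the spacings constrain the endpoint.

## KDE overlap surfaces

Per 1-ka bin between 50 and 30 ka BP, each date contributes its calibrated
mass inside the bin, spread over a 0.5° grid with a Gaussian kernel on
haversine distance (sphere radius 6371 km) with σ = 150 km — a bandwidth
on the scale of ethnographic annual mobility. The overlap raster is the
pixel-wise NAI × SAI product, non-zero exactly where both proxies have
support. Rasters are xarray Datasets on (time, lat, lon).

## Biogeographic regions

dCORT between two NPP series on a shared grid is
`φ_k(CORT) · d_Euclid(raw values)` with CORT the cosine similarity of
first differences and `φ_k(u) = 2/(1+e^{ku})` (k = 2 by default; k = 0
reduces to plain Euclidean distance; the base distance is raw Euclidean,
configurable). Clustering is agglomerative with average linkage —
deterministic relabeling by smallest member id, so input order never
matters — and the default cluster count maximizes the relative gap in
merge heights. The same machinery clusters the guild Jaccard matrix.
The Köppen–Geiger classifier implements the Peel-style thresholds for
the extratropical C/D/E families ("a" at hottest ≥ 22 °C, "b" at ≥ 4
months ≥ 10 °C, tundra at 0 < hottest ≤ 10 °C; dry-summer/dry-winter
ratios 1/3 and 1/10), read from a machine-readable rule table in
`data/koppen_rules.yaml`. Regions are the refinement of the NPP clusters
split by climate class or fauna cluster, numbered east to west by mean
longitude; the partition never merges NPP clusters.

## Carrying capacity

Total supportable herbivore biomass per time step is
`B_tot(t) = f · (NPP(t)·10⁶)^β` kg/km²/yr (β = 1 by default, so CC is
homogeneous of degree one in NPP). The guild shares B_tot in proportion
to the allometric expected biomass `a·M^{b+1}` (individual density a·M^b
times mass); a species' CC is its share averaged over the window and a
size class is the exact sum of its members (small < 20 kg, medium 20–300
inclusive, large > 300; species under 1 kg are rejected at ingest).

Defaults are this package's own documented calibration, not fitted
values: a = 91.2 ind/km² and b = −0.73 in the range of classical mammal
density–mass allometries, and f = 0.0027 chosen once so a reference NPP
of 0.3 kg/m²/yr supports ≈ 800 kg/km²/yr of herbivores — the scale implied
by summing the packaged region-table size classes. All four are
configuration with 95% CIs; uncertainty is propagated by Monte-Carlo
draws of (a, b, f) (normal, sd = CI width/3.92, truncated to physical
ranges; 1000 draws by default). The central estimate uses central
parameters, so degenerate cases have closed forms; CI bounds are clamped
to bracket it. Whether to time-average before or after parameter
propagation is ambiguous in principle; draws are time-averaged (each draw
is a full trajectory), which keeps class additivity exact per draw.

Validation correlates predicted allometric densities against observed
park densities per park (≥ 3 matched species) and pooled; on noiseless
model-generated data the pooled r is 1 by construction, and with
lognormal noise (σ = 0.5) it sits in the 0.4–0.95 band. Guild
completeness uses incidence-based rarefaction (hypergeometric
interpolation; Chao2-style extrapolation of undetected species) with a
500-replicate bootstrap over levels for the 95% CI.

## Coexistence summaries

Minimal overlap = youngest SAI-start 95% bound − oldest NAI-end 95%
bound; central overlap = mode difference; a region coexists when the
minimal overlap is positive (a 68%-based variant is available via the
`level` flag). Group contrasts are unweighted means with
`100·(1 − mean_no-coex/mean_coex)`. The packaged no-coexistence partition
{R_2, R_3, R_13, R_16} is shipped as data because no rule applied to the
packaged chronology tables alone reproduces it exactly (e.g. R_5's modes
also fail to overlap); the summary functions accept any partition. The
CV is 100·sample SD/mean; the packaged tables reproduce their own printed
CVs only to rounding, so fixture checks allow for that. The percentile
classification in reports uses inclusive linear quartiles over regions
(L < Q1, H > Q3, boundary ties M); the packaged tables' printed class
column follows a different, unpublished reference distribution and is
not asserted.

## Eigenvector spatial filtering

Weights are inverse great-circle distance (or a distance band), zero
diagonal, with a row-standardized copy; the scheme is configurable since
no single convention is canonical. Candidate filters are eigenvectors of
`M W M` (M the centering projector) with eigenvalue above 0.25 of the
maximum — map patterns of positive spatial autocorrelation. Forward
selection adds the candidate that most reduces |residual Moran's I| and
stops when the residual autocorrelation is no longer significant at 0.10
(permutation test, 199 permutations inside selection by default) or no
candidate improves; selected vectors strictly reduce |I| at every step,
and with zero selections the fit is exactly plain OLS. The coefficient
of interest and its two-sided p come from the OLS of y on x plus selected
vectors.

CI uncertainty is propagated by redrawing every y and x value from a
two-piece normal (sd above/below the estimate from the corresponding CI
half-width / 1.96; optional truncation to the bounds) and refitting,
10,000 times by default with a global scale-down factor in the pipeline.
Reported: the coefficient and p distributions, their medians, and the
fraction of resamples with p ≤ 0.05. No multiple-testing correction is
applied across variable pairs — the output is the p-value distribution
itself. Under a spatially structured null the procedure's type-I error is
5–6% at nominal 5%; regions lacking an SAI phase are dropped from overlap
regressions with a log message.

## Synthetic worlds

The generator reproduces the statistical structure the analysis assumes,
not the physics behind it. Regions sit on a jittered lattice over a
Europe-sized lat/lon box (abstract geography; great-circle distances are
still meaningful). NPP is a square-wave stadial/interstadial signal with
change-points jittered around a 1.5-ka cycle (Dansgaard–Oeschger pacing)
plus AR(1) noise (ρ = 0.8), base 0.28 ± regional spatial variation,
amplitude 0.08, noise SD 0.02 — chosen to match the mean/CV ranges of the
packaged region table. Guilds are regional subsets of a 20-species master
pool spanning 2–3900 kg. The true NAI end is uniform in the younger third
of the window; the true overlap is `1.5 + overlap_effect·(CC_med −
mean) + η` with η spatially autocorrelated (exponential covariance,
500-km range, SD 0.75 ka) — the ESF stage's reason for existing. One site
per region ends its NAI occupation exactly at the true end (and one
starts its SAI occupation exactly at the true start), so the truth is
recoverable; all other intervals shrink inward exponentially, which
reproduces the record's inward bias. Dates mix AMS (80%), ABOx (7%),
conventional (5%, filtered out downstream), and OSL/TL (8%); lab errors
are lognormal around 0.35 ka with occasional 8× inflation to exercise the
CV filter; QC flags and anthropic flags are Bernoulli. A hidden
`_true_age_ka` column carries provenance for recovery tests only.

What the generator does not emulate: climate fields (no monthly normals
are generated, so synthetic pipeline runs use a single Köppen class),
taphonomic loss gradients, inter-lab offsets (a single lab-error term is
assumed), marine reservoirs, and real geography. Passing recovery tests
therefore demonstrate the estimators' statistical correctness under the
stated error model, not robustness to every bias in real compilations.

## Problem sizes and numerical conventions

Default test/acceptance problem sizes are the package's own choices for a
single-CPU run: phase-model coverage over 50 synthetic phases of 20
events; OLE coverage over 1000 sighting records with 100 measurement
resamples each; ESF type-I error over 2000 nulls of 30 regions with
99-permutation Moran tests; power over 20 worlds of 30 regions × 12
sites with 100 CI resamples per world. Pipeline defaults use a 0.01-ka
calibration grid (single-date calibration defaults to 0.005). Ties in
clustering are broken lexicographically by id; degenerate inputs
(constant series, empty classes, zero-width CIs) take the documented
conventions rather than erroring where a convention exists.

## Known limitations

- The phase model treats events as exchangeable within a phase; no
  stratigraphic ordering constraints are used.
- The CC model is bottom-up only: no seasonality, predation, or
  density-dependence beyond the allometry, and the NPP–biomass transfer
  is assumed stationary. CC is an index of potential biomass for
  comparison between regions, not an abundance estimate.
- The OLE analytic CI assumes the Weibull tail model; with very few or
  nearly equally spaced sightings its far bound is weakly constrained.
- Region delimitation on synthetic worlds exercises the machinery but the
  analysis units default to the generator's regions, mirroring a study
  design where regions are fixed before regression.
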