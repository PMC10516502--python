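# paleocoex

Ecosystem productivity, herbivore carrying capacity, and the regional
chronology of the Middle-to-Upper-Paleolithic transition (MUPT) in Europe.

## The scientific problem

During Marine Isotope Stage 3 (~60–30 ka BP) Neanderthals were replaced by
*H. sapiens* across Europe, but the timing was a regional mosaic: in some
regions the Neanderthal-associated industries (NAI) vanish millennia before
the first *H. sapiens*-associated industries (SAI); in others the two
overlap for thousands of years. One candidate driver is trophic resource
availability: regions whose ecosystems sustained more herbivore biomass
could absorb a second large predator into the guild, extending coexistence.

`paleocoex` implements the full inference chain needed to test this idea,
usable both on synthetic data with known ground truth and on packaged
region-level summary tables:

1. **Chronology** — quality filtering of chronometric dates under two tiers
   (FC1: reliable lab protocols; FC2: additionally only human-modified
   material), radiocarbon calibration against an IntCal-dialect curve,
   same-sample pooling, a hierarchical Bayesian phase model giving the
   posterior mode and HPD intervals of each techno-complex's start/end per
   region, the Solow–Roberts optimal linear estimator (OLE) as an
   independent endpoint method, and spatiotemporal KDE overlap surfaces
   (Gaussian kernel, σ = 150 km, 1-ka bins).
2. **Biogeography** — region delimitation by clustering NPP trajectories
   with the dCORT dissimilarity `φ_k(CORT) · d_Euclid` (CORT = correlation
   of first differences, `φ_k(u) = 2/(1+e^{ku})`), refined by
   Köppen–Geiger climate class and Jaccard guild dissimilarity.
3. **Carrying capacity** — a macroecological model partitioning the
   NPP-supported herbivore biomass `B_tot = f · NPP` among guild members in
   proportion to their Damuth-style allometric biomass `a·M^{b+1}`
   (defaults a = 91.2 ind/km², b = −0.73), with Monte-Carlo CI propagation,
   modern-density validation, and incidence-based rarefaction with
   bootstrap CIs.
4. **Coexistence** — minimal overlap (youngest SAI 95% bound − oldest NAI
   95% bound) and central overlap (mode difference) per region, plus the
   group contrasts between coexistence and no-coexistence regions.
5. **Spatial statistics** — Moran-eigenvector spatial filtering (ESF):
   OLS of a chronological variable on an ecological one plus
   forward-selected eigenvectors of the doubly-centered spatial weight
   matrix, with uncertainty propagated by redrawing every variable from its
   95% CI (10,000 resamples by default).
6. **Synthetic data** — a generator producing a complete world (regions,
   NPP with stadial/interstadial square-wave dynamics, guilds, occupation
   histories, noisy dates through a toy calibration curve) in which the
   true regional NAI/SAI overlap is linear in the true medium-size CC, so
   every stage has a recoverable ground truth.

## Worked example

`examples/05_full_synthetic_run.py` generates a 16-region world with a
planted positive effect of medium-size herbivore CC on the NAI/SAI overlap
(0.02 ka per kg/km²/yr) and runs the full chain:

```
regions with both phases: 16 / 16
coexistence regions (minimal overlap > 0): 3
overlap~cc_medium: median coefficient 0.0152, median p 0.0108, fraction of resamples significant 0.80
nai_end~cc_medium: median coefficient -0.0007, median p 0.5845, fraction of resamples significant 0.02
```

The planted overlap–CC slope (0.02) is recovered (median coefficient
0.015, significant in 80% of the CI resamples), while the unplanted
NAI-end association correctly stays null. The `examples/` directory holds
one short script per capability: calibration and same-sample pooling,
phase/OLE endpoint estimation, region delimitation, carrying capacity and
rarefaction, and the full pipeline.

The packaged region tables can be analysed directly:

```python
from paleocoex.datasets import load_productivity_table, NO_COEXISTENCE_REGIONS
from paleocoex.coexistence import group_percent_difference

tab = load_productivity_table()
cmp = group_percent_difference(tab["medium_mean"], NO_COEXISTENCE_REGIONS)
print(round(cmp.percent_difference, 1))   # 41.1 — % lower medium-size CC
                                          # where NAI and SAI never overlap
```

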