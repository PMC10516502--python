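"""Estimate a techno-complex end date with the phase model and with OLE.

Simulates 20 dated events from an occupation that truly ends at 38.0 ka BP,
then estimates the phase end with the Bayesian phase model and the
extinction-style OLE extrapolation.
"""

import numpy as np

from paleocoex.chronology import BAMSettings, OLEConfig, calibrate, fit_bam, run_ole
from paleocoex.synthetic import generate_toy_calibration_curve

rng = np.random.default_rng(0)
curve = generate_toy_calibration_curve(window=(60.0, 0.0), wiggle_amplitude=0.0, seed=0)

true_ages = rng.uniform(38.0, 42.0, size=20)      # occupation truly ends at 38.0
measured = rng.normal(true_ages, 0.3)
densities = [calibrate(m, 0.3, curve, units="ka") for m in measured]

fit = fit_bam(densities, window=(55.0, 30.0), settings=BAMSettings(seed=1))
lo, hi = fit.end.hpd95[0]
print(f"phase end mode: {fit.end.mode:.2f} ka BP, HPD95 [{lo:.2f}, {hi:.2f}]")
print(f"convergence R-hat: {max(fit.rhat.values()):.3f}")
# The phase end posterior tracks the youngest events; its HPD95 should
# bracket the true boundary at 38.0 ka BP.

ole = run_ole(measured, np.full(20, 0.3), OLEConfig(k=5, n_resamples=2000, seed=2))
print(
    f"OLE last-appearance estimate: {ole.estimate:.2f} ka BP, "
    f"95% CI [{ole.ci_low:.2f}, {ole.ci_high:.2f}]"
)
# OLE extrapolates beyond the youngest sighting using the spacing of the
# k most extreme dates, so its point estimate sits at or below the
# youngest measured age.
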