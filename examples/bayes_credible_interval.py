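"""Noninformative-Bayes HPD interval on a simulated reproducibility study.

We simulate a 96-sample x 6-lab study with true ICC_b = 0.70, fit the
flat-on-standard-deviations posterior by Gibbs sampling, and compare the
highest-posterior-density interval with the equal-tailed one and with the
frequentist MLS interval on the same data.
"""

import numpy as np

from icc_intervals import (
    DesignSpec,
    ScenarioSpec,
    compute_mean_squares,
    fit_posterior,
    generate,
    hpd_interval,
    mls_interval,
)
from icc_intervals.bayes import equal_tailed_interval

spec = ScenarioSpec(
    design=DesignSpec(b0=96, l0=6, r0=1),
    icc_b=0.70,
    icc_w=0.90,
    family="normal",
    mu=10.0,
    seed=42,
)
grid = generate(spec)

from icc_intervals import estimate_variance_components, point_icc_b

summary = compute_mean_squares(grid)
plug_in = point_icc_b(estimate_variance_components(summary))

sample = fit_posterior(grid, n_iter=60_000, burnin=10_000, thin=10, seed=7)
hpd = hpd_interval(sample, level=0.95)
et = equal_tailed_interval(sample, level=0.95)
mls = mls_interval(summary, level=0.95)

print(f"true ICC_b = {spec.icc_b}; this dataset's plug-in estimate = {plug_in:.3f}")
print(f"posterior median = {np.median(sample.rho_b):.3f} "
      f"(ESS {sample.meta['ess_rho']:.0f})")
print(f"95% HPD:          ({hpd.lower:.3f}, {hpd.upper:.3f})  width {hpd.width:.3f}")
print(f"95% equal-tailed: ({et.lower:.3f}, {et.upper:.3f})  width {et.width:.3f}")
print(f"95% MLS:          ({mls.lower:.3f}, {mls.upper:.3f})  width {mls.width:.3f}")
print()
print("With only 6 labs the lab variance is poorly determined, so a single "
      "dataset's realized ICC can sit well away from the truth - note how "
      "the posterior median tracks this dataset's own plug-in estimate, and "
      "how the frequentist interval agrees.  The HPD window is never wider "
      "than the equal-tailed one on the same draws.")
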