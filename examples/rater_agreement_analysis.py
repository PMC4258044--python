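"""Analyze a published rater-agreement ANOVA table.

A psychiatric-agreement study had 24 children scored by 10 emergency-room
staff members (one score per child-rater pair).  Only the ANOVA table is
needed: the three observed mean squares and the design.  We invert the
expected mean squares to variance components, form the between-rater ICC,
and attach the two frequentist intervals.
"""

from icc_intervals import (
    AnovaSummary,
    DesignSpec,
    estimate_variance_components,
    gci_interval,
    mls_interval,
    point_icc_b,
    point_icc_w,
)

summary = AnovaSummary(
    ms_subject=95.450,  # children
    ms_rater=4.414,     # staff raters
    ms_error=0.786,
    design=DesignSpec(b0=24, l0=10, r0=1),
)

vc = estimate_variance_components(summary)
gci = gci_interval(summary, level=0.95, n_draws=100_000, seed=1)
mls = mls_interval(summary, level=0.95)

print(f"variance components: subject {vc.sigma2_b:.4f}, "
      f"rater {vc.sigma2_l:.6f}, error {vc.sigma2_e:.4f}")
print(f"ICC_b = {point_icc_b(vc):.4f}   (agreement between raters)")
print(f"ICC_w = {point_icc_w(vc):.4f}   (repeatability within one rater)")
print(f"95% GCI: ({gci.lower:.4f}, {gci.upper:.4f})   [{gci.meta['n_draws']} pivot draws]")
print(f"95% MLS: ({mls.lower:.4f}, {mls.upper:.4f})   [closed form]")
print()
print("About 91% of score variance is real child-to-child difference; even "
      "the interval lower bounds stay above 0.84, so rater agreement is high.")
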