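"""Small coverage/width campaign under the normal model.

Repeatedly simulate a 48-subject x 3-lab study with true ICC_b = 0.70 and
ICC_w = 0.99, build 95% intervals by each method, and report how often they
contain the truth and how wide they are.  (Published full-scale campaigns
use 10,000 replicates; 1,000 keeps this demo under a minute.)
"""

from icc_intervals import DesignSpec, IntervalSettings, ScenarioSpec, run_coverage_study

spec = ScenarioSpec(
    design=DesignSpec(b0=48, l0=3, r0=1), icc_b=0.70, icc_w=0.99, family="normal"
)
settings = IntervalSettings(level=0.95, gci_draws=10_000)

records = run_coverage_study(
    spec, methods=["mls", "gci", "bayes"], n_reps=1_000,
    interval_settings=settings, seed=1,
)

print(f"design {spec.design.b0}x{spec.design.l0}, true ICC_b={spec.icc_b}, "
      f"ICC_w={spec.icc_w}, nominal level {settings.level:.0%}")
print(f"{'method':8s} {'coverage':>9s} {'mean width':>11s} {'(sem)':>8s}")
for rec in records:
    print(f"{rec.method:8s} {rec.coverage:9.3f} {rec.mean_width:11.3f} "
          f"({rec.sem_width:.4f})")
print()
print("MLS and GCI sit near the nominal 0.95 with practically identical "
      "widths, while the noninformative-Bayes HPD interval misses the truth "
      "far more often on this 3-lab design - the failure mode that drives "
      "the package's method guidance.")
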