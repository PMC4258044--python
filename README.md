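# icc-intervals

Point and interval estimation for intraclass correlation coefficients (ICCs)
in the balanced two-way crossed random-effects model — the standard model
for reproducibility and inter-rater agreement studies in which every
biological sample (subject, patient, ...) is measured by every laboratory
(rater, instrument, ...).

## The model and the two ICCs

For subject *b* = 1..*b₀*, lab *l* = 1..*l₀* and replicate *r* = 1..*r₀*,

```
y_blr = μ + B_b + L_l + e_blr,
B_b ~ N(0, σ²_b),  L_l ~ N(0, σ²_l),  e_blr ~ N(0, σ²_e),  all independent.
```

Two variance ratios summarize reproducibility:

* **ICC_b** = σ²_b / (σ²_b + σ²_l + σ²_e) — agreement *between* labs: the
  fraction of total variance that is real subject-to-subject signal.
* **ICC_w** = (σ²_b + σ²_l) / (σ²_b + σ²_l + σ²_e) — repeatability *within*
  one lab.  Always ICC_w ≥ ICC_b.

Point estimates invert the expected mean squares of the two-way ANOVA
(method of moments, negative estimates truncated at zero).  For ICC_b the
package provides three 95%-style intervals:

* **GCI** — generalized confidence interval: Monte Carlo quantiles of a
  generalized pivotal quantity built from independent χ² variates and the
  observed mean squares.
* **MLS** — modified large sample: closed-form limits calibrated to be
  exact when all but one variance component vanishes.
* **NIB HPD** — noninformative Bayes: Gibbs sampling under an improper
  prior flat on (σ_b, σ_l, σ_e), with a highest-posterior-density credible
  interval.  This prior keeps the induced ICC prior non-degenerate and the
  posterior scale-invariant.

A simulation harness measures coverage probability and mean width of each
method under normal, uniform, bimodal-mixture and skewed shifted-gamma
effect distributions (all moment-matched to the same variance components),
plus a Shapiro–Wilk residual study quantifying how hard skewness is to
detect, and a design-guidance helper.

## Worked example

A psychiatric-agreement study scored 24 children on video, each rated by 10
emergency-room staff members.  Only the ANOVA table is needed (mean squares
95.450 children / 4.414 raters / 0.786 error):

```bash
python examples/rater_agreement_analysis.py
```

```
variance components: subject 9.4664, rater 0.151167, error 0.7860
ICC_b = 0.9099   (agreement between raters)
ICC_w = 0.9244   (repeatability within one rater)
95% GCI: (0.8413, 0.9525)   [100000 pivot draws]
95% MLS: (0.8412, 0.9536)   [closed form]
```

About 91% of the score variance is genuine child-to-child difference, and
the interval lower bounds stay above 0.84, so agreement is high.  The other
scripts in `examples/` demonstrate the Bayes interval, a coverage campaign,
and the normality screen; the same operations are available from a thin CLI:

```bash
icc point --ms 95.450 4.414 0.786 --design 24 10 1
icc gci   --ms 95.450 4.414 0.786 --design 24 10 1 --draws 100000 --seed 1
icc simulate --family gamma --alpha 3 --b0 48 --l0 3 --icc-b 0.7 --icc-w 0.99 --out data.csv
icc bayes data.csv --iters 100000 --burnin 10000 --thin 10 --seed 1
icc recommend --b0 48 --l0 3
```

## Method guidance in one paragraph

Under normality, MLS and GCI hold 95% coverage with practically identical
widths across designs as small as 48 subjects × 3 labs; the
noninformative-Bayes HPD interval undercovers on few-lab designs while not
being narrower, and becomes competitive only at roughly 8+ levels of the
smaller factor.  Under strong skewness (shifted gamma, skewness 1.15) no
method holds nominal coverage, and about half of such datasets still pass a
Shapiro–Wilk residual screen — so a passing normality test is weak
assurance.  `recommend_method` encodes exactly this logic, caveats included.
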