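# Methods

## Model and estimands

All computations assume the balanced two-way crossed random-effects model
without interaction,

    y_blr = mu + B_b + L_l + e_blr,    b = 1..b0, l = 1..l0, r = 1..r0,

with mutually independent zero-mean effects: `B_b` (subjects / biological
samples), `L_l` (labs / raters / instruments) and errors `e_blr`, with
variances sigma2_b, sigma2_l, sigma2_e.  With r0 = 1 the additive model is
saturated and the "error" mean square is the residual (interaction) mean
square; the package treats the replicate index as informational only.

The estimands are the between-lab ICC, rho_b = sigma2_b / total, and the
within-lab ICC, rho_w = (sigma2_b + sigma2_l) / total, where total is the
sum of the three components.  rho_w >= rho_b holds identically.

Expected mean squares: E[MS_subject] = sigma2_e + l0 r0 sigma2_b,
E[MS_rater] = sigma2_e + b0 r0 sigma2_l, E[MS_error] = sigma2_e, with
degrees of freedom (b0-1, l0-1, r0 b0 l0 - b0 - l0 + 1).  Point estimation
inverts these moments.  Negative inversions are truncated at zero *for
point estimates only*, keeping the reported ICCs inside [0, 1]; both
interval methods consume the untruncated observed mean squares, which is
how their calibration theory is stated.

## Generalized confidence interval (GCI)

No exact pivot exists for rho_b, so the interval uses a generalized pivotal
quantity.  Conditional on the observed mean squares (S1, S2, S3), draw
independent W1 ~ chi2(n1), W2 ~ chi2(n2), W3 ~ chi2(n3) and form component
pivots

    T_b = c2 S1/W1 - c3 S3/W3,         c2 = (b0-1)/(l0 r0),  c3 = n3/(l0 r0)
    T_l = c1 S2/W2 - (n3/(b0 r0)) S3/W3,   c1 = (l0-1)/(b0 r0)
    T_e = n3 S3/W3,

whose conditional distributions match the frequentist uncertainty about the
three variance components.  The ICC pivot is G = T_b+/(T_b+ + T_l+ + T_e)
with negative component pivots clamped at zero, so G always lies in [0, 1];
T_e is strictly positive, so no resampling is ever needed in practice
(an all-zero denominator would be resampled).  The equal-tailed interval
takes the alpha/2 and 1-alpha/2 empirical quantiles of a Monte Carlo sample
of G (default 100,000 draws; numpy's linear-interpolation quantile
estimator).  Replacing each W by its degrees of freedom collapses G to the
truncated plug-in estimate, a useful self-check.

Numerical notes: chi-squared variates come from one seeded generator per
interval call, making results bit-reproducible; the interval is invariant
to rescaling all three mean squares; endpoint Monte Carlo error scales as
n_draws^(-1/2) and is about 0.001 at 100,000 draws for the worked example.

## Modified large sample (MLS) interval

MLS limits are deterministic functions of the observed mean squares.  The
target is reached through lambda = sigma2_b/(sigma2_l + sigma2_e), with
rho_b = lambda/(1+lambda) monotone.  The claim lambda > x is equivalent to
positivity of

    delta(x) = theta_1 - x (l0/b0) theta_2 - (1 + x (l0/b0)(b0 r0 - 1)) theta_3

in the expected mean squares theta_i.  The package uses the square-root MLS
bounds with per-component squared contributions,

    L(x) = delta_hat(x) - sqrt(g1^2 S1^2 + h2^2 d2(x)^2 S2^2 + h3^2 d3(x)^2 S3^2)
    U(x) = delta_hat(x) + sqrt(h1^2 S1^2 + g2^2 d2(x)^2 S2^2 + g3^2 d3(x)^2 S3^2)

with g_i = 1 - 1/F(alpha; n_i, inf), h_i = 1/F(1-alpha; n_i, inf) - 1 at
alpha = (1-level)/2 per tail, and d2, d3 the (positive) coefficients of the
negative terms.  Each confidence limit is the root in x of the
corresponding bound; roots are bracketed on [0, 1e9] with Brent's method at
1e-12 tolerance (lambda = 1e9 is treated as the open upper end, i.e. an
upper ICC limit of 1).  Results are clipped to [0, 1] with pre-clip values
kept in the result metadata.

Design choice: a refinement of these bounds adds cross-product terms
(F-quantile combinations of mean-square pairs) to the square-root.  Both
forms are exactly calibrated when all but one variance component vanishes;
they differ by a few thousandths in endpoint position on realistic designs.
We ship the squared-terms-only form: in this package's own coverage
campaigns (normal model, 48x3 and larger designs, 10,000 replicates) it
holds 95.0-95.1% coverage at ICC_w = 0.99 and shows the expected mild
conservatism (96.9%) at ICC_w = 0.71, while sitting slightly wide of the
GCI, whereas the cross-term form was consistently slightly narrower than
the GCI in the same campaigns.  The agreement gate |MLS - GCI| < 0.02 per
endpoint on the worked example holds for both.

## Noninformative-Bayes HPD interval

The prior is improper and flat on (mu, sigma_b, sigma_l, sigma_e), i.e.
uniform on standard deviations.  Among common "noninformative" variance
priors this one neither concentrates the induced rho_b prior at {0, 1} nor
reacts to rescaling the data; inverse-gamma priors do both, which is why
they are not offered.

Sampling is Gibbs with conjugate blocks.  Effects and mu have normal full
conditionals; under the flat-on-sigma prior each variance has an
inverse-gamma full conditional with shape (n-1)/2 and rate S/2 for n
effects with sum of squares S.  The sampler advances many chains at once on
stacked arrays (one chain per dataset), which is what makes 1,000-replicate
Bayes coverage campaigns feasible on one CPU in about a minute.  rho_b is
derived per retained draw.  Defaults: 100,000 iterations / 10,000 burn-in /
thin 10 for single-dataset analyses; 13,000 / 3,000 / 10 (1,000 retained)
for harness campaigns.  Effective sample size of the rho chain is estimated
with arviz and a warning is recorded below ESS 100.  With l0 = 2 the
rater-variance conditional has shape 1/2 and the posterior is barely
proper; the package warns for l0 < 3.

The reported interval is the highest-posterior-density (HPD) window: the
shortest interval containing ceil(level * n) sorted draws.  It is never
wider than the equal-tailed interval on the same draws (offered behind a
flag).  Note a finite-sample artifact: the HPD width estimated from m
retained draws is biased downward, noticeably so at m = 1,000.  Coverage
checks use the harness schedule above; the qualitative comparison of Bayes
vs frequentist mean widths uses 5,000 retained draws per dataset, where the
bias is small.

## Synthetic data

`ScenarioSpec` fixes a design, target (ICC_b, ICC_w), a distribution family
and a total variance (default 1 — coverage and width for rho_b depend on
the components only through the scale-invariant ICCs, so the absolute scale
is a pure normalization).  Components solve sigma2_b = ICC_b * T,
sigma2_l = (ICC_w - ICC_b) * T, sigma2_e = (1 - ICC_w) * T.

All four families are moment-matched: zero mean and exactly the requested
variance per term.

* normal: N(0, sd^2).
* uniform on [-A, A], A = sd sqrt(3).
* mixture: equal-weight normal mixture at +/- m with component sd m/3,
  m = 3 sd / sqrt(10); bimodal, symmetric.
* gamma: w = G - alpha * theta, G ~ Gamma(alpha, theta), theta =
  sd/sqrt(alpha); skewness 2/sqrt(alpha), kurtosis 3 + 6/alpha.  Shape 3 is
  the "high skew" setting (1.15, 5), shape 10 "low skew" (0.63, 3.6).

Each random term draws from its own substream spawned from the scenario
seed, so changing one dimension leaves the other terms' draws intact.  What
the generator does *not* emulate: unbalanced or missing data,
heterogeneous within-lab variances, subject-by-lab interaction, serial or
batch correlation.  Passing coverage tests under these scenarios therefore
says nothing about such violations.

## Evaluation harness

`run_coverage_study` simulates n_reps datasets (all methods see the same
data), builds each interval, and records containment of the true ICC_b
(closed endpoints), mean width, width SEM, and the mean/SD of the point
estimates.  Interval failures are excluded with a recorded count and may
not exceed 0.1% of replicates.  Campaign defaults: 10,000 replicates;
Bayes rows may use 1,000 replicates (SE of a coverage estimate near 0.86 is
then about 0.011).  GCI intervals inside campaigns default to 10,000 pivot
draws rather than 100,000 — endpoint MC error ~0.003, negligible against
between-dataset variation — keeping a 10,000-replicate GCI campaign near
two minutes.

`shapiro_residual_study` targets the r0 = 1 case, where the additive-fit
residuals are exactly the doubly centered errors
r_bl = y_bl - ybar_b. - ybar_.l + ybar..; each simulated dataset yields one
Shapiro-Wilk p-value (scipy implementation, cross-checked against R's
shapiro.test to machine-level agreement).  Under the high-skew gamma model
at 48x3 roughly half the p-values exceed 0.05 — the headline fact that a
badly skewed model usually passes a residual screen.  Residual vectors are
capped at n = 5000 (the test's reliable range).

`recommend_method` encodes the resulting decision logic: non-normal
residuals -> no method endorsed (transform or redesign); normal-looking
residuals with fewer than 8 levels of the smaller factor -> MLS or GCI
(the Bayes interval undercovers there while not being narrower); 8+ levels
-> all three.  The 8-level cutoff is an estimate from simulation evidence,
flagged as such in the rationale text, and the rationale always carries the
weak-screen caveat.

## Degenerate inputs and edge cases

* All mean squares zero: undefined ICC, raised as an error.
* MS_subject below MS_error: point estimate truncates to sigma2_b = 0; the
  GCI/MLS lower limits clamp to 0 naturally.
* Mean squares implying lambda -> inf (error MS ~ 0): upper limits clip
  to 1.
* Ties in posterior draws or pivot samples: quantile/HPD interpolation
  handles them without special casing.

## Known limitations

* Interval support is for ICC_b only; ICC_w gets a point estimate but no
  interval (the constructions here are not validated for it).
* Balanced complete designs only; no REML/ML, no unbalanced data.
* The Bayes module offers a single prior family; sensitivity analysis
  across priors is out of scope.
* Printed-table comparisons in the test suite are Monte Carlo quantities;
  tolerances of 2-3 standard errors are used, so single-test failures at
  the band edge can occur at roughly the implied rates.
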