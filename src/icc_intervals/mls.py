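"""Modified large sample (MLS) confidence limits for ICC_b.

The MLS approach corrects naive large-sample limits on variance-component
functions so that the interval is exact whenever all but one variance
component vanishes.  ICC_b is handled through the monotone transformation

    lambda = sigma2_b / (sigma2_l + sigma2_e),    ICC_b = lambda / (1 + lambda),

and the statement ``lambda > x`` is rewritten as positivity of the linear
combination of expected mean squares

    delta(x) = theta_subject - x (l0/b0) theta_rater
               - (1 + x (l0/b0)(b0 r0 - 1)) theta_error.

For a combination sum_i c_i theta_i - sum_j c_j theta_j with observed mean
squares S_i, the MLS bounds are the plug-in estimate minus (lower) or plus
(upper) a square-root term with squared per-component contributions,

    L = delta_hat - sqrt( g1^2 c1^2 S1^2 + h2^2 c2^2 S2^2 + h3^2 c3^2 S3^2 )
    U = delta_hat + sqrt( h1^2 c1^2 S1^2 + g2^2 c2^2 S2^2 + g3^2 c3^2 S3^2 )

where g_i = 1 - 1/F(alpha; n_i, inf) and h_i = 1/F(1-alpha; n_i, inf) - 1
are the one-sided chi-squared coefficients at the working tail probability
alpha = (1 - level)/2.  Each confidence limit for ``lambda`` is the value of
``x`` at which the corresponding bound for ``delta(x)`` crosses zero; it is
found by deterministic root bracketing and mapped back to the ICC scale.
When all but one component is zero the bound collapses to the exact
chi-squared limit for that component, which is the MLS calibration property.
The resulting interval is deterministic, scale invariant in the mean
squares, and clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import chi2
from scipy.stats import f as f_dist

from .anova import AnovaSummary
from .errors import UndefinedIccError
from .results import IntervalResult

__all__ = ["MlsConstants", "mls_constants", "mls_interval"]

_LAMBDA_MAX = 1e9  # lambda ~ 1e9 maps to ICC_b ~ 1 - 1e-9; treated as the open upper end


def _f_upper_inf(p: float, a: float) -> float:
    """Upper-tail quantile of F(a, infinity) = chi2(a)/a."""
    return float(chi2.isf(p, a)) / a


@dataclass(frozen=True)
class MlsConstants:
    """The six quantile constants of the MLS square-root terms.

    All depend only on the confidence level and the three degrees of freedom
    (df_subject, df_rater, df_error) = (n1, n2, n3); two summaries with the
    same design and level share identical constants.  g_i shrinks an
    overestimated component (lower limits), h_i inflates an underestimated
    one (upper limits); both are one-sided chi-squared coefficients expressed
    through F(n_i, infinity) quantiles.
    """

    level: float
    df_subject: int
    df_rater: int
    df_error: int
    g1: float
    g2: float
    g3: float
    h1: float
    h2: float
    h3: float


def mls_constants(level: float, summary: AnovaSummary) -> MlsConstants:
    """Compute the quantile constants for ``summary``'s design at ``level``.

    Equal tail split: each square-root term works at alpha/2 per side.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    n1, n2, n3 = summary.df_subject, summary.df_rater, summary.df_error
    al = (1.0 - level) / 2.0
    return MlsConstants(
        level=level,
        df_subject=n1,
        df_rater=n2,
        df_error=n3,
        g1=1.0 - 1.0 / _f_upper_inf(al, n1),
        g2=1.0 - 1.0 / _f_upper_inf(al, n2),
        g3=1.0 - 1.0 / _f_upper_inf(al, n3),
        h1=1.0 / _f_upper_inf(1.0 - al, n1) - 1.0,
        h2=1.0 / _f_upper_inf(1.0 - al, n2) - 1.0,
        h3=1.0 / _f_upper_inf(1.0 - al, n3) - 1.0,
    )


def _lambda_bounds(summary: AnovaSummary, k: MlsConstants) -> tuple[float, float]:
    s1, s2, s3 = summary.ms_subject, summary.ms_rater, summary.ms_error
    d = summary.design
    u = d.l0 / d.b0
    v = u * (d.b0 * d.r0 - 1)

    def delta_hat(x: float) -> float:
        return s1 - x * u * s2 - (1.0 + x * v) * s3

    def v_lower(x: float) -> float:
        d2 = x * u
        d3 = 1.0 + x * v
        return k.g1**2 * s1**2 + k.h2**2 * d2**2 * s2**2 + k.h3**2 * d3**2 * s3**2

    def v_upper(x: float) -> float:
        d2 = x * u
        d3 = 1.0 + x * v
        return k.h1**2 * s1**2 + k.g2**2 * d2**2 * s2**2 + k.g3**2 * d3**2 * s3**2

    def lo_fn(x: float) -> float:
        return delta_hat(x) - np.sqrt(v_lower(x))

    def up_fn(x: float) -> float:
        return delta_hat(x) + np.sqrt(v_upper(x))

    if lo_fn(0.0) <= 0.0:
        lam_lo = 0.0
    else:
        lam_lo = brentq(lo_fn, 0.0, _LAMBDA_MAX, xtol=1e-12, rtol=1e-14)
    if up_fn(0.0) <= 0.0:
        lam_up = 0.0
    elif up_fn(_LAMBDA_MAX) > 0.0:
        lam_up = np.inf
    else:
        lam_up = brentq(up_fn, 0.0, _LAMBDA_MAX, xtol=1e-12, rtol=1e-14)
    return lam_lo, lam_up


def mls_interval(summary: AnovaSummary, level: float = 0.95) -> IntervalResult:
    """Closed-form (no Monte Carlo) MLS interval for ICC_b.

    Deterministic: identical inputs give bit-identical intervals.  Raises
    :class:`UndefinedIccError` when all three mean squares are zero.
    """
    if summary.ms_subject == 0 and summary.ms_rater == 0 and summary.ms_error == 0:
        raise UndefinedIccError("all mean squares are zero; ICC undefined")
    k = mls_constants(level, summary)
    lam_lo, lam_up = _lambda_bounds(summary, k)
    raw_lower = lam_lo / (1.0 + lam_lo)
    raw_upper = 1.0 if np.isinf(lam_up) else lam_up / (1.0 + lam_up)
    return IntervalResult(
        method="mls",
        level=level,
        lower=float(np.clip(raw_lower, 0.0, 1.0)),
        upper=float(np.clip(raw_upper, 0.0, 1.0)),
        meta={"raw_lower": raw_lower, "raw_upper": raw_upper},
    )
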