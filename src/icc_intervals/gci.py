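"""Generalized confidence interval (GCI) for ICC_b.

No exact pivot exists for ICC_b in the two-way crossed random model, so the
interval is built from a *generalized* pivotal quantity: a function of the
observed mean squares and of independent chi-squared variates

    W1 ~ chi2(df_subject), W2 ~ chi2(df_rater), W3 ~ chi2(df_error)

whose conditional distribution, given the observed mean squares, is free of
unknown parameters.  Writing c1 = (l0-1)/(b0 r0), c2 = (b0-1)/(l0 r0) and
c3 = df_error/(l0 r0), the component pivots are

    T_b = c2 MS_subject / W1 - c3 MS_error / W3          (for sigma2_b)
    T_l = c1 MS_rater  / W2 - (df_error/(b0 r0)) MS_error / W3   (for sigma2_l)
    T_e = df_error MS_error / W3                         (for sigma2_e)

and the ICC pivot is G = T_b+ / (T_b+ + T_l+ + T_e), with negative component
pivots clamped at zero so that G stays in [0, 1].  Empirical quantiles of a
large Monte Carlo sample of G give the equal-tailed interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anova import AnovaSummary
from .results import IntervalResult

__all__ = ["PivotalDraws", "draw_pivot", "gci_interval", "pivot_bounds_many"]


@dataclass(frozen=True)
class PivotalDraws:
    """A Monte Carlo sample of the generalized ICC_b pivot."""

    g_values: np.ndarray
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_draws < 1000:
            raise ValueError("need at least 1000 pivot draws")
        g = np.asarray(self.g_values)
        if g.shape != (self.n_draws,) or g.min() < 0 or g.max() > 1:
            raise ValueError("g_values must be n_draws values in [0, 1]")


def _pivot_constants(summary: AnovaSummary) -> tuple[float, float, float, float]:
    d = summary.design
    c1 = (d.l0 - 1) / (d.b0 * d.r0)
    c2 = (d.b0 - 1) / (d.l0 * d.r0)
    c3 = d.df_error / (d.l0 * d.r0)
    ce = d.df_error / (d.b0 * d.r0)
    return c1, c2, c3, ce


def _pivot_values(
    summary: AnovaSummary,
    w1: np.ndarray,
    w2: np.ndarray,
    w3: np.ndarray,
) -> np.ndarray:
    """ICC_b pivot realizations from chi-squared triples (broadcastable)."""
    c1, c2, c3, ce = _pivot_constants(summary)
    t_b = np.clip(c2 * summary.ms_subject / w1 - c3 * summary.ms_error / w3, 0.0, None)
    t_l = np.clip(c1 * summary.ms_rater / w2 - ce * summary.ms_error / w3, 0.0, None)
    t_e = summary.design.df_error * summary.ms_error / w3
    denom = t_b + t_l + t_e
    with np.errstate(invalid="ignore"):
        g = np.where(denom > 0, t_b / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(g, 0.0, 1.0)


def draw_pivot(summary: AnovaSummary, n_draws: int = 100_000, seed: int = 0) -> PivotalDraws:
    """Sample ``n_draws`` realizations of the generalized ICC_b pivot.

    One seeded generator per call; identical arguments give bit-identical
    samples.  In the infinite-df limit (each W replaced by its df) the pivot
    collapses to the truncated plug-in point estimate of ICC_b.
    """
    if n_draws < 1000:
        raise ValueError("need at least 1000 pivot draws")
    d = summary.design
    rng = np.random.default_rng(seed)
    w1 = rng.chisquare(d.df_subject, n_draws)
    w2 = rng.chisquare(d.df_rater, n_draws)
    w3 = rng.chisquare(d.df_error, n_draws)
    g = _pivot_values(summary, w1, w2, w3)
    return PivotalDraws(g_values=g, n_draws=n_draws, seed=seed)


def gci_interval(
    summary: AnovaSummary,
    level: float = 0.95,
    n_draws: int = 100_000,
    seed: int = 0,
) -> IntervalResult:
    """Equal-tailed (level)-GCI for ICC_b from ``n_draws`` pivot samples.

    Endpoints are the alpha/2 and 1 - alpha/2 empirical quantiles (linear
    interpolation between order statistics).  The interval is invariant to
    rescaling all three mean squares by a common positive factor.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    draws = draw_pivot(summary, n_draws=n_draws, seed=seed)
    alpha = 1.0 - level
    lower, upper = np.quantile(draws.g_values, [alpha / 2, 1.0 - alpha / 2])
    return IntervalResult(
        method="gci",
        level=level,
        lower=float(lower),
        upper=float(upper),
        meta={"n_draws": n_draws, "seed": seed},
    )


def pivot_bounds_many(
    ms: np.ndarray,
    design,
    level: float,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """GCI bounds for a stack of ANOVA summaries sharing one design.

    ``ms`` has shape (n, 3) with columns (MS_subject, MS_rater, MS_error).
    Returns an (n, 2) array of interval bounds.  Used by the simulation
    harness, where constructing one interval at a time would dominate the
    runtime; a fresh block of chi-squared triples is drawn for each summary.
    """
    ms = np.asarray(ms, dtype=float)
    n = ms.shape[0]
    alpha = 1.0 - level
    qs = (alpha / 2, 1.0 - alpha / 2)
    d = design
    c1 = (d.l0 - 1) / (d.b0 * d.r0)
    c2 = (d.b0 - 1) / (d.l0 * d.r0)
    c3 = d.df_error / (d.l0 * d.r0)
    ce = d.df_error / (d.b0 * d.r0)
    out = np.empty((n, 2))
    for i in range(n):
        s1, s2, s3 = ms[i]
        w1 = rng.chisquare(d.df_subject, n_draws)
        w2 = rng.chisquare(d.df_rater, n_draws)
        w3 = rng.chisquare(d.df_error, n_draws)
        t_b = np.clip(c2 * s1 / w1 - c3 * s3 / w3, 0.0, None)
        t_l = np.clip(c1 * s2 / w2 - ce * s3 / w3, 0.0, None)
        t_e = d.df_error * s3 / w3
        g = t_b / (t_b + t_l + t_e)
        out[i] = np.quantile(g, qs)
    return np.clip(out, 0.0, 1.0)
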