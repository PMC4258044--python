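"""Balanced two-way ANOVA decomposition and ICC point estimation.

Mean squares for the additive model are the classical balanced two-way
quantities,

    MS_subject = l0 r0 * sum_b (ybar_b.. - ybar...)^2 / (b0 - 1)
    MS_rater   = b0 r0 * sum_l (ybar_.l. - ybar...)^2 / (l0 - 1)
    MS_error   = SS_residual / (r0 b0 l0 - b0 - l0 + 1)

with expected values

    E[MS_subject] = sigma2_e + l0 r0 sigma2_b
    E[MS_rater]   = sigma2_e + b0 r0 sigma2_l
    E[MS_error]   = sigma2_e.

Inverting the expectations gives the method-of-moments variance-component
estimates, and from those the two intraclass correlations:

    ICC_b = sigma2_b / (sigma2_b + sigma2_l + sigma2_e)
    ICC_w = (sigma2_b + sigma2_l) / (sigma2_b + sigma2_l + sigma2_e).

``ICC_b`` measures agreement *between* raters/labs (the proportion of total
variance due to real subject differences); ``ICC_w`` measures repeatability
*within* a single rater/lab, and always dominates ``ICC_b``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DataGrid, DesignSpec
from .errors import UndefinedIccError

__all__ = [
    "AnovaSummary",
    "VarianceComponents",
    "compute_mean_squares",
    "estimate_variance_components",
    "point_icc_b",
    "point_icc_w",
]


@dataclass(frozen=True)
class AnovaSummary:
    """Observed mean squares and degrees of freedom of the two-way fit.

    Can be built from raw data via :func:`compute_mean_squares` or directly
    from a published ANOVA table (summary-mode input).
    """

    ms_subject: float
    ms_rater: float
    ms_error: float
    design: DesignSpec

    def __post_init__(self) -> None:
        if min(self.ms_subject, self.ms_rater, self.ms_error) < 0:
            raise ValueError("mean squares must be non-negative")

    @property
    def df_subject(self) -> int:
        return self.design.df_subject

    @property
    def df_rater(self) -> int:
        return self.design.df_rater

    @property
    def df_error(self) -> int:
        return self.design.df_error

    def raw_components(self) -> tuple[float, float, float]:
        """Untruncated method-of-moments components (may be negative)."""
        d = self.design
        s2e = self.ms_error
        s2b = (self.ms_subject - self.ms_error) / (d.l0 * d.r0)
        s2l = (self.ms_rater - self.ms_error) / (d.b0 * d.r0)
        return s2b, s2l, s2e


@dataclass(frozen=True)
class VarianceComponents:
    """Non-negative variance components (sigma2_b, sigma2_l, sigma2_e)."""

    sigma2_b: float
    sigma2_l: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if min(self.sigma2_b, self.sigma2_l, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def total(self) -> float:
        return self.sigma2_b + self.sigma2_l + self.sigma2_e


def compute_mean_squares(grid: DataGrid) -> AnovaSummary:
    """Two-way (no-interaction) ANOVA mean squares of a balanced grid.

    Location-invariant: adding a constant to every response leaves all three
    mean squares unchanged.  Multiplying responses by ``c`` multiplies every
    mean square by ``c**2``.
    """
    y = grid.values
    d = grid.design
    gm = y.mean()
    subj_means = y.mean(axis=(1, 2))
    rater_means = y.mean(axis=(0, 2))
    ss_subject = d.l0 * d.r0 * float(np.sum((subj_means - gm) ** 2))
    ss_rater = d.b0 * d.r0 * float(np.sum((rater_means - gm) ** 2))
    ss_total = float(np.sum((y - gm) ** 2))
    ss_error = ss_total - ss_subject - ss_rater
    return AnovaSummary(
        ms_subject=ss_subject / d.df_subject,
        ms_rater=ss_rater / d.df_rater,
        ms_error=max(ss_error, 0.0) / d.df_error,
        design=d,
    )


def estimate_variance_components(summary: AnovaSummary) -> VarianceComponents:
    """Method-of-moments estimates, truncated at zero.

    Negative inversions (possible when an effect mean square falls below the
    error mean square) are clipped to 0 so the derived ICCs stay in [0, 1].
    Interval methods operate on the untruncated mean squares directly and are
    unaffected by this rule; see :meth:`AnovaSummary.raw_components` for the
    raw values.
    """
    s2b, s2l, s2e = summary.raw_components()
    return VarianceComponents(max(s2b, 0.0), max(s2l, 0.0), s2e)


def _check_total(vc: VarianceComponents) -> float:
    if vc.total <= 0:
        raise UndefinedIccError("all variance components are zero; ICC undefined")
    return vc.total


def point_icc_b(vc: VarianceComponents) -> float:
    """Between-rater ICC: share of total variance due to subjects."""
    return vc.sigma2_b / _check_total(vc)


def point_icc_w(vc: VarianceComponents) -> float:
    """Within-rater ICC: subject plus rater share of total variance."""
    return (vc.sigma2_b + vc.sigma2_l) / _check_total(vc)
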