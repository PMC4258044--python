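"""Balanced two-way crossed designs and their data grids.

A reproducibility (or inter-rater agreement) study in the balanced two-way
crossed layout measures ``b0`` subjects by each of ``l0`` raters/labs, with
``r0`` replicate measurements per (subject, rater) cell.  The additive
random-effects model without interaction is

    y_blr = mu + B_b + L_l + e_blr,

with mutually independent zero-mean effects ``B_b`` (subjects), ``L_l``
(raters/labs) and errors ``e_blr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BalanceError, DesignError

__all__ = ["DesignSpec", "DataGrid"]


@dataclass(frozen=True)
class DesignSpec:
    """A balanced b0 x l0 x r0 crossed design.

    Parameters
    ----------
    b0 : number of subject (biological sample, patient, ...) levels, >= 2.
    l0 : number of rater/lab/instrument levels, >= 2.
    r0 : replicates per (subject, rater) cell, >= 1.
    """

    b0: int
    l0: int
    r0: int = 1

    def __post_init__(self) -> None:
        if self.b0 < 2 or self.l0 < 2 or self.r0 < 1:
            raise DesignError(
                f"need b0 >= 2, l0 >= 2, r0 >= 1; got ({self.b0}, {self.l0}, {self.r0})"
            )
        if self.df_error < 1:
            raise DesignError(
                f"error degrees of freedom {self.df_error} < 1 for design "
                f"({self.b0}, {self.l0}, {self.r0})"
            )

    @property
    def df_subject(self) -> int:
        return self.b0 - 1

    @property
    def df_rater(self) -> int:
        return self.l0 - 1

    @property
    def df_error(self) -> int:
        # residual df of the additive (no-interaction) fit
        return self.r0 * self.b0 * self.l0 - self.b0 - self.l0 + 1

    @property
    def n_obs(self) -> int:
        return self.b0 * self.l0 * self.r0


@dataclass
class DataGrid:
    """A complete grid of responses for a :class:`DesignSpec`.

    ``values`` has shape ``(b0, l0, r0)``; axis order is (subject, rater,
    replicate).  Labels are optional and carried through I/O only.
    """

    values: np.ndarray
    design: DesignSpec
    subject_labels: list[str] = field(default_factory=list)
    rater_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        expected = (self.design.b0, self.design.l0, self.design.r0)
        if v.ndim == 2 and self.design.r0 == 1:
            v = v[:, :, None]
        if v.shape != expected:
            raise BalanceError(
                f"values shape {v.shape} does not match design {expected}"
            )
        if not np.all(np.isfinite(v)):
            raise BalanceError("grid contains non-finite values")
        self.values = v
        if not self.subject_labels:
            self.subject_labels = [str(i + 1) for i in range(self.design.b0)]
        if not self.rater_labels:
            self.rater_labels = [str(i + 1) for i in range(self.design.l0)]

    @property
    def grand_mean(self) -> float:
        return float(self.values.mean())
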