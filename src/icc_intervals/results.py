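"""Common interval-result container shared by the three methods."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["IntervalResult"]


@dataclass(frozen=True)
class IntervalResult:
    """A two-sided interval for ICC_b on the [0, 1] scale.

    ``method`` is one of ``"gci"``, ``"mls"``, ``"bayes"``; ``meta`` carries
    Monte Carlo settings (draws, seed, chain settings, pre-clip bounds, ...)
    sufficient to reproduce the result.
    """

    method: str
    level: float
    lower: float
    upper: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError(
                f"require 0 <= lower <= upper <= 1, got ({self.lower}, {self.upper})"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        """Closed-endpoint containment."""
        return self.lower <= value <= self.upper
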