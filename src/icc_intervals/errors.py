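"""Exception types raised across the package."""


class IccError(Exception):
    """Base class for all package-specific errors."""


class DesignError(IccError):
    """The design is too small or degenerate (e.g. error df < 1)."""


class BalanceError(IccError):
    """The data do not form a complete balanced subject x rater x replicate grid."""


class UndefinedIccError(IccError):
    """All variance components (or all mean squares) are zero, so no ICC exists."""


class InfeasibleTargetError(IccError):
    """Requested target ICC pair violates 0 < ICC_b <= ICC_w < 1."""
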