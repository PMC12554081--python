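"""Exception hierarchy.

All user-facing errors derive from :class:`EffectKitError` so callers (and the
CLI) can map them onto exit codes: configuration problems, malformed data, and
numeric failures are distinguished.
"""


class EffectKitError(Exception):
    """Base class for all errors raised by effectkit."""


class InvalidInputError(EffectKitError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedCorrelationError(InvalidInputError):
    """A correlation was requested on constant input."""


class ZeroCellError(InvalidInputError):
    """A 2x2 table cell needed for an odds ratio is zero.

    The offending cell name is stored in :attr:`cell`.
    """

    def __init__(self, cell: str):
        self.cell = cell
        super().__init__(
            f"contingency cell '{cell}' is zero; enable the continuity "
            "correction (+0.5 to every cell) to proceed"
        )


class UnsupportedCombinationError(InvalidInputError):
    """A combination of options has no defined behaviour (e.g. the
    normal-theory equivalence p-value with an asymmetric interval)."""


class IncompatibleMetricError(InvalidInputError):
    """An effect estimate was placed against a benchmark table for a
    different metric without an explicit conversion."""


class UnattainablePowerError(InvalidInputError):
    """No finite sample size reaches the requested power (zero effect)."""


class ConfigError(EffectKitError):
    """The analysis configuration is invalid or incomplete (exit code 2)."""


class DataError(EffectKitError):
    """An input table could not be parsed or fails validation (exit code 3)."""


class NumericError(EffectKitError):
    """A computation failed numerically (exit code 4)."""
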