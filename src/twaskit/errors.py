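"""Exception hierarchy shared across the package."""


class TwaskitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TwaskitError):
    """An input file is malformed or missing required columns."""


class EmptyInputError(TwaskitError):
    """An input contained no usable records after validation."""


class DomainError(TwaskitError, ValueError):
    """An argument lies outside its mathematical or logical domain."""


class UndefinedStatisticError(TwaskitError):
    """The variance term w'Dw is numerically zero, so z_TWAS is undefined."""


class FeatureSkipped(TwaskitError):
    """A gene-tissue feature was excluded from the scan (not fatal).

    The ``reason`` attribute carries a human-readable explanation that is
    propagated into the scan's skip log.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class ConfigError(TwaskitError):
    """Pipeline configuration is inconsistent or incomplete."""
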