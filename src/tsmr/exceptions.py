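"""Exception hierarchy for the tsmr package."""


class TsmrError(Exception):
    """Base class for all package errors."""


class FormatError(TsmrError):
    """A summary-statistics or LD file could not be parsed."""


class HarmonizationError(TsmrError):
    """Allele sets of the two traits cannot be reconciled for a SNP."""


class ConfigurationError(TsmrError):
    """Invalid configuration, unknown preset, or missing required input."""


class NoInstrumentsError(TsmrError):
    """An analysis leg was left with zero instruments."""


class InsufficientInstrumentsError(TsmrError):
    """A method needs more instruments than are available."""

    def __init__(self, method: str, needed: int, available: int):
        self.method = method
        self.needed = needed
        self.available = available
        super().__init__(
            f"{method} requires at least {needed} instruments, got {available}"
        )
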