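"""Exception hierarchy for the pvsignal pipeline."""


class PvSignalError(Exception):
    """Base class for all pvsignal errors."""


class FormatError(PvSignalError, ValueError):
    """Raised when an input file violates the expected tabular format."""


class ConfigError(PvSignalError, ValueError):
    """Raised for invalid configuration (probabilities, hyperparameters, ...)."""


class InvalidTableError(PvSignalError, ValueError):
    """Raised when a contingency table cannot support a statistic (e.g. a < 1)."""


class UnmappedTermError(PvSignalError, KeyError):
    """Raised when preferred terms are missing from the PT -> SOC map.

    Carries the offending terms in ``.terms``.
    """

    def __init__(self, terms):
        self.terms = sorted(terms)
        super().__init__(f"preferred terms not present in PT->SOC map: {self.terms}")
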