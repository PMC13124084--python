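"""Exception hierarchy shared across the package."""


class CogmarkerError(Exception):
    """Base class for all package-specific errors."""


class LexiconError(CogmarkerError):
    """Raised when the packaged lexicon resource is missing, corrupt, or
    contains a row/pattern that cannot be parsed or compiled."""


class CorpusFormatError(CogmarkerError):
    """Raised when an input corpus file violates the expected dialect."""


class EmptyCohortError(CogmarkerError):
    """Raised when a prevalence denominator would be zero."""


class EmptyDistributionError(CogmarkerError):
    """Raised when no session contributes to a within-session distribution."""


class UndefinedRatioError(CogmarkerError):
    """Raised when a prevalence ratio has a zero denominator prevalence."""


class DegenerateSampleError(CogmarkerError):
    """Raised when a statistical test receives a sample it cannot handle
    (too few values, zero variance where positive variance is required)."""


class ConfigError(CogmarkerError):
    """Raised for invalid simulation or run configuration."""
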