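"""Exception hierarchy shared across the pipeline stages."""


class TimepairError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TimepairError):
    """An input record or table violates a stage's contract."""


class ConfigurationError(TimepairError):
    """A configuration value is out of its documented range."""


class UnitError(TimepairError):
    """An expression matrix was passed in the wrong unit."""


class DesignError(TimepairError):
    """The paired design and the supplied samples do not match."""


class ParseError(TimepairError):
    """A file does not conform to its declared dialect."""
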