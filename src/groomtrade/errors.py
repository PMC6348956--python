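"""Exception hierarchy shared across the package."""


class GroomtradeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GroomtradeError):
    """The input file does not conform to the expected schema."""


class RecordError(GroomtradeError):
    """A single record violates an invariant (bad actor pair, duration, ...)."""


class ConfigError(GroomtradeError):
    """Invalid configuration values."""


class AnalysisError(GroomtradeError):
    """An analysis precondition is not met (too few individuals, no data, ...)."""
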