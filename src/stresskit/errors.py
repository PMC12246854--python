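"""Exception hierarchy shared by all stresskit modules."""


class StressKitError(Exception):
    """Base class for all stresskit errors."""


class FormatError(StressKitError):
    """A file does not parse under its declared dialect."""


class ValidationError(StressKitError):
    """Parsed data violates a domain-type invariant."""


class ParameterError(StressKitError):
    """An operation was called with an out-of-range parameter."""


class ConfigError(StressKitError):
    """Configuration is inconsistent with the data it describes."""


class NumericalError(StressKitError):
    """A numerical step is degenerate (e.g. singular extinction matrix)."""
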