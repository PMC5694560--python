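"""Exception hierarchy shared across the package."""


class MQTLKitError(Exception):
    """Base class for all package errors."""


class MapFormatError(MQTLKitError):
    """A tabular input is structurally malformed (e.g. missing columns)."""


class ValidationError(MQTLKitError):
    """A row or record violates a documented invariant."""


class ProjectionError(MQTLKitError):
    """A position cannot be projected (too few anchors, broken frame)."""


class AnalysisError(MQTLKitError):
    """A meta-analysis precondition is violated (empty input, bad K)."""


class ConfigError(MQTLKitError):
    """A pipeline configuration is invalid or references missing files."""
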