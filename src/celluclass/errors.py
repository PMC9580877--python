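"""Exception hierarchy shared across the pipeline."""


class CelluclassError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CelluclassError):
    """A catalog or run configuration is invalid."""


class ValidationError(CelluclassError):
    """Input data violates a documented precondition."""


class ParseError(CelluclassError):
    """A file could not be interpreted in the declared format."""
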