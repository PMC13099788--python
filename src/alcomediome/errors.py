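"""Shared exception types."""


class AlcomediomeError(Exception):
    """Base class for package errors."""


class ConfigError(AlcomediomeError, ValueError):
    """Invalid configuration value; message names the offending field."""


class SchemaError(AlcomediomeError, KeyError):
    """Input table is missing required columns or has the wrong layout."""


class DomainError(AlcomediomeError, ValueError):
    """Numeric input outside the mathematical domain of an operation."""


class UsageError(AlcomediomeError, ValueError):
    """Operation called in a way its contract forbids (bad k, missing term, ...)."""


class AlignmentError(AlcomediomeError, ValueError):
    """Per-sample inputs whose lengths or indexes do not line up."""


class RankError(AlcomediomeError, ValueError):
    """Design matrix rank deficiency / aliased terms; message names the terms."""


class ConvergenceError(AlcomediomeError, RuntimeError):
    """Iterative fit failed to converge and no flagged-fit fallback applies."""
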