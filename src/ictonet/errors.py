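"""Exception hierarchy shared across the pipeline."""


class IctonetError(Exception):
    """Base class for all package errors."""


class FormatError(IctonetError):
    """Malformed signal file (missing channel column, non-numeric data, ...)."""


class AnnotationError(IctonetError):
    """Invalid stage annotation (non-monotone timestamps, empty slice, ...)."""


class StructuralError(IctonetError):
    """Inconsistent table / graph structure (missing columns, bad nodes)."""


class ConfigError(IctonetError):
    """Invalid configuration value (unstable coupling matrix, bad fraction)."""
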