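"""Exception types shared across the package."""


class HalotaxisError(Exception):
    """Base class for package errors."""


class ParameterError(HalotaxisError, ValueError):
    """A physical or configuration parameter is outside its valid range."""


class TrackFormatError(HalotaxisError, ValueError):
    """Track table is malformed (columns, dtypes, ordering, duplicates)."""


class DegenerateTrackError(HalotaxisError, ValueError):
    """A track cannot support the requested statistic (e.g. zero mean speed)."""


class FitError(HalotaxisError, RuntimeError):
    """A model fit failed to converge; carries diagnostic detail."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(HalotaxisError, ValueError):
    """Pipeline/CLI configuration is invalid (unknown keys, missing paths)."""
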