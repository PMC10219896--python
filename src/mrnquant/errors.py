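"""Exception types shared across the pipeline."""


class MrnQuantError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MrnQuantError, ValueError):
    """A physical or statistical parameter is outside its valid domain."""


class GeometryError(MrnQuantError, ValueError):
    """Requested geometry cannot be rendered (e.g. nerve disc exceeds the FOV)."""


class EmptyROIError(MrnQuantError, ValueError):
    """A slice was analyzed whose mask contains no foreground pixel."""


class IncompleteCoverageError(MrnQuantError, ValueError):
    """The supplied slabs do not cover the configured slice range."""


class RegionUndefinedError(MrnQuantError, ValueError):
    """A region aggregate was requested but no valid slice contributes to it."""


class UndefinedCorrelationError(MrnQuantError, ValueError):
    """Correlation undefined because one input has zero variance."""
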