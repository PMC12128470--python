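"""Exception hierarchy for trace ingestion and analysis."""


class NoximError(Exception):
    """Base class for all package-specific errors."""


class TraceFormatError(NoximError):
    """A trace file could not be parsed (bad delimiter, non-numeric cell, ...)."""


class TraceStructureError(NoximError):
    """A trace file parsed but violates structural requirements (e.g. timestamps not increasing)."""


class CoverageError(NoximError):
    """A trace does not span the requested analysis window."""


class DegenerateTraceError(NoximError):
    """No valid samples remain; downstream metrics are undefined."""


class ValidationError(NoximError):
    """An input value is outside its permitted domain."""
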