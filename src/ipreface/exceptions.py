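"""Package-level exception hierarchy.

Each stage of the pipeline raises a distinct subclass so that CLI error
messages can name the failing stage.
"""


class IprefaceError(Exception):
    """Base class for all package errors."""


class ClassificationError(IprefaceError):
    """Five-tier level lookup failed (missing axis value or incomplete table)."""


class TimelineValidationError(IprefaceError):
    """A labor-case timeline or event-placement invariant is violated."""


class SchemaError(IprefaceError):
    """An input file does not match the documented schema."""


class CoverageError(IprefaceError):
    """A scoring window is not fully covered by the CTG recording."""


class ScoringError(IprefaceError):
    """An event in a scoring window cannot be scored (e.g. no level assigned)."""


class AnalysisError(IprefaceError):
    """A diagnostic-accuracy computation received degenerate input."""


class ComparisonError(IprefaceError):
    """Group comparison received an empty or invalid grouping."""


class GenerationError(IprefaceError):
    """The synthetic-cohort generator was given an infeasible configuration."""


class SignalError(IprefaceError):
    """Trace rendering / deceleration detection received inconsistent signals."""
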