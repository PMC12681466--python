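"""Exception hierarchy for the event-related force-plate pipeline.

Every stage raises a subclass of :class:`ErfpError` so callers can catch
pipeline failures without masking programming errors.
"""


class ErfpError(Exception):
    """Base class for all package errors."""


class ParameterError(ErfpError, ValueError):
    """A parameter violates its documented constraints."""


class FormatError(ErfpError, ValueError):
    """A file on disk does not match the expected schema."""


class ConsistencyError(ErfpError, ValueError):
    """Cross-table references disagree (e.g. events for unknown trials)."""


class OrderingError(ErfpError, ValueError):
    """A table is not sorted the way the operation requires."""


class LayoutError(ErfpError, ValueError):
    """Simulated trials overlap in time."""


class SegmentationError(ErfpError, ValueError):
    """An epoch window does not fit inside the recording."""


class AlignmentError(ErfpError, ValueError):
    """Two series do not share a time base."""


class AggregationError(ErfpError, ValueError):
    """A participant x condition cell has no included trials."""


class DegenerateInputError(ErfpError, ValueError):
    """Too few observations for the requested statistic."""


class DesignError(ErfpError, ValueError):
    """An experimental design constraint is violated."""


class PipelineError(ErfpError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


class PlottingError(ErfpError, ValueError):
    """Figure rendering received empty or inconsistent input."""
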