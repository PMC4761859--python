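"""Exception hierarchy shared across the package."""


class GraspkinError(Exception):
    """Base class for all graspkin errors."""


class FormatError(GraspkinError, ValueError):
    """An input file or array does not have the expected layout."""


class ValidationError(GraspkinError, ValueError):
    """A domain invariant is violated (e.g. non-monotone timestamps)."""


class ParameterError(GraspkinError, ValueError):
    """A parameter is out of its admissible range."""


class CapabilityError(GraspkinError, RuntimeError):
    """The input lacks a channel required by the requested operation."""


class EventNotFoundError(GraspkinError, RuntimeError):
    """An event detector found no sample satisfying its criterion.

    ``event`` names the detection stage that failed ("contact", "onset",
    "apex", "end") so pipeline callers can report how far they got.
    """

    def __init__(self, event: str, message: str = ""):
        self.event = event
        detail = f": {message}" if message else ""
        super().__init__(f"event not found: {event}{detail}")


class CalibrationError(GraspkinError, RuntimeError):
    """Automatic mirror-annulus calibration failed."""


class DegenerateClusterError(GraspkinError, RuntimeError):
    """Fewer distinct colors than requested clusters."""


class AmbiguousClusterError(GraspkinError, RuntimeError):
    """Two cluster centroids are equidistant from the skin reference."""


class UndefinedMetricError(GraspkinError, ValueError):
    """A metric is undefined for this input (e.g. zero traveled distance)."""


class PipelineError(GraspkinError, RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(message or f"pipeline stage failed: {stage}")
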