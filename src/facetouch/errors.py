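"""Exception hierarchy for the face-touch recognition pipeline.

Every stage raises a subclass of :class:`FaceTouchError` so callers (and the
CLI) can catch pipeline failures distinctly from programming errors.
"""


class FaceTouchError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(FaceTouchError):
    """Invalid simulation or pipeline configuration."""


class ParseError(FaceTouchError):
    """A CSV row could not be parsed; message carries the line number."""


class DataError(FaceTouchError):
    """A recording violates a stream invariant (e.g. non-monotone time)."""


class RateMismatchError(DataError):
    """Inferred sampling rate deviates >1% from the configured rate."""


class EmptyRecordingError(DataError):
    """Recording file contains a header but no samples."""


class LabelError(FaceTouchError):
    """Unknown activity name in an annotation log."""


class AnnotationError(FaceTouchError):
    """Annotation intervals overlap or are otherwise inconsistent."""


class CoverageError(FaceTouchError):
    """An annotated interval is not fully covered by the recording."""


class DegenerateIntervalError(FaceTouchError):
    """Annotated interval shorter than trim_front + trim_back."""


class WindowTooShortError(FaceTouchError):
    """Feature extraction needs at least two samples per window."""


class EmptyMatrixError(FaceTouchError):
    """Windowing produced zero windows over all segments."""


class DesignError(FaceTouchError):
    """Cross-validation plan cannot be built for the given participants."""


class StratificationError(FaceTouchError):
    """An inner training split is missing a class."""


class UnsupportedFamilyError(FaceTouchError):
    """Operation requested for a model family that does not support it."""
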