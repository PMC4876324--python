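"""Exception hierarchy.

Every stage raises a subclass of :class:`HistoscreenError` so pipeline code
can attach the stage name when propagating.
"""


class HistoscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HistoscreenError):
    """Invalid configuration (simulation spec, network topology, splits)."""


class FormatError(HistoscreenError):
    """Unsupported image or file format."""


class AnnotationError(HistoscreenError):
    """Malformed polygon annotation."""


class GeometryError(HistoscreenError):
    """Raster geometry mismatch or out-of-bounds access."""


class SamplingError(HistoscreenError):
    """Patch sampling could not satisfy the request."""


class TrainingError(HistoscreenError):
    """Numerical failure during network training."""


class ConversionError(HistoscreenError):
    """Patch network cannot be converted to a fully convolutional one."""


class ScoringError(HistoscreenError):
    """Slide-level scoring failure (e.g. empty tissue mask)."""


class EvaluationError(HistoscreenError):
    """Undefined metric (e.g. single-class ROC, empty Dice)."""
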