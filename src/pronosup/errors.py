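"""Typed exceptions raised across the pipeline.

Every validation failure raises one of these; malformed input is never
silently passed through.
"""


class PronosupError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PronosupError):
    """A file does not conform to the expected layout (missing column, bad header)."""


class RangeError(PronosupError):
    """A channel value exceeds the sensor's physical measuring range."""


class ValidationError(PronosupError):
    """A domain object violates one of its invariants."""


class ParameterError(PronosupError):
    """An operation was configured with out-of-contract parameters."""


class InputError(PronosupError):
    """An input sequence is unusable (too short, misaligned, non-overlapping)."""


class SegmentationError(PronosupError):
    """The seven-phase state machine could not locate a valid task execution.

    Carries diagnostic envelope data so the failure can be inspected.
    """

    def __init__(self, message, *, envelope=None, threshold=None):
        super().__init__(message)
        self.envelope = envelope
        self.threshold = threshold


class OscillationError(PronosupError):
    """Too few zero crossings / oscillations to form pair segments."""


class FeatureError(PronosupError):
    """A recording does not support computation of the feature set."""


class SelectionError(PronosupError):
    """Feature subset search cannot run (single class, no candidates)."""


class PredictionError(PronosupError):
    """A feature required by the decision tree is missing from the input vector."""


class ModelIOError(PronosupError):
    """A serialized model could not be loaded (truncated, wrong version)."""


class GenerationError(PronosupError):
    """Synthesis parameters would exceed the physical sensor ranges."""
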