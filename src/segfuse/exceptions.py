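"""Exception hierarchy for segfuse."""


class SegfuseError(Exception):
    """Base class for all segfuse errors."""


class FormatError(SegfuseError):
    """Unreadable or inconsistent on-disk image data."""


class CohortError(SegfuseError):
    """Subject-level inconsistency (e.g. modality shape mismatch)."""


class PreprocessingError(SegfuseError):
    """Invalid input to a preprocessing operation."""


class LabelError(SegfuseError):
    """Label values outside the declared label space."""


class ConfigError(SegfuseError):
    """Invalid configuration."""


class QuantizationError(SegfuseError):
    """Invalid gray-level quantization parameters."""


class TrainingError(SegfuseError):
    """Invalid training inputs (label space mismatch, single-class labels, ...)."""


class InferenceError(SegfuseError):
    """Model/input mismatch at prediction time."""


class MaskingError(SegfuseError):
    """Shape mismatch when applying an ROI mask."""


class FusionError(SegfuseError):
    """Feature assembly / reconstruction inconsistency."""


class SelectionError(SegfuseError):
    """Model selection on an empty or invalid evaluation split."""


class EvaluationError(SegfuseError):
    """Invalid evaluation inputs."""
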