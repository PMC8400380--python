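"""Exception hierarchy for the k-space splicing pipeline."""


class KSpaceError(Exception):
    """Base class for all package errors."""


class InvalidSizeError(KSpaceError):
    """Matrix or region size violates the line-group machinery (M < 12 or M % 4 != 0)."""


class ShapeError(KSpaceError):
    """Array is not a 2-D complex k-space matrix, or shapes of a pair disagree."""


class MetadataError(KSpaceError):
    """Required acquisition metadata (e.g. the receiving-gain label) is missing."""


class DegenerateDataError(KSpaceError):
    """All sample pairs of a line group were excluded, or a background has zero spread."""


class ClippingError(KSpaceError):
    """ADC-clipped samples fall inside a k-space region the splice would use."""


class ConfigError(KSpaceError):
    """Pipeline configuration failed schema validation."""


class PipelineError(KSpaceError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
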