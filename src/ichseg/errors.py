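"""Exception hierarchy shared across the pipeline stages."""


class IchsegError(Exception):
    """Base class for all package errors."""


class ValidationError(IchsegError, ValueError):
    """Input violates a documented precondition."""


class SeriesReadError(IchsegError, IOError):
    """A CT series could not be read (missing/corrupt files)."""


class InconsistentSeriesError(ValidationError):
    """Slices of a series disagree on geometry beyond tolerance."""


class NoHyperdenseSeedError(IchsegError):
    """Automatic seeding found no candidate above the hyperdensity floor.

    Under default settings this usually signals the absence of an acute
    hemorrhage rather than a failure of the watershed stage.
    """


class EmptySegmentationError(IchsegError):
    """Region growing produced an empty mask."""


class DegenerateHistogramError(IchsegError):
    """Otsu thresholding received a single-intensity sample."""


class StageError(IchsegError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
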