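"""Exception hierarchy for the dietfreq pipeline."""


class DietFreqError(Exception):
    """Base class for all package errors."""


class InvalidSpecificationError(DietFreqError):
    """A phantom/recording specification violates its physical constraints
    (non-positive volume, Nyquist violation, empty frequency list, ...)."""


class DegenerateGeometryError(DietFreqError):
    """A point cloud cannot support the 4x4 segmentation (e.g. fewer than
    four distinct heights)."""


class NoUsableRunsError(DietFreqError):
    """Every input-frequency run was rejected by the segment-irregularity
    rule; carries per-run diagnostics."""

    def __init__(self, message: str, fractions=None):
        super().__init__(message)
        self.fractions = dict(fractions or {})


class IndeterminateBreastError(DietFreqError):
    """All control segments are missing for a breast, so the tolerance
    criterion can be neither positive nor negative."""


class BundleFormatError(DietFreqError):
    """A recording bundle on disk is missing files/keys or is internally
    inconsistent."""


class FitError(DietFreqError):
    """The ROC curve fit is ill-posed (e.g. all points at the origin)."""


class PipelineStageError(DietFreqError):
    """A pipeline stage failed; wraps the original error with a stage tag."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
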