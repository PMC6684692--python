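"""Exception hierarchy for the nac3d pipeline.

Every stage failure maps to a distinct exception so the pipeline driver can
record *where* a case failed (nipple segmentation, lesion detection, ...)
the same way a clinical cohort accounts for its exclusions.
"""


class Nac3dError(Exception):
    """Base class for all package errors."""


class FormatError(Nac3dError):
    """A file could not be parsed (missing/corrupt header field)."""


class GeometryError(Nac3dError):
    """Inconsistent voxel geometry (e.g. non-uniform slice spacing)."""


class OrientationError(Nac3dError):
    """Orientation metadata is missing, ambiguous or not axis-aligned."""


class PhantomSpecError(Nac3dError):
    """Phantom specification violates its own invariants."""


class SegmentationFailureError(Nac3dError):
    """A segmentation stage produced no usable output.

    Carries the QC flags that triggered the refusal.
    """

    def __init__(self, message, qc_flags=frozenset()):
        super().__init__(message)
        self.qc_flags = frozenset(qc_flags)


class DegenerateSeedError(SegmentationFailureError):
    """Region-growing seed has zero intensity; the relative tolerance is undefined."""


class DegenerateCurveError(SegmentationFailureError):
    """Too few NAC base boundary points to fit a cubic B-spline."""


class LesionDetectionError(Nac3dError):
    """No enhancing lesion candidate survived (the per-lesion miss case)."""


class DegenerateCohortError(Nac3dError):
    """Cohort lacks involved or uninvolved patients; ROC is undefined."""
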