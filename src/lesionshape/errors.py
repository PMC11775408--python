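"""Exception hierarchy for lesion morphometry.

Hard errors are preferred over silent clamping: a marker outside its
mathematically admissible range (beyond a small discretization slack)
signals a bug or an unusable input, never a value to be repaired.
"""


class LesionShapeError(Exception):
    """Base class for all package errors."""


class DimensionalityError(LesionShapeError):
    """Input image is not a 3D volume."""


class EmptyMaskError(LesionShapeError):
    """Mask contains no foreground voxels — nothing to measure."""


class GeometryError(LesionShapeError):
    """Invalid geometry metadata (e.g. non-invertible affine)."""


class DegenerateResampleError(LesionShapeError):
    """Target spacing is too coarse for the foreground extent."""


class AnisotropicGridError(LesionShapeError):
    """Operation requires an isotropic voxel grid; resample first."""


class DegenerateHullError(LesionShapeError):
    """Vertex set is degenerate (coplanar/collinear); no 3D hull exists."""


class InsufficientScalesError(LesionShapeError):
    """Too few dyadic box sizes for a box-counting fit (< 4 scales)."""


class MarkerDomainError(LesionShapeError):
    """Marker inputs outside their admissible domain."""


class InconsistentMarkersError(LesionShapeError):
    """Internally inconsistent marker values beyond discretization slack."""


class DegenerateDifferencesError(LesionShapeError):
    """All paired differences are zero — no evidence either way."""


class StatsDomainError(LesionShapeError):
    """Invalid input to a statistical routine (empty, too few pairs...)."""


class SyntheticSpecError(LesionShapeError):
    """Invalid synthetic lesion / acquisition specification."""


class CohortError(LesionShapeError):
    """Invalid cohort manifest or marker table."""
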