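"""Exception hierarchy shared across the pipeline.

Errors are split by *stage semantics* so the CLI can map them onto exit
codes: input/format problems versus geometric contract violations versus
method-level failures (thin segmentations, infeasible sphere placements,
undefined deltas).
"""


class LafqError(Exception):
    """Base class for all package errors."""


class FormatError(LafqError):
    """Unsupported or unrecognized file format."""


class VolumeParseError(LafqError):
    """A file of a supported format could not be parsed."""


class GridMismatchError(LafqError):
    """Two grid-bound objects do not share the same voxel grid."""


class GeometryError(LafqError):
    """Physical-space geometry violation (e.g. non-overlapping extents)."""


class ThinSegmentationError(LafqError):
    """Erosion emptied the segmentation; the wall radius is too large."""


class SpherePlacementError(LafqError):
    """Blood-pool sampling sphere does not fit where requested."""


class BloodPoolTooSmallError(SpherePlacementError):
    """No inscribed sphere of the requested diameter exists.

    Carries ``max_feasible_diameter_mm`` so callers can retry.
    """

    def __init__(self, requested_mm: float, max_feasible_mm: float):
        self.requested_diameter_mm = float(requested_mm)
        self.max_feasible_diameter_mm = float(max_feasible_mm)
        super().__init__(
            f"blood pool too small for a {requested_mm:g} mm sphere; "
            f"maximum feasible diameter is {max_feasible_mm:.2f} mm"
        )


class DiskPlacementError(LafqError):
    """Ostial disk does not intersect the atrial wall."""


class UndefinedDeltaError(LafqError):
    """A longitudinal delta is undefined (zero baseline)."""


class PhantomSpecError(LafqError):
    """Invalid synthetic-phantom specification."""


class StatisticsError(LafqError):
    """Invalid input to the outcome-statistics layer."""


class SeparationError(StatisticsError):
    """Perfect separation detected in a logistic model."""
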