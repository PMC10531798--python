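"""Cross-sequence rigid/affine registration (LGE fixed, angio moving).

The angiographic volume carries the anatomy and its LA+PV segmentation;
the LGE volume carries the enhancement signal.  Registration aligns the
two so the segmentation can be propagated into LGE space, using
multi-resolution Mattes mutual information — the standard robust choice
for multimodal MRI.  Metric sampling uses SimpleITK's REGULAR strategy,
which is deterministic by construction, so repeated runs give identical
transforms.

Transform convention (ITK): ``T(p) = matrix @ (p - center) + center +
translation`` in physical mm, and the registered transform maps *fixed*
(LGE) physical points into *moving* (angio) physical space — the
direction needed to resample moving data onto the fixed grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import GeometryError
from .image_model import LabelMask, Volume3D

__all__ = [
    "SpatialTransform",
    "RegistrationReport",
    "RegistrationSettings",
    "register",
    "apply_transform",
    "resample_volume",
    "dice",
]


@dataclass
class SpatialTransform:
    """Rigid or affine map of physical (mm) points."""

    kind: str  # "rigid" | "affine"
    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if self.kind not in ("rigid", "affine"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.kind == "rigid":
            if abs(np.linalg.det(self.matrix) - 1.0) > 1e-6 or not np.allclose(
                self.matrix @ self.matrix.T, np.eye(3), atol=1e-6
            ):
                raise ValueError("rigid transform requires an orthonormal "
                                 "matrix with det = +1")

    # -- algebra ----------------------------------------------------------
    @classmethod
    def identity(cls, kind: str = "rigid") -> "SpatialTransform":
        return cls(kind, np.eye(3), np.zeros(3))

    def map_points(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - self.center) @ self.matrix.T + self.center + self.translation

    def as_homogeneous(self) -> np.ndarray:
        H = np.eye(4)
        H[:3, :3] = self.matrix
        H[:3, 3] = self.translation + self.center - self.matrix @ self.center
        return H

    @classmethod
    def from_homogeneous(cls, H, kind: str = "affine") -> "SpatialTransform":
        H = np.asarray(H, dtype=float).reshape(4, 4)
        return cls(kind, H[:3, :3], H[:3, 3])

    def compose(self, other: "SpatialTransform") -> "SpatialTransform":
        """``self ∘ other`` (apply ``other`` first)."""
        H = self.as_homogeneous() @ other.as_homogeneous()
        kind = "rigid" if self.kind == other.kind == "rigid" else "affine"
        return SpatialTransform.from_homogeneous(H, kind)

    def invert(self) -> "SpatialTransform":
        H = np.linalg.inv(self.as_homogeneous())
        return SpatialTransform.from_homogeneous(H, self.kind)

    # -- SimpleITK bridge -------------------------------------------------
    def to_sitk(self) -> sitk.Transform:
        t = sitk.AffineTransform(3)
        t.SetMatrix(tuple(self.matrix.flatten()))
        t.SetCenter(tuple(self.center))
        t.SetTranslation(tuple(self.translation))
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Transform, kind: str) -> "SpatialTransform":
        if not hasattr(t, "GetMatrix"):
            t = t.Downcast()
        matrix = np.asarray(t.GetMatrix(), dtype=float).reshape(3, 3)
        if kind == "rigid":
            # re-orthonormalize against optimizer round-off
            u, _, vt = np.linalg.svd(matrix)
            matrix = u @ vt
        return cls(kind, matrix,
                   np.asarray(t.GetTranslation(), dtype=float),
                   np.asarray(t.GetCenter(), dtype=float))

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Plain-text 4×4 homogeneous matrix (mm, LPS) + JSON sidecar."""
        H = self.as_homogeneous()
        np.savetxt(path, H, fmt="%.12g")
        with open(str(path) + ".json", "w") as fh:
            json.dump({"kind": self.kind, "units": "mm", "frame": "LPS",
                       "convention": "maps fixed physical points to moving"},
                      fh, indent=2)

    @classmethod
    def load(cls, path) -> "SpatialTransform":
        H = np.loadtxt(path).reshape(4, 4)
        kind = "affine"
        try:
            with open(str(path) + ".json") as fh:
                kind = json.load(fh).get("kind", "affine")
        except FileNotFoundError:
            pass
        t = cls.from_homogeneous(H, "affine")
        if kind == "rigid":
            u, _, vt = np.linalg.svd(t.matrix)
            t = cls("rigid", u @ vt, t.translation, t.center)
        return t


@dataclass
class RegistrationReport:
    final_metric: float
    iterations_per_level: list
    converged: bool
    stop_condition: str = ""


@dataclass
class RegistrationSettings:
    """Knobs for the mutual-information optimization."""

    shrink_factors: tuple = (4, 2, 1)
    smoothing_sigmas: tuple = (2.0, 1.0, 0.0)
    histogram_bins: int = 32
    sampling_fraction: float = 0.25
    max_iterations: int = 300
    learning_rate: float = 1.0
    min_step: float = 1e-4
    seed: int = 0  # kept for interface stability; REGULAR sampling is deterministic


def _physical_bounds(v: Volume3D) -> tuple:
    corners = np.array([[i, j, k] for i in (0, v.shape[0]) for j in (0, v.shape[1])
                        for k in (0, v.shape[2])], dtype=float) - 0.5
    pts = v.index_to_physical(corners)
    return pts.min(axis=0), pts.max(axis=0)


def _check_overlap(fixed: Volume3D, moving: Volume3D) -> None:
    lo_f, hi_f = _physical_bounds(fixed)
    lo_m, hi_m = _physical_bounds(moving)
    if np.any(hi_f < lo_m) or np.any(hi_m < lo_f):
        raise GeometryError("fixed and moving volumes have no overlapping "
                            "physical extent")


def register(fixed: Volume3D, moving: Volume3D, mode: str = "rigid",
             settings: RegistrationSettings | None = None
             ) -> tuple[SpatialTransform, RegistrationReport]:
    """Align ``moving`` onto ``fixed`` by Mattes mutual information.

    Rigid initialization is by center-of-mass (moments) alignment;
    ``mode="affine"`` refines the rigid result with a full affine model.
    Returns the transform (fixed → moving physical space) and a report.
    Non-convergence is flagged in the report, not raised.
    """
    if mode not in ("rigid", "affine"):
        raise ValueError(f"mode must be 'rigid' or 'affine', got {mode!r}")
    if fixed.voxels.size == 0 or moving.voxels.size == 0:
        raise GeometryError("cannot register empty volumes")
    _check_overlap(fixed, moving)
    settings = settings or RegistrationSettings()

    f = sitk.Cast(fixed.to_sitk(), sitk.sitkFloat32)
    m = sitk.Cast(moving.to_sitk(), sitk.sitkFloat32)

    initial = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.MOMENTS)

    rigid_tx, report = _run(f, m, sitk.Euler3DTransform(initial), settings)
    result = SpatialTransform.from_sitk(rigid_tx, "rigid")
    if mode == "affine":
        aff = sitk.AffineTransform(3)
        aff.SetMatrix(tuple(result.matrix.flatten()))
        aff.SetTranslation(tuple(result.translation))
        aff.SetCenter(tuple(result.center))
        aff_tx, report = _run(f, m, aff, settings)
        result = SpatialTransform.from_sitk(aff_tx, "affine")
    return result, report


def _run(fixed, moving, transform, s: RegistrationSettings):
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=s.histogram_bins)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(s.sampling_fraction, int(s.seed) or 1)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=s.learning_rate, minStep=s.min_step,
        numberOfIterations=s.max_iterations, relaxationFactor=0.6)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(s.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(s.smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(transform, inPlace=True)

    iters = []
    reg.AddCommand(sitk.sitkMultiResolutionIterationEvent,
                   lambda: iters.append(0))
    reg.AddCommand(sitk.sitkIterationEvent,
                   lambda: iters.__setitem__(-1, iters[-1] + 1))

    out = reg.Execute(fixed, moving)
    stop = reg.GetOptimizerStopConditionDescription()
    converged = "MaximumNumberOfIterations" not in stop.replace(" ", "")
    report = RegistrationReport(
        final_metric=float(reg.GetMetricValue()),
        iterations_per_level=[max(i, 1) for i in iters] or [1],
        converged=bool(converged),
        stop_condition=stop,
    )
    return out, report


def apply_transform(mask: LabelMask, t: SpatialTransform,
                    reference: Volume3D) -> LabelMask:
    """Resample a mask onto ``reference``'s grid (nearest-neighbor)."""
    img = mask.to_sitk()
    out = sitk.Resample(img, reference.to_sitk(), t.to_sitk(),
                        sitk.sitkNearestNeighbor, 0.0, img.GetPixelID())
    res = LabelMask.from_sitk(out)
    # resampling through sitk preserves the reference grid; re-attach the
    # reference metadata verbatim to avoid 1e-12 float drift
    return LabelMask(res.voxels, reference.spacing.copy(),
                     reference.origin.copy(), reference.direction.copy())


def resample_volume(v: Volume3D, t: SpatialTransform,
                    reference: Volume3D) -> Volume3D:
    """Resample a gray-level volume onto ``reference`` (linear interp)."""
    out = sitk.Resample(sitk.Cast(v.to_sitk(), sitk.sitkFloat64),
                        reference.to_sitk(), t.to_sitk(),
                        sitk.sitkLinear, 0.0, sitk.sitkFloat64)
    res = Volume3D.from_sitk(out)
    return Volume3D(res.voxels, reference.spacing.copy(),
                    reference.origin.copy(), reference.direction.copy())


def dice(a: LabelMask, b: LabelMask) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a.require_same_grid(b, "dice operand")
    na, nb = a.cardinality, b.cardinality
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    return 2.0 * inter / (na + nb)
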