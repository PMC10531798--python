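"""Volumetric data model, medical-image I/O, masking and point-cloud export.

The in-memory containers are thin, validated wrappers around NumPy arrays
with explicit physical-space metadata (mm units, LPS axes).  The voxel
array of a :class:`Volume3D` is indexed ``[i, j, k]`` where axis ``i``
maps to the first column of ``direction`` and so on; a voxel's physical
position is its **center**, located at continuous index ``index + 0.5``:

    x_phys = origin + direction @ (spacing * (index + 0.5))

so ``origin`` is the corner of voxel (0, 0, 0).  File I/O goes through
SimpleITK (NIfTI and MetaImage); the half-voxel offset between this
corner-origin convention and ITK's center-origin convention is applied on
the way in and out, so metadata round-trips exactly.

Masked enhancement data can be exported as a point cloud in VTK XML
PolyData (``.vtp``) with the gray level attached as a point scalar, for
downstream mesh/visualization tools.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, GridMismatchError, VolumeParseError

__all__ = [
    "Volume3D",
    "LabelMask",
    "MaskedSurfaceExport",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "mask_volume",
    "export_masked_surface",
    "read_vtp",
]

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha", ".mhd")

GRID_TOL = 1e-6  # mm / dimensionless tolerance for grid metadata equality


def _as_float3(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(3)
    return a


def _check_direction(direction: np.ndarray) -> None:
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise ValueError("direction must be a 3x3 matrix")
    if abs(abs(np.linalg.det(d)) - 1.0) > 1e-6:
        raise ValueError("direction matrix must have |det| = 1")
    if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
        raise ValueError("direction matrix must be orthonormal")


@dataclass
class _Grid:
    """Shared grid plumbing for volumes and masks."""

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing = _as_float3(self.spacing)
        self.origin = _as_float3(self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive on all axes")
        _check_direction(self.direction)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, index) -> np.ndarray:
        """Physical center (mm) of voxel ``index``; accepts (..., 3) arrays."""
        idx = np.asarray(index, dtype=float)
        cont = (idx + 0.5) * self.spacing
        return cont @ self.direction.T + self.origin

    def voxel_centers(self, indices=None) -> np.ndarray:
        """Physical centers of all voxels (or of the given (N,3) indices)."""
        if indices is None:
            indices = np.stack(
                np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"),
                axis=-1,
            ).reshape(-1, 3)
        return self.index_to_physical(indices)

    def same_grid(self, other, tol: float = GRID_TOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def require_same_grid(self, other, what: str = "operand") -> None:
        if self.shape != other.shape:
            raise GridMismatchError(f"{what}: shape {other.shape} != {self.shape}")
        for name in ("spacing", "origin", "direction"):
            if not np.allclose(getattr(self, name), getattr(other, name), atol=GRID_TOL):
                raise GridMismatchError(
                    f"{what}: {name} mismatch ({getattr(other, name)!r} vs "
                    f"{getattr(self, name)!r})"
                )

    # -- SimpleITK bridge --------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        vox = self.voxels.astype(np.uint8) if self.voxels.dtype == bool else self.voxels
        arr = np.ascontiguousarray(np.transpose(vox, (2, 1, 0)))
        img = sitk.GetImageFromArray(arr)
        img.SetSpacing(tuple(self.spacing))
        # ITK origin is the *center* of voxel 0 → shift by half a voxel
        center0 = self.index_to_physical([0, 0, 0])
        img.SetOrigin(tuple(center0))
        img.SetDirection(tuple(self.direction.flatten()))
        return img


class Volume3D(_Grid):
    """A scalar 3D image with physical-space (mm, LPS) metadata."""

    def with_voxels(self, voxels: np.ndarray) -> "Volume3D":
        """Same grid, new voxel data."""
        return Volume3D(voxels, self.spacing.copy(), self.origin.copy(),
                        self.direction.copy())

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume3D":
        return cls(**_grid_kwargs_from_sitk(img))


class LabelMask(_Grid):
    """A binary mask sharing the :class:`Volume3D` grid contract."""

    def __post_init__(self):
        super().__post_init__()
        vox = self.voxels
        if vox.dtype != bool:
            uniq = np.unique(vox)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be in {0, 1}")
            self.voxels = vox.astype(bool)

    @property
    def cardinality(self) -> int:
        return int(np.count_nonzero(self.voxels))

    @property
    def volume_mm3(self) -> float:
        return self.cardinality * self.voxel_volume_mm3

    def with_voxels(self, voxels: np.ndarray) -> "LabelMask":
        return LabelMask(voxels, self.spacing.copy(), self.origin.copy(),
                         self.direction.copy())

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "LabelMask":
        kw = _grid_kwargs_from_sitk(img)
        kw["voxels"] = kw["voxels"] > 0
        return cls(**kw)


def _grid_kwargs_from_sitk(img: sitk.Image) -> dict:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    voxels = np.transpose(arr, (2, 1, 0))
    spacing = _as_float3(img.GetSpacing())
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    center0 = _as_float3(img.GetOrigin())
    origin = center0 - direction @ (0.5 * spacing)
    return dict(voxels=voxels, spacing=spacing, origin=origin, direction=direction)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _check_format(path: str) -> None:
    p = str(path)
    if not p.endswith(_SUPPORTED_EXT):
        raise FormatError(
            f"unsupported image format for {p!r}; expected one of {_SUPPORTED_EXT}"
        )


def read_volume(path) -> Volume3D:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) scalar volume."""
    _check_format(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises RuntimeError with ITK detail
        raise VolumeParseError(f"could not parse {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeParseError(f"{path!r}: expected 3 dimensions, got {img.GetDimension()}")
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise VolumeParseError(f"{path!r}: expected scalar voxels")
    return Volume3D.from_sitk(img)


def write_volume(v: Volume3D, path) -> None:
    """Write a volume; format chosen by extension (NIfTI or MetaImage)."""
    _check_format(path)
    sitk.WriteImage(v.to_sitk(), str(path))


def read_mask(path) -> LabelMask:
    """Read a binary label mask (any nonzero voxel becomes foreground)."""
    v = read_volume(path)
    return LabelMask(v.voxels > 0, v.spacing, v.origin, v.direction)


def write_mask(m: LabelMask, path) -> None:
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(m.voxels.astype(np.uint8), (2, 1, 0))))
    img.CopyInformation(m.to_sitk())
    _check_format(path)
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

BACKGROUND = np.nan
"""Sentinel for voxels outside a mask.

NaN rather than 0 because 0 is a legal gray level; NaN voxels are excluded
from every downstream statistic by construction.
"""


def mask_volume(v: Volume3D, m: LabelMask) -> Volume3D:
    """Keep ``v``'s voxels where ``m`` is set; background sentinel elsewhere."""
    v.require_same_grid(m, "mask")
    out = np.full(v.shape, BACKGROUND, dtype=float)
    out[m.voxels] = v.voxels[m.voxels]
    return v.with_voxels(out)


def foreground_values(masked: Volume3D) -> np.ndarray:
    """Gray levels of a masked volume, background sentinel excluded."""
    vox = np.asarray(masked.voxels, dtype=float)
    return vox[~np.isnan(vox)]


# ---------------------------------------------------------------------------
# VTK XML PolyData export
# ---------------------------------------------------------------------------

@dataclass
class MaskedSurfaceExport:
    """Point cloud of masked voxel centers with gray-level scalars."""

    points: np.ndarray  # (N, 3) mm
    scalars: np.ndarray  # (N,)
    provenance: dict

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.scalars = np.asarray(self.scalars, dtype=float).reshape(-1)
        if len(self.points) != len(self.scalars):
            raise ValueError("points and scalars must have equal length")


def export_masked_surface(v: Volume3D, m: LabelMask, path) -> MaskedSurfaceExport:
    """Export one point per nonzero mask voxel (at its physical center).

    The gray level of the source volume is attached as the point scalar
    and the file is written as ASCII VTK XML PolyData (``.vtp``).  An
    empty mask yields a valid empty file (with a warning).
    """
    import warnings

    v.require_same_grid(m, "mask")
    idx = np.argwhere(m.voxels)
    points = v.index_to_physical(idx) if len(idx) else np.empty((0, 3))
    scalars = v.voxels[m.voxels].astype(float)
    if len(points) == 0:
        warnings.warn("export_masked_surface: empty mask, writing empty .vtp")
    export = MaskedSurfaceExport(points, scalars,
                                 provenance={"n_mask_voxels": int(len(points))})
    _write_vtp(export, path)
    return export


def _write_vtp(export: MaskedSurfaceExport, path) -> None:
    n = len(export.points)
    pts = " ".join(f"{c:.10g}" for c in export.points.reshape(-1))
    sca = " ".join(f"{s:.10g}" for s in export.scalars)
    conn = " ".join(str(i) for i in range(n))
    offs = " ".join(str(i + 1) for i in range(n))
    xml = f"""<?xml version="1.0"?>
<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">
  <PolyData>
    <Piece NumberOfPoints="{n}" NumberOfVerts="{n}" NumberOfLines="0" NumberOfStrips="0" NumberOfPolys="0">
      <PointData Scalars="gray_level">
        <DataArray type="Float64" Name="gray_level" format="ascii">{sca}</DataArray>
      </PointData>
      <Points>
        <DataArray type="Float64" NumberOfComponents="3" format="ascii">{pts}</DataArray>
      </Points>
      <Verts>
        <DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>
        <DataArray type="Int64" Name="offsets" format="ascii">{offs}</DataArray>
      </Verts>
    </Piece>
  </PolyData>
</VTKFile>
"""
    with open(path, "w") as fh:
        fh.write(xml)


def read_vtp(path) -> MaskedSurfaceExport:
    """Read back a point cloud written by :func:`export_masked_surface`."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise VolumeParseError(f"could not parse {path!r}: {exc}") from exc
    root = tree.getroot()
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise VolumeParseError(f"{path!r}: no PolyData piece")
    pts_el = piece.find("./Points/DataArray")
    pts = np.array((pts_el.text or "").split(), dtype=float).reshape(-1, 3)
    sc_el = piece.find("./PointData/DataArray")
    sca = (np.array((sc_el.text or "").split(), dtype=float)
           if sc_el is not None else np.zeros(len(pts)))
    return MaskedSurfaceExport(pts, sca, provenance={"source": str(path)})
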