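"""Blood-pool and atrial-wall extraction by spherical binary morphology.

Starting from the registered LA+PV segmentation, the blood pool is the
segmentation eroded by a Euclidean ball (default radius 3 voxels) and the
wall shell is the Boolean difference between the dilated and the eroded
segmentation — a band straddling the segmentation boundary that likely
contains the thin atrial wall.

The structuring element is the exact set of integer lattice offsets with
Euclidean norm ≤ radius; "3 pixels" is interpreted in index space
regardless of voxel anisotropy, matching the workflow this reproduces.
An anisotropy-aware physical-space ball (``radius_mm``) is available as
an opt-in alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ThinSegmentationError
from .image_model import LabelMask

__all__ = [
    "StructuringElement",
    "WallRegions",
    "spherical_element",
    "physical_element",
    "erode",
    "dilate",
    "extract_regions",
]


@dataclass
class StructuringElement:
    """Euclidean-ball structuring element as explicit lattice offsets."""

    radius_px: float
    offsets: np.ndarray  # (K, 3) int

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=int).reshape(-1, 3)

    @property
    def footprint(self) -> np.ndarray:
        """Dense boolean footprint array (odd side lengths, centered)."""
        r = np.max(np.abs(self.offsets), axis=0) if len(self.offsets) else np.zeros(3, int)
        fp = np.zeros(2 * r + 1, dtype=bool)
        fp[tuple((self.offsets + r).T)] = True
        return fp


def spherical_element(radius_px: int) -> StructuringElement:
    """All integer offsets with ``x² + y² + z² ≤ radius²``."""
    if radius_px < 1:
        raise ValueError("structuring-element radius must be ≥ 1")
    r = int(radius_px)
    grid = np.arange(-r, r + 1)
    X, Y, Z = np.meshgrid(grid, grid, grid, indexing="ij")
    keep = X**2 + Y**2 + Z**2 <= r * r
    offsets = np.stack([X[keep], Y[keep], Z[keep]], axis=1)
    return StructuringElement(radius_px=r, offsets=offsets)


def physical_element(radius_mm: float, spacing) -> StructuringElement:
    """Anisotropic ball: offsets with ``‖spacing ∘ offset‖ ≤ radius_mm``."""
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    spacing = np.asarray(spacing, dtype=float)
    r = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    axes = [np.arange(-ri, ri + 1) for ri in r]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    off = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    keep = np.linalg.norm(off * spacing, axis=1) <= radius_mm + 1e-9
    return StructuringElement(radius_px=float(radius_mm), offsets=off[keep])


def erode(m: LabelMask, e: StructuringElement) -> LabelMask:
    """Voxels where the whole element fits inside the mask (outside = 0)."""
    out = ndimage.binary_erosion(m.voxels, structure=e.footprint, border_value=0)
    return m.with_voxels(out)


def dilate(m: LabelMask, e: StructuringElement) -> LabelMask:
    """Voxels reached by the (symmetric) element from any mask voxel.

    Computed on an internally padded array so that structure overhang at
    the array border never truncates the result inside the grid.
    """
    pad = int(np.max(np.abs(e.offsets))) if len(e.offsets) else 0
    padded = np.pad(m.voxels, pad, mode="constant", constant_values=False)
    out = ndimage.binary_dilation(padded, structure=e.footprint, border_value=0)
    if pad:
        out = out[pad:-pad, pad:-pad, pad:-pad]
    return m.with_voxels(out)


@dataclass
class WallRegions:
    """Derived blood-pool mask and atrial-wall shell, with the radii used."""

    blood_pool: LabelMask
    wall: LabelMask
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.blood_pool.voxels & self.wall.voxels):
            raise ValueError("blood pool and wall must be disjoint")


def extract_regions(seg: LabelMask, radius_px: int = 3,
                    radius_mm: float | None = None) -> WallRegions:
    """Blood pool = erode(seg); wall = dilate(seg) minus blood pool.

    Parameters
    ----------
    seg : registered LA+PV segmentation in the LGE grid.
    radius_px : Euclidean-ball radius in voxels (default 3).
    radius_mm : if given, use a physical-space ball of this radius in mm
        instead of the voxel-space ball.
    """
    if seg.cardinality == 0:
        raise ValueError("segmentation is empty")
    if radius_mm is not None:
        elem = physical_element(radius_mm, seg.spacing)
        params = {"radius_mm": float(radius_mm)}
    else:
        elem = spherical_element(radius_px)
        params = {"radius_px": int(radius_px)}
    blood_pool = erode(seg, elem)
    if blood_pool.cardinality == 0:
        raise ThinSegmentationError(
            f"segmentation too thin: erosion by radius {params} emptied it; "
            "retry with a smaller radius"
        )
    dilated = dilate(seg, elem)
    wall = dilated.with_voxels(dilated.voxels & ~blood_pool.voxels)
    n_components = int(ndimage.label(wall.voxels)[1])
    params["wall_connected_components"] = n_components
    return WallRegions(blood_pool=blood_pool, wall=wall, params=params)
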