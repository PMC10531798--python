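"""Fibrosis threshold selection, wall/ostial volumetry and delta metrics.

The per-scan threshold separating fibrotic from healthy wall is the mean
gray level of a fixed-diameter sphere (default 10 mm) placed inside the
blood pool, plus a multiple (default 2) of its standard deviation.  The
fixed sphere standardizes the blood-pool sample and tolerates imperfect
segmentations.  Thresholds are computed independently for each scan —
baseline and follow-up are never shared.

Ostial fibrosis is measured inside thin disks (default 2 mm thick)
placed at each pulmonary-vein ostium, intersected with the wall shell.
Longitudinal change is summarized by the baseline-normalized change in
total wall fibrosis volume, the per-vein change in ostial fibrosis
fraction, and the count of veins whose ostial fibrosis *decreased* after
ablation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    BloodPoolTooSmallError,
    DiskPlacementError,
    SpherePlacementError,
    UndefinedDeltaError,
)
from .image_model import LabelMask, Volume3D

__all__ = [
    "VEINS",
    "ThresholdResult",
    "OstiumDisk",
    "FibrosisResult",
    "PatientMetrics",
    "auto_sphere_center",
    "compute_threshold",
    "quantify_wall_fibrosis",
    "rasterize_disk",
    "quantify_ostial_fibrosis",
    "delta_la_fibrosis",
    "delta_pv_fibrosis",
    "count_pvs_without_increase",
    "read_landmarks",
    "write_landmarks",
]

VEINS = ("LSPV", "LIPV", "RSPV", "RIPV")


# ---------------------------------------------------------------------------
# Threshold selection
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    """Blood-pool sample statistics and the derived fibrosis cutoff."""

    sample_mean: float
    sample_sd: float
    sd_multiplier: float
    threshold: float
    sphere_center: np.ndarray
    sphere_diameter_mm: float
    n_sample_voxels: int

    def __post_init__(self):
        self.sphere_center = np.asarray(self.sphere_center, dtype=float).reshape(3)
        expected = self.sample_mean + self.sd_multiplier * self.sample_sd
        if abs(self.threshold - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("threshold must equal mean + multiplier·SD")
        if self.n_sample_voxels < 10:
            raise ValueError("blood-pool sphere sample must contain ≥ 10 voxels")


def _sphere_indices(grid, center, radius_mm):
    """Indices of voxels whose centers lie within ``radius_mm`` of center."""
    center = np.asarray(center, dtype=float)
    # bounding box in continuous index space (axis-aligned grids and
    # rotated grids alike: map the 8 box corners conservatively)
    inv = np.linalg.inv(grid.direction)
    c_idx = inv @ (center - grid.origin) / grid.spacing - 0.5
    r_idx = radius_mm / grid.spacing
    lo = np.maximum(np.floor(c_idx - r_idx - 1).astype(int), 0)
    hi = np.minimum(np.ceil(c_idx + r_idx + 1).astype(int) + 1,
                    np.asarray(grid.shape))
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=int)
    axes = [np.arange(lo[a], hi[a]) for a in range(3)]
    I, J, K = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([I, J, K], axis=-1).reshape(-1, 3)
    pts = grid.index_to_physical(idx)
    keep = np.linalg.norm(pts - center, axis=1) <= radius_mm
    return idx[keep]


def auto_sphere_center(blood_pool: LabelMask, diameter_mm: float = 10.0
                       ) -> np.ndarray:
    """Deepest point of the blood pool (Euclidean distance-transform argmax).

    Returns the physical center (mm) of the best-embedded voxel; ties are
    broken deterministically by the lowest ``(z, y, x)`` index.  Raises
    :class:`BloodPoolTooSmallError` if no sphere of the requested diameter
    fits, reporting the maximum feasible diameter.
    """
    bp = blood_pool.voxels
    if not bp.any():
        raise BloodPoolTooSmallError(diameter_mm, 0.0)
    edt = ndimage.distance_transform_edt(bp, sampling=blood_pool.spacing)
    dmax = float(edt.max())
    if 2.0 * dmax <= diameter_mm:
        raise BloodPoolTooSmallError(diameter_mm, 2.0 * dmax)
    cand = np.argwhere(edt == dmax)
    order = np.lexsort((cand[:, 0], cand[:, 1], cand[:, 2]))  # sort by (z,y,x)
    best = cand[order[0]]
    return blood_pool.index_to_physical(best)


def compute_threshold(lge: Volume3D, blood_pool: LabelMask,
                      center=None, diameter_mm: float = 10.0,
                      sd_multiplier: float = 2.0) -> ThresholdResult:
    """Blood-pool sphere statistics → fibrosis threshold (mean + k·SD).

    ``center=None`` auto-places the sphere at the blood pool's deepest
    point.  The sphere must lie entirely inside the blood pool; partial
    placements raise rather than silently clip.  The SD uses the n−1
    (sample) convention.
    """
    lge.require_same_grid(blood_pool, "blood pool")
    if center is None or (isinstance(center, str) and center == "auto"):
        center = auto_sphere_center(blood_pool, diameter_mm)
    center = np.asarray(center, dtype=float).reshape(3)
    idx = _sphere_indices(lge, center, diameter_mm / 2.0)
    if len(idx) == 0:
        raise SpherePlacementError("sphere contains no voxel centers")
    inside = blood_pool.voxels[tuple(idx.T)]
    if not inside.all():
        raise SpherePlacementError(
            f"sphere at {np.round(center, 2)} extends outside the blood pool "
            f"({int((~inside).sum())}/{len(idx)} voxels)"
        )
    values = lge.voxels[tuple(idx.T)].astype(float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return ThresholdResult(
        sample_mean=mean, sample_sd=sd, sd_multiplier=float(sd_multiplier),
        threshold=mean + sd_multiplier * sd, sphere_center=center,
        sphere_diameter_mm=float(diameter_mm), n_sample_voxels=int(len(values)),
    )


# ---------------------------------------------------------------------------
# Regional volumetry
# ---------------------------------------------------------------------------

@dataclass
class FibrosisResult:
    """Fibrosis volume inside one region (whole wall or one PV ostium)."""

    region: str  # "whole-wall" or a vein id
    fibrosis_volume_mm3: float
    region_volume_mm3: float
    fibrosis_fraction: float
    threshold_used: float

    def __post_init__(self):
        if not (0.0 <= self.fibrosis_volume_mm3 <= self.region_volume_mm3 + 1e-9):
            raise ValueError("fibrosis volume must lie in [0, region volume]")
        if not (0.0 <= self.fibrosis_fraction <= 1.0 + 1e-12):
            raise ValueError("fibrosis fraction must lie in [0, 1]")


def _quantify(lge: Volume3D, region_mask: np.ndarray, threshold: float,
              region: str) -> FibrosisResult:
    vv = lge.voxel_volume_mm3
    values = lge.voxels[region_mask].astype(float)
    n_region = int(values.size)
    n_fib = int(np.count_nonzero(values > threshold))  # strict: the exact
    # blood-pool statistic itself is never counted as fibrosis
    return FibrosisResult(
        region=region,
        fibrosis_volume_mm3=n_fib * vv,
        region_volume_mm3=n_region * vv,
        fibrosis_fraction=(n_fib / n_region) if n_region else 0.0,
        threshold_used=float(threshold),
    )


def quantify_wall_fibrosis(lge: Volume3D, wall: LabelMask,
                           thr: ThresholdResult) -> FibrosisResult:
    """Fibrosis volume over the whole wall shell (LA + PVs)."""
    lge.require_same_grid(wall, "wall")
    if wall.cardinality == 0:
        raise ValueError("wall mask is empty")
    return _quantify(lge, wall.voxels, thr.threshold, "whole-wall")


@dataclass
class OstiumDisk:
    """A thin disk marking one PV ostium (center + axis normal, mm)."""

    vein: str
    center: np.ndarray
    normal: np.ndarray
    thickness_mm: float = 2.0
    radius_mm: float = 10.0

    def __post_init__(self):
        if self.vein not in VEINS:
            raise ValueError(f"vein must be one of {VEINS}, got {self.vein!r}")
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("disk normal must be nonzero")
        self.normal = n / nn
        if self.thickness_mm <= 0 or self.radius_mm <= 0:
            raise ValueError("disk thickness and radius must be positive")


def rasterize_disk(d: OstiumDisk, reference: Volume3D) -> LabelMask:
    """Voxels whose centers fall inside the disk slab ∩ radial cylinder."""
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in reference.shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    pts = reference.index_to_physical(idx)
    rel = pts - d.center
    axial = rel @ d.normal
    radial = np.linalg.norm(rel - np.outer(axial, d.normal), axis=1)
    keep = (np.abs(axial) <= d.thickness_mm / 2.0) & (radial <= d.radius_mm)
    vox = np.zeros(reference.shape, dtype=bool)
    vox[tuple(idx[keep].T)] = True
    return LabelMask(vox, reference.spacing.copy(), reference.origin.copy(),
                     reference.direction.copy())


def quantify_ostial_fibrosis(lge: Volume3D, wall: LabelMask, disk: OstiumDisk,
                             thr: ThresholdResult) -> FibrosisResult:
    """Fibrosis inside ``wall ∩ disk``, tagged with the vein id."""
    lge.require_same_grid(wall, "wall")
    disk_mask = rasterize_disk(disk, lge)
    region = wall.voxels & disk_mask.voxels
    if not region.any():
        raise DiskPlacementError(
            f"disk for {disk.vein} does not intersect the wall; "
            "verify the marker position"
        )
    return _quantify(lge, region, thr.threshold, disk.vein)


# ---------------------------------------------------------------------------
# Longitudinal deltas
# ---------------------------------------------------------------------------

def delta_la_fibrosis(pre: FibrosisResult, post: FibrosisResult) -> float:
    """(post − pre) / pre on total wall fibrosis volumes (dimensionless)."""
    if pre.fibrosis_volume_mm3 <= 0:
        raise UndefinedDeltaError(
            "baseline fibrosis volume is zero; normalized delta undefined")
    return (post.fibrosis_volume_mm3 - pre.fibrosis_volume_mm3) / pre.fibrosis_volume_mm3


def delta_pv_fibrosis(pre: FibrosisResult, post: FibrosisResult) -> float:
    """Change in ostial fibrosis fraction (volume-indexed) for one vein."""
    if pre.region_volume_mm3 <= 0 or post.region_volume_mm3 <= 0:
        raise UndefinedDeltaError("ostial region volume is zero")
    return post.fibrosis_fraction - pre.fibrosis_fraction


def count_pvs_without_increase(deltas) -> int:
    """Number of veins with a *strictly negative* ostial fibrosis delta."""
    deltas = list(deltas)
    if len(deltas) != len(VEINS):
        raise ValueError(f"expected {len(VEINS)} per-vein deltas, got {len(deltas)}")
    if any(d is None or not np.isfinite(d) for d in deltas):
        raise ValueError("missing per-vein delta")
    return int(sum(1 for d in deltas if d < 0))


@dataclass
class PatientMetrics:
    """Per-patient fibrosis metrics, with deltas when both timepoints exist."""

    patient_id: str
    la: dict = field(default_factory=dict)        # timepoint -> FibrosisResult
    per_vein: dict = field(default_factory=dict)  # timepoint -> {vein: FibrosisResult}
    delta_la: float | None = None
    delta_pv: dict | None = None                  # vein -> float
    n_pv_no_increase: int | None = None

    def compute_deltas(self) -> "PatientMetrics":
        """Fill the longitudinal fields once both timepoints are present."""
        if "baseline" in self.la and "day30" in self.la:
            self.delta_la = delta_la_fibrosis(self.la["baseline"], self.la["day30"])
            self.delta_pv = {
                vein: delta_pv_fibrosis(self.per_vein["baseline"][vein],
                                        self.per_vein["day30"][vein])
                for vein in VEINS
            }
            self.n_pv_no_increase = count_pvs_without_increase(
                [self.delta_pv[v] for v in VEINS])
        return self

    def to_rows(self) -> list:
        """Flat rows (one per timepoint-region) for the results CSV."""
        rows = []
        for tp, res in self.la.items():
            rows.append(self._row(tp, res))
        for tp, veins in self.per_vein.items():
            for vein in VEINS:
                if vein in veins:
                    rows.append(self._row(tp, veins[vein]))
        return rows

    def _row(self, timepoint: str, res: FibrosisResult) -> dict:
        return {
            "patient_id": self.patient_id,
            "timepoint": timepoint,
            "region": res.region,
            "fibrosis_volume_mm3": res.fibrosis_volume_mm3,
            "region_volume_mm3": res.region_volume_mm3,
            "fibrosis_fraction": res.fibrosis_fraction,
            "threshold_used": res.threshold_used,
        }

    def summary(self) -> dict:
        """Patient-level summary feeding the outcome-statistics layer."""
        out = {"patient_id": self.patient_id}
        if "baseline" in self.la:
            out["baseline_la_fibrosis"] = self.la["baseline"].fibrosis_fraction
        if self.delta_la is not None:
            out["delta_la"] = self.delta_la
            out["delta_pv_mean"] = float(np.mean([self.delta_pv[v] for v in VEINS]))
            out["n_pv_no_increase"] = self.n_pv_no_increase
            for v in VEINS:
                out[f"delta_pv_{v}"] = self.delta_pv[v]
        return out


# ---------------------------------------------------------------------------
# Landmark I/O
# ---------------------------------------------------------------------------

_CSV_FIELDS = ["vein", "center_x", "center_y", "center_z",
               "normal_x", "normal_y", "normal_z", "radius_mm", "thickness_mm"]


def read_landmarks(path) -> list:
    """Read PV ostium landmarks from JSON (list of objects) or CSV."""
    p = str(path)
    if p.endswith(".json"):
        with open(p) as fh:
            records = json.load(fh)
    else:
        with open(p, newline="") as fh:
            records = [
                {
                    "vein": row["vein"],
                    "center": [row["center_x"], row["center_y"], row["center_z"]],
                    "normal": [row["normal_x"], row["normal_y"], row["normal_z"]],
                    "radius_mm": row.get("radius_mm", 10.0),
                    "thickness_mm": row.get("thickness_mm", 2.0),
                }
                for row in csv.DictReader(fh)
            ]
    disks = [
        OstiumDisk(
            vein=r["vein"],
            center=np.asarray(r["center"], dtype=float),
            normal=np.asarray(r["normal"], dtype=float),
            radius_mm=float(r.get("radius_mm", 10.0)),
            thickness_mm=float(r.get("thickness_mm", 2.0)),
        )
        for r in records
    ]
    return disks


def write_landmarks(disks, path) -> None:
    p = str(path)
    if p.endswith(".json"):
        records = [
            {"vein": d.vein, "center": d.center.tolist(),
             "normal": d.normal.tolist(), "radius_mm": d.radius_mm,
             "thickness_mm": d.thickness_mm}
            for d in disks
        ]
        with open(p, "w") as fh:
            json.dump(records, fh, indent=2)
    else:
        with open(p, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
            w.writeheader()
            for d in disks:
                w.writerow({
                    "vein": d.vein,
                    "center_x": d.center[0], "center_y": d.center[1],
                    "center_z": d.center[2],
                    "normal_x": d.normal[0], "normal_y": d.normal[1],
                    "normal_z": d.normal[2],
                    "radius_mm": d.radius_mm, "thickness_mm": d.thickness_mm,
                })
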