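"""Synthetic atrial phantom: paired angio/LGE volumes with known truth.

The phantom is deliberately idealized — an ellipsoidal atrial shell with
four tubular pulmonary veins, ring-shaped ablation fibrosis at the vein
ostia and optional diffuse baseline patches — so that every ground-truth
quantity (masks, volumes, landmarks, the misalignment between the two
sequences) is computable in closed form and by exact voxel recount.

Geometry is built by analytic inside-tests at voxel centers; the angio
volume is rendered directly at misaligned sample points (no resampling
interpolation), so its truth segmentation is exact in angio space.  On
the LGE rendering, fibrotic wall is brighter than the blood-pool mean
plus twice the noise SD (enhancing scar retains gadolinium), healthy
wall is darker than blood; on the angio rendering blood is bright and
fibrosis is indistinguishable from healthy wall.

A cohort generator links recurrence to the true longitudinal deltas via
a logistic model with controllable strength, producing the clinical
table for the outcome-statistics layer.  Its default lightweight mode
uses analytic truth volumes (no voxel grids); ``volumes=True``
materializes full longitudinal image pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import PhantomSpecError
from .fibrosis_quant import VEINS, OstiumDisk
from .image_model import LabelMask, Volume3D
from .registration import SpatialTransform

__all__ = [
    "ClassIntensities",
    "VeinSpec",
    "PhantomSpec",
    "PhantomCase",
    "SyntheticCohort",
    "default_misalignment",
    "generate_phantom",
    "generate_longitudinal_pair",
    "generate_cohort",
    "analytic_ring_volume",
]


@dataclass
class ClassIntensities:
    """Per-tissue-class mean gray levels for one sequence."""

    background: float
    healthy_wall: float
    blood: float
    fibrotic_wall: float


@dataclass
class VeinSpec:
    """One tubular pulmonary vein attached to the atrial shell."""

    direction: np.ndarray        # unit vector, outward from the atrium center
    radius_mm: float = 6.0       # lumen radius
    length_mm: float = 16.0
    ring_coverage: float = 0.0   # angular fraction of the ostial fibrosis ring
    ring_axial_mm: float = 4.0
    ring_offset_mm: float = 1.0  # axial start of the ring, distal of the ostium

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float).reshape(3)
        self.direction = d / np.linalg.norm(d)
        if not (0.0 <= self.ring_coverage <= 1.0):
            raise PhantomSpecError("ring coverage must lie in [0, 1]")


def _default_veins() -> dict:
    dirs = {
        "LSPV": (2.0, 1.0, 1.0),
        "LIPV": (2.0, 1.0, -1.0),
        "RSPV": (-2.0, 1.0, 1.0),
        "RIPV": (-2.0, 1.0, -1.0),
    }
    return {v: VeinSpec(direction=np.asarray(d)) for v, d in dirs.items()}


def default_misalignment(center) -> SpatialTransform:
    """Rigid misalignment: 5° rotation about z plus (4, −2, 3) mm shift."""
    a = math.radians(5.0)
    R = np.array([[math.cos(a), -math.sin(a), 0.0],
                  [math.sin(a), math.cos(a), 0.0],
                  [0.0, 0.0, 1.0]])
    return SpatialTransform("rigid", R, np.array([4.0, -2.0, 3.0]),
                            center=np.asarray(center, dtype=float))


@dataclass
class PhantomSpec:
    """Full description of one synthetic case (geometry, signal, noise)."""

    shape: tuple = (96, 96, 96)
    spacing: tuple = (1.0, 1.0, 1.0)
    semiaxes_mm: tuple = (26.0, 22.0, 20.0)
    wall_thickness_mm: float = 3.0
    veins: dict = field(default_factory=_default_veins)
    diffuse_fibrosis_mm3: float = 0.0
    diffuse_patch_radius_mm: float = 8.0
    lge_intensity: ClassIntensities = field(
        default_factory=lambda: ClassIntensities(10.0, 60.0, 100.0, 170.0))
    angio_intensity: ClassIntensities = field(
        default_factory=lambda: ClassIntensities(10.0, 50.0, 200.0, 50.0))
    noise_sd: float = 10.0
    noise_model: str = "gaussian"  # "gaussian" | "rician"
    misalign: bool = True
    misalignment: SpatialTransform | None = None
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.wall_thickness_mm < 2.0 * max(self.spacing):
            raise PhantomSpecError("wall thickness must span at least 2 voxels")
        if self.noise_model not in ("gaussian", "rician"):
            raise PhantomSpecError(f"unknown noise model {self.noise_model!r}")
        for vein, vs in self.veins.items():
            if vs.ring_axial_mm <= 0 or vs.ring_axial_mm > vs.length_mm:
                raise PhantomSpecError(
                    f"{vein}: ring axial extent must lie in (0, vein length]")

    @property
    def center_mm(self) -> np.ndarray:
        return 0.5 * np.asarray(self.shape) * np.asarray(self.spacing)

    def true_misalignment(self) -> SpatialTransform:
        if not self.misalign:
            return SpatialTransform.identity()
        if self.misalignment is not None:
            return self.misalignment
        return default_misalignment(self.center_mm)


def analytic_ring_volume(vein: VeinSpec, wall_thickness_mm: float) -> float:
    """Closed-form ostial ring volume: coverage · π((r+w)² − r²) · axial."""
    r, w = vein.radius_mm, wall_thickness_mm
    return vein.ring_coverage * math.pi * ((r + w) ** 2 - r**2) * vein.ring_axial_mm


@dataclass
class PhantomCase:
    """One generated case with exhaustive ground truth."""

    lge: Volume3D
    angio: Volume3D
    truth_seg: LabelMask          # LA+PV blood segmentation, angio space
    truth_seg_fixed: LabelMask    # same segmentation in LGE space
    truth_wall: LabelMask         # true wall tissue, LGE space
    truth_fibrosis: LabelMask     # all fibrotic wall, LGE space
    truth_rings: dict             # vein -> LabelMask (LGE space)
    truth_volumes: dict           # region -> mm³ (exact voxel recounts)
    landmarks: list               # four OstiumDisk, LGE space
    true_transform: SpatialTransform  # fixed(LGE) → moving(angio) map
    misalignment: SpatialTransform    # moving(angio) → fixed(LGE) map
    spec: PhantomSpec = None


class _Scene:
    """Analytic tissue-class tests in fixed (LGE) physical space."""

    def __init__(self, spec: PhantomSpec, diffuse_centers):
        self.spec = spec
        self.center = spec.center_mm
        self.a = np.asarray(spec.semiaxes_mm, dtype=float)
        self.w = spec.wall_thickness_mm
        self.diffuse_centers = diffuse_centers  # list of (point, radius)
        self.ostia = {}
        for vein, vs in spec.veins.items():
            t = 1.0 / math.sqrt(float(np.sum((vs.direction / self.a) ** 2)))
            self.ostia[vein] = self.center + t * vs.direction

    def classify(self, pts: np.ndarray):
        """Labels (0 bg, 1 healthy, 2 blood, 3 fibrotic) + per-vein rings."""
        spec, w = self.spec, self.w
        rel = pts - self.center
        inside_la = np.sum((rel / self.a) ** 2, axis=1) <= 1.0
        outer_la = np.sum((rel / (self.a + w)) ** 2, axis=1) <= 1.0

        blood = inside_la.copy()
        wallish = outer_la & ~inside_la
        rings = {}
        ring_geom = {}
        for vein, vs in spec.veins.items():
            d = vs.direction
            q = pts - self.ostia[vein]
            s = q @ d
            radial = np.linalg.norm(q - np.outer(s, d), axis=1)
            lumen = (s >= -w - 1.0) & (s <= vs.length_mm) & (radial <= vs.radius_mm)
            vwall = ((s >= -w) & (s <= vs.length_mm)
                     & (radial > vs.radius_mm) & (radial <= vs.radius_mm + w))
            blood |= lumen
            wallish |= vwall
            ring_geom[vein] = (vwall, s, q, d)

        wall = wallish & ~blood
        fib = np.zeros(len(pts), dtype=bool)
        for vein, vs in spec.veins.items():
            vwall, s, q, d = ring_geom[vein]
            ring = np.zeros(len(pts), dtype=bool)
            if vs.ring_coverage > 0:
                u = np.cross(d, [0.0, 0.0, 1.0] if abs(d[2]) < 0.9 else [1.0, 0.0, 0.0])
                u /= np.linalg.norm(u)
                v = np.cross(d, u)
                theta = np.mod(np.arctan2(q @ v, q @ u), 2.0 * math.pi)
                in_axial = (s >= vs.ring_offset_mm) & (s <= vs.ring_offset_mm + vs.ring_axial_mm)
                ring = (vwall & wall & in_axial
                        & (theta <= vs.ring_coverage * 2.0 * math.pi + 1e-12))
            rings[vein] = ring
            fib |= ring
        for c, r in self.diffuse_centers:
            fib |= wall & (np.linalg.norm(pts - c, axis=1) <= r)
        fib &= wall

        labels = np.zeros(len(pts), dtype=np.uint8)
        labels[wall] = 1
        labels[blood] = 2
        labels[fib] = 3
        return labels, blood, wall, fib, rings


def _render(labels: np.ndarray, intensity: ClassIntensities, noise_sd: float,
            noise_model: str, rng: np.random.Generator) -> np.ndarray:
    means = np.array([intensity.background, intensity.healthy_wall,
                      intensity.blood, intensity.fibrotic_wall])
    signal = means[labels]
    if noise_sd <= 0:
        return signal
    if noise_model == "rician":
        n1 = rng.normal(0.0, noise_sd, size=signal.shape)
        n2 = rng.normal(0.0, noise_sd, size=signal.shape)
        return np.sqrt((signal + n1) ** 2 + n2**2)
    return signal + rng.normal(0.0, noise_sd, size=signal.shape)


def _diffuse_centers(spec: PhantomSpec, rng: np.random.Generator,
                     voxel_volume: float) -> list:
    """Place wall patches until the analytic budget is met (deterministic)."""
    if spec.diffuse_fibrosis_mm3 <= 0:
        return []
    a = np.asarray(spec.semiaxes_mm, dtype=float)
    centers = []
    # rough per-patch volume: half-ball cap of the patch radius through a
    # thin wall ≈ π r² w; recounted exactly on the voxel grid afterwards
    per_patch = math.pi * spec.diffuse_patch_radius_mm**2 * spec.wall_thickness_mm
    n_patches = max(1, int(round(spec.diffuse_fibrosis_mm3 / per_patch)))
    for _ in range(n_patches):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        t = 1.0 / math.sqrt(float(np.sum((d / a) ** 2)))
        surface = spec.center_mm + (t + 0.5 * spec.wall_thickness_mm) * d
        centers.append((surface, spec.diffuse_patch_radius_mm))
    return centers


def _grid_points(shape, spacing) -> np.ndarray:
    axes = [np.arange(n) for n in shape]
    I, J, K = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([I, J, K], axis=-1).reshape(-1, 3).astype(float)
    return (idx + 0.5) * np.asarray(spacing)


def generate_phantom(spec: PhantomSpec, _streams=None) -> PhantomCase:
    """Build one case deterministically from ``spec.seed``."""
    if _streams is None:
        geom_ss, lge_ss, angio_ss = np.random.SeedSequence(spec.seed).spawn(3)
    else:
        geom_ss, lge_ss, angio_ss = _streams
    geom_rng = np.random.default_rng(geom_ss)

    vv = float(np.prod(spec.spacing))
    scene = _Scene(spec, _diffuse_centers(spec, geom_rng, vv))
    pts = _grid_points(spec.shape, spec.spacing)

    labels, blood, wall, fib, rings = scene.classify(pts)
    shp = spec.shape
    grid = dict(spacing=spec.spacing, origin=np.zeros(3), direction=np.eye(3))

    lge_vox = _render(labels, spec.lge_intensity, spec.noise_sd,
                      spec.noise_model, np.random.default_rng(lge_ss))
    lge = Volume3D(lge_vox.reshape(shp), **grid)

    mis = spec.true_misalignment()            # angio physical → LGE physical
    true_transform = mis.invert()             # LGE physical → angio physical
    pts_angio_in_fixed = mis.map_points(pts)  # where each angio voxel samples
    labels_m, blood_m, *_ = scene.classify(pts_angio_in_fixed)
    angio_vox = _render(labels_m, spec.angio_intensity, spec.noise_sd,
                        spec.noise_model, np.random.default_rng(angio_ss))
    angio = Volume3D(angio_vox.reshape(shp), **grid)

    def _mask(flat):
        return LabelMask(flat.reshape(shp), **grid)

    truth_rings = {v: _mask(rings[v]) for v in spec.veins}
    truth_volumes = {
        "wall_mm3": float(np.count_nonzero(wall)) * vv,
        "fibrosis_mm3": float(np.count_nonzero(fib)) * vv,
        "blood_mm3": float(np.count_nonzero(blood)) * vv,
    }
    for v in spec.veins:
        truth_volumes[f"ring_{v}_mm3"] = float(truth_rings[v].cardinality) * vv

    landmarks = []
    for vein in VEINS:
        if vein not in spec.veins:
            continue
        vs = spec.veins[vein]
        mid = vs.ring_offset_mm + 0.5 * vs.ring_axial_mm
        landmarks.append(OstiumDisk(
            vein=vein,
            center=scene.ostia[vein] + mid * vs.direction,
            normal=vs.direction,
            thickness_mm=vs.ring_axial_mm + 2.0,
            radius_mm=vs.radius_mm + spec.wall_thickness_mm + 2.0,
        ))

    return PhantomCase(
        lge=lge, angio=angio,
        truth_seg=_mask(blood_m), truth_seg_fixed=_mask(blood),
        truth_wall=_mask(wall), truth_fibrosis=_mask(fib),
        truth_rings=truth_rings, truth_volumes=truth_volumes,
        landmarks=landmarks, true_transform=true_transform,
        misalignment=mis, spec=spec,
    )


def generate_longitudinal_pair(spec: PhantomSpec, ablation: dict
                               ) -> tuple[PhantomCase, PhantomCase]:
    """Baseline case + day-30 case with ostial rings added per vein.

    ``ablation`` maps vein id → ring coverage *added* at day 30 (≥ 0).
    Geometry (including diffuse baseline patches) is shared; only the
    noise realizations differ between timepoints.
    """
    for vein, added in ablation.items():
        if vein not in spec.veins:
            raise PhantomSpecError(f"unknown vein {vein!r}")
        if added < 0:
            raise PhantomSpecError(
                f"{vein}: day-30 ring coverage cannot decrease (got {added})")
    streams = np.random.SeedSequence(spec.seed).spawn(5)
    geom = streams[0]
    baseline = generate_phantom(spec, _streams=(geom, streams[1], streams[2]))

    veins30 = {
        v: replace(vs, ring_coverage=min(1.0, vs.ring_coverage + ablation.get(v, 0.0)))
        for v, vs in spec.veins.items()
    }
    spec30 = replace(spec, veins=veins30)
    day30 = generate_phantom(spec30, _streams=(geom, streams[3], streams[4]))
    return baseline, day30


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Clinical table plus (optionally) the underlying image pairs."""

    clinical: pd.DataFrame
    truth: pd.DataFrame
    cases: list | None = None


def _logit(p):
    return math.log(p / (1.0 - p))


def generate_cohort(n: int, effect: float = 0.0, censoring_rate: float = 0.2,
                    seed: int = 0, base_spec: PhantomSpec | None = None,
                    volumes: bool = False, base_rate: float = 0.33,
                    measurement_sd: float = 0.02,
                    followup_cap_months: float = 24.0) -> SyntheticCohort:
    """Synthetic patient cohort with a controllable fibrosis–recurrence link.

    Recurrence is Bernoulli with ``logit p = β₀ + effect · z`` where ``z``
    is the cohort-standardized true mean per-vein ostial delta and ``β₀``
    matches ``base_rate``.  ``effect = 0`` gives the null: outcome
    independent of every fibrosis metric.  The default mode derives the
    per-patient deltas from analytic truth volumes (with a small
    measurement-noise term); ``volumes=True`` also materializes the full
    longitudinal image pairs.
    """
    if n < 4:
        raise ValueError("cohort size must be ≥ 4")
    base_spec = base_spec or PhantomSpec(diffuse_fibrosis_mm3=800.0)
    root = np.random.SeedSequence(seed)
    patient_ss = root.spawn(n)
    outcome_rng = np.random.default_rng(root.spawn(1)[0])

    rows, cases = [], []
    for i, ss in enumerate(patient_ss):
        rng = np.random.default_rng(ss)
        jitter = 1.0 + rng.uniform(-0.08, 0.08, size=3)
        semi = tuple(np.asarray(base_spec.semiaxes_mm) * jitter)
        veins = {}
        added = {}
        for v, vs in base_spec.veins.items():
            base_cov = float(rng.uniform(0.0, 0.15))
            veins[v] = replace(vs, ring_coverage=base_cov)
            added[v] = float(rng.uniform(0.0, 0.8))
        pseed = int(rng.integers(0, 2**31 - 1))
        spec = replace(base_spec, semiaxes_mm=semi, veins=veins, seed=pseed)

        w = spec.wall_thickness_mm
        diff = spec.diffuse_fibrosis_mm3
        pre_rings = {v: analytic_ring_volume(veins[v], w) for v in veins}
        post_rings = {
            v: analytic_ring_volume(
                replace(veins[v], ring_coverage=min(1.0, veins[v].ring_coverage + added[v])), w)
            for v in veins
        }
        fib_pre = sum(pre_rings.values()) + diff
        fib_post = sum(post_rings.values()) + diff
        delta_la_true = (fib_post - fib_pre) / fib_pre

        dpv_true = {}
        for v, vs in veins.items():
            region = math.pi * ((vs.radius_mm + w) ** 2 - vs.radius_mm**2) * (
                vs.ring_axial_mm + 2.0)
            dpv_true[v] = (post_rings[v] - pre_rings[v]) / region
        dpv_obs = {v: dpv_true[v] + rng.normal(0.0, measurement_sd)
                   for v in dpv_true}

        row = {
            "patient_id": f"P{i:03d}",
            "baseline_la_fibrosis": fib_pre,
            "delta_la": delta_la_true + rng.normal(0.0, measurement_sd),
            "delta_pv_mean": float(np.mean(list(dpv_obs.values()))),
            "n_pv_no_increase": int(sum(1 for d in dpv_obs.values() if d < 0)),
            "_delta_pv_mean_true": float(np.mean(list(dpv_true.values()))),
        }
        for v in VEINS:
            row[f"delta_pv_{v}"] = dpv_obs[v]
        rows.append(row)
        if volumes:
            cases.append(generate_longitudinal_pair(spec, added))

    df = pd.DataFrame(rows)
    z = df["_delta_pv_mean_true"].to_numpy()
    z = (z - z.mean()) / (z.std(ddof=0) or 1.0)
    p = 1.0 / (1.0 + np.exp(-(_logit(base_rate) + effect * z)))
    recurrence = (outcome_rng.uniform(size=n) < p).astype(int)

    event_scale = 16.0 / math.log(2.0)  # median event time 16 months
    t_event = outcome_rng.exponential(event_scale, size=n)
    cut = np.full(n, followup_cap_months)
    if censoring_rate > 0:
        censored = outcome_rng.uniform(size=n) < censoring_rate
        cut = np.where(censored,
                       outcome_rng.uniform(1.0, followup_cap_months, size=n), cut)
    followup = np.where(recurrence == 1, np.minimum(t_event, cut), cut)
    event = ((recurrence == 1) & (t_event <= cut)).astype(int)

    df["recurrence"] = recurrence
    df["followup_months"] = followup
    df["event"] = event
    truth = df[["patient_id", "_delta_pv_mean_true"]].rename(
        columns={"_delta_pv_mean_true": "delta_pv_mean_true"})
    clinical = df.drop(columns=["_delta_pv_mean_true"])
    return SyntheticCohort(clinical=clinical, truth=truth,
                           cases=cases if volumes else None)
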