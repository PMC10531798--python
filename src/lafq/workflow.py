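"""End-to-end orchestration: register → wall → threshold → quantify.

``run_patient`` executes the full per-patient pipeline (one or two
timepoints), writing every derived artifact plus overlay snapshots at
the three human-review checkpoints (input quality, post-registration
alignment, ostial marker placement).  The manual radiologist review the
workflow calls for cannot be automated, so the checkpoints are surfaced
as images rather than simulated; a failed registration convergence flag
aborts unless ``force`` is set.

``run_cohort`` joins the per-patient metrics with a clinical table and
runs the outcome-statistics layer.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import fibrosis_quant as fq
from . import outcome_stats, registration, wall_extraction
from .errors import LafqError
from .image_model import (LabelMask, Volume3D, export_masked_surface,
                          mask_volume, read_mask, read_volume, write_mask)

__all__ = ["RunConfig", "TimepointPaths", "StageError", "run_patient",
           "run_timepoint", "run_cohort"]


class StageError(LafqError):
    """A pipeline stage failed; carries the stage name and a hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        super().__init__(f"[{stage}] {message}" + (f" — {hint}" if hint else ""))


@dataclass
class TimepointPaths:
    lge: str
    angio: str
    segmentation: str


@dataclass
class RunConfig:
    """All inputs and workflow parameters for one patient run."""

    patient_id: str
    output_dir: str
    baseline: TimepointPaths | None = None
    day30: TimepointPaths | None = None
    landmarks: str | None = None
    radius_px: int = 3
    sphere_diameter_mm: float = 10.0
    sd_multiplier: float = 2.0
    registration_mode: str = "rigid"
    seed: int = 0
    force: bool = False
    export_vtp: bool = True
    snapshots: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for tp in ("baseline", "day30"):
            if d.get(tp) is not None:
                d[tp] = TimepointPaths(**d[tp])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            if str(path).endswith(".json"):
                return cls.from_dict(json.load(fh))
            return cls.from_dict(yaml.safe_load(fh))


def _snapshot(volume: Volume3D, mask: LabelMask | None, path: str,
              title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = volume.shape[2] // 2
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(volume.voxels[:, :, k].T, cmap="gray", origin="lower")
    if mask is not None and mask.voxels[:, :, k].any():
        ax.contour(mask.voxels[:, :, k].T.astype(float), levels=[0.5],
                   colors="r", linewidths=0.8)
    ax.set_title(title)
    ax.axis("off")
    fig.savefig(path, dpi=90, bbox_inches="tight")
    plt.close(fig)


def run_timepoint(lge: Volume3D, angio: Volume3D, seg: LabelMask,
                  landmarks: list | None, config: RunConfig,
                  out_dir: str | None = None, tag: str = "baseline") -> dict:
    """Run the full single-scan pipeline; returns results + intermediates."""
    os.makedirs(out_dir, exist_ok=True) if out_dir else None

    def artifact(name):
        return os.path.join(out_dir, f"{tag}_{name}") if out_dir else None

    if out_dir and config.snapshots:
        _snapshot(lge, None, artifact("check1_inputs.png"),
                  f"{tag}: LGE input quality check")

    # -- registration -----------------------------------------------------
    try:
        settings = registration.RegistrationSettings(seed=config.seed)
        transform, report = registration.register(
            lge, angio, mode=config.registration_mode, settings=settings)
    except LafqError as exc:
        raise StageError("registration", str(exc)) from exc
    if not report.converged and not config.force:
        raise StageError("registration", "optimizer did not converge",
                         "inspect the overlay snapshot or rerun with force")
    seg_fixed = registration.apply_transform(seg, transform, lge)
    if out_dir:
        transform.save(artifact("transform.txt"))
        write_mask(seg_fixed, artifact("seg_registered.nii.gz"))
        if config.snapshots:
            _snapshot(lge, seg_fixed, artifact("check2_registration.png"),
                      f"{tag}: registered segmentation on LGE")

    # -- wall extraction ---------------------------------------------------
    try:
        regions = wall_extraction.extract_regions(seg_fixed,
                                                  radius_px=config.radius_px)
    except LafqError as exc:
        raise StageError("wall_extraction", str(exc),
                         "try a smaller erosion radius") from exc
    if out_dir:
        write_mask(regions.blood_pool, artifact("bloodpool.nii.gz"))
        write_mask(regions.wall, artifact("wall.nii.gz"))
        with open(artifact("wall_params.json"), "w") as fh:
            json.dump(regions.params, fh, indent=2)

    # -- threshold ---------------------------------------------------------
    try:
        thr = fq.compute_threshold(lge, regions.blood_pool,
                                   diameter_mm=config.sphere_diameter_mm,
                                   sd_multiplier=config.sd_multiplier)
    except LafqError as exc:
        raise StageError("threshold", str(exc),
                         "check the blood-pool mask") from exc
    if out_dir:
        with open(artifact("threshold.json"), "w") as fh:
            json.dump({"mean": thr.sample_mean, "sd": thr.sample_sd,
                       "multiplier": thr.sd_multiplier,
                       "threshold": thr.threshold,
                       "center_mm": thr.sphere_center.tolist(),
                       "diameter_mm": thr.sphere_diameter_mm,
                       "n_voxels": thr.n_sample_voxels}, fh, indent=2)

    # -- quantification ----------------------------------------------------
    wall_result = fq.quantify_wall_fibrosis(lge, regions.wall, thr)
    if out_dir and config.export_vtp:
        export_masked_surface(lge, regions.wall, artifact("wall_masked.vtp"))

    ostial = {}
    if landmarks:
        for disk in landmarks:
            if out_dir and config.snapshots:
                dm = fq.rasterize_disk(disk, lge)
                _snapshot(lge, dm, artifact(f"check3_marker_{disk.vein}.png"),
                          f"{tag}: {disk.vein} ostial marker")
            try:
                ostial[disk.vein] = fq.quantify_ostial_fibrosis(
                    lge, regions.wall, disk, thr)
            except LafqError as exc:
                raise StageError("ostial_quantification", str(exc),
                                 "verify the marker position") from exc

    return {"transform": transform, "report": report, "seg_fixed": seg_fixed,
            "regions": regions, "threshold": thr, "wall": wall_result,
            "ostial": ostial}


def _write_metrics_csv(rows: list, path: str) -> None:
    fields = ["patient_id", "timepoint", "region", "fibrosis_volume_mm3",
              "region_volume_mm3", "fibrosis_fraction", "threshold_used"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields)
        w.writeheader()
        for row in rows:
            w.writerow({k: (f"{v:.10g}" if isinstance(v, float) else v)
                        for k, v in row.items()})


def run_patient(config: RunConfig,
                inputs: dict | None = None) -> fq.PatientMetrics:
    """Execute the pipeline for one patient (one or two timepoints).

    ``inputs`` may supply already-loaded objects per timepoint
    (``{"baseline": (lge, angio, seg), ...}`` plus ``"landmarks"``);
    otherwise everything is read from the paths in ``config``.  Artifacts
    and the verbatim config are written under ``config.output_dir``; wall
    metrics are persisted even when the ostial stage later fails.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    with open(os.path.join(config.output_dir, "config_used.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    inputs = inputs or {}
    landmarks = inputs.get("landmarks")
    landmarks_error = None
    if landmarks is None and config.landmarks:
        try:
            landmarks = fq.read_landmarks(config.landmarks)
        except FileNotFoundError as exc:
            landmarks_error = StageError("ostial_quantification",
                                         f"landmark file missing: {exc}")

    metrics = fq.PatientMetrics(patient_id=config.patient_id)
    rows = []
    csv_path = os.path.join(config.output_dir, "metrics.csv")
    pending_error = None
    for tp in ("baseline", "day30"):
        paths = getattr(config, tp)
        if tp in inputs:
            lge, angio, seg = inputs[tp]
        elif paths is not None:
            lge = read_volume(paths.lge)
            angio = read_volume(paths.angio)
            seg = read_mask(paths.segmentation)
        else:
            continue
        try:
            res = run_timepoint(lge, angio, seg, landmarks, config,
                                out_dir=config.output_dir, tag=tp)
        except StageError as exc:
            if exc.stage == "ostial_quantification":
                pending_error = exc  # wall metrics still usable
                res = None
            else:
                _write_metrics_csv(rows, csv_path)
                raise
        if res is None:
            break
        metrics.la[tp] = res["wall"]
        metrics.per_vein[tp] = res["ostial"]
        rows.extend(fq.PatientMetrics(config.patient_id,
                                      {tp: res["wall"]},
                                      {tp: res["ostial"]}).to_rows())

    _write_metrics_csv(rows, csv_path)
    if landmarks_error is not None:
        raise landmarks_error
    if pending_error is not None:
        raise pending_error

    metrics.compute_deltas()
    with open(os.path.join(config.output_dir, "patient.json"), "w") as fh:
        json.dump(metrics.summary(), fh, indent=2)
    return metrics


def run_cohort(summaries: pd.DataFrame, clinical: pd.DataFrame,
               covariates=None, out_dir: str | None = None
               ) -> outcome_stats.CohortReport:
    """Join per-patient metrics with a clinical table and run statistics.

    ``summaries`` needs one row per patient (``patient_id`` + fibrosis
    metrics); ``clinical`` needs ``patient_id``, ``recurrence``,
    ``followup_months`` and optional covariates.
    """
    drop = [c for c in clinical.columns
            if c != "patient_id" and c in summaries.columns]
    df = summaries.merge(clinical.drop(columns=drop), on="patient_id",
                         how="inner")
    if len(df) == 0:
        raise outcome_stats.StatisticsError(
            "no patients in common between metrics and clinical tables")
    report = outcome_stats.analyze_cohort(df, covariates=covariates)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        report.group_comparisons.to_csv(
            os.path.join(out_dir, "group_comparisons.csv"), index=False)
        report.univariate.to_csv(
            os.path.join(out_dir, "univariate_or.csv"), index=False)
        if report.multivariate is not None:
            report.multivariate.to_csv(
                os.path.join(out_dir, "multivariate_or.csv"), index=False)
        with open(os.path.join(out_dir, "report.txt"), "w") as fh:
            fh.write(report.to_text())
        if report.survival is not None:
            km_rows = []
            for g in report.survival.groups:
                for t, s in zip(report.survival.timelines[g],
                                report.survival.survival[g]):
                    km_rows.append({"group": g, "time": t, "survival": s})
            pd.DataFrame(km_rows).to_csv(
                os.path.join(out_dir, "km_curves.csv"), index=False)
    return report
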