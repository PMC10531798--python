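# Methods

`lafq` measures ablation-induced fibrosis of the left atrium (LA) and the
pulmonary-vein (PV) ostia from a paired MRI acquisition: a bright-blood
angiographic volume that carries the anatomy (and on which the LA+PV
segmentation is drawn), and a late-gadolinium-enhancement (LGE) volume
that carries the fibrosis signal. This note records the model, the
parameters that matter, the numerical choices, what the synthetic phantom
does and does not emulate, and the known limitations.

## Coordinate and image model

Volumes live in physical LPS millimetre space. A voxel's physical
position is its **center**, at continuous index `index + 0.5`:

    x = origin + direction · (spacing ∘ (index + 0.5))

so `origin` is the corner of voxel (0,0,0). File I/O (NIfTI, MetaImage)
goes through SimpleITK; the half-voxel offset between this corner-origin
convention and ITK's center-origin convention is translated at the I/O
boundary, so metadata round-trips within 1e-6. Masked volumes use NaN as
the background sentinel — never 0, which is a legal gray level — so
background can never contaminate intensity statistics. Masked enhancement
data can be exported as a `.vtp` point cloud (one point per mask voxel,
gray level as point scalar) for external mesh tools; the writer emits
plain ASCII VTK XML PolyData.

## Registration

The LGE volume is the fixed image; the angio volume (and hence its
segmentation) is moving. Alignment uses multi-resolution (shrink factors
4/2/1, smoothing sigmas 2/1/0 mm) Mattes mutual information with 32
histogram bins, moments (center-of-mass) initialization, and a
regular-step gradient-descent optimizer with scales estimated from
physical shift — the standard robust recipe for cross-sequence MRI.
Metric sampling uses SimpleITK's REGULAR strategy at 25%, which is
deterministic by construction, so identical inputs always give identical
transforms. Rigid is the default; `mode="affine"` refines the rigid
result with a full affine model. The returned transform maps fixed
physical points into moving space (the direction needed for resampling),
and masks are resampled with nearest-neighbor interpolation only, so
they stay binary. Non-convergence is reported as a flag, not an
exception; the orchestrated pipeline refuses to continue on a
non-converged registration unless forced, and emits mid-slice overlay
snapshots at the three human-review checkpoints (input quality,
post-registration alignment, ostial marker placement) since the
radiologist review those checkpoints stand for cannot be automated.

## Wall extraction

From the registered LA+PV segmentation: the blood pool is the
segmentation **eroded** by a Euclidean ball of radius 3 voxels; the wall
shell is the **dilation** (same ball) minus the blood pool — a band
straddling the segmentation boundary that likely contains the thin
(~2–4 mm) atrial wall. The structuring element is the exact set of
integer offsets with ‖offset‖ ≤ r (7/33/123 offsets for r = 1/2/3), and
the implementation is voxel-exact against a brute-force morphology
oracle. The radius is interpreted in index space regardless of voxel
anisotropy, matching the pixel-based workflow this reproduces; an
anisotropy-aware physical-space ball (`radius_mm`) is available as an
opt-in. Erosion and dilation radii are equal by default but exposed
separately. The filled segmentation (not a one-voxel contour) is eroded:
that is the standard reading and the only one that yields a blood pool.
No topology correction or connected-component filtering is applied; the
wall's component count is logged for QC only.

## Threshold selection

The fibrosis cutoff is per-scan: the mean gray level of a 10 mm diameter
sphere placed inside the blood pool plus 2 sample standard deviations
(n−1 convention; at ~500 voxels the difference from n is negligible).
The sphere is auto-placed at the blood pool's deepest point (argmax of
the Euclidean distance transform computed in mm; deterministic tie-break
by lowest (z,y,x) index) and must lie entirely inside the blood pool —
partial placements raise instead of silently clipping, and an infeasible
request reports the maximum feasible diameter. Baseline and day-30
thresholds are computed independently; nothing is shared across scans.
Classification is strict (`> threshold`), so the boundary statistic
itself is never counted as fibrosis.

A structural property of this rule: by construction ~2.3% of blood-pool
voxels exceed mean + 2 SD under Gaussian noise, and the wall shell
contains the blood-side band between the eroded and original
segmentation. Those voxels are the dominant false-positive source at low
fibrosis load; with the default phantom's post-ablation load they bias
measured volume by a few percent, at near-zero load they can dominate
relatively. This is inherent to the method, not to the implementation.

## Ostial volumetry and longitudinal deltas

Each PV ostium is marked by a disk (center, unit normal, thickness
default 2 mm, radial bound default 10 mm; the radial bound is a design
choice — without one a slab would span the whole atrium). A voxel
belongs to the disk when its center satisfies both the slab and the
radial test; rasterization is voxel-exact against a point-test oracle.
The ostial region is disk ∩ wall, and fibrosis within it is measured
with the same threshold.

Longitudinal change (baseline vs day 30):

* `delta_la = (V_post − V_pre) / V_pre` on total wall fibrosis volumes;
  zero baseline yields a flagged missing delta, never a sentinel value.
* `delta_pv` per vein = change in ostial fibrosis **fraction**
  (fibrosis volume / ostial region volume at each timepoint). Volume
  indexing was chosen over surface indexing because the workflow
  measures fibrosis as a volume.
* `n_pv_no_increase` counts veins with a **strictly negative** delta
  (an exactly-zero delta is neither an increase nor a decrease).

## Outcome statistics

Standard estimators behind a thin surface: Student's t (equal
variances) and Fisher's exact test (probability-ordering two-sided p,
the mainstream-software convention) for group comparisons;
maximum-likelihood logistic regression with Wald 95% CIs on the
odds-ratio scale (perfect or quasi-perfect separation is detected —
complete-separation scan plus unbounded-SE guard — and flagged with no
estimates returned); ROC with the exact tie-corrected AUC
`P(s⁺ > s⁻) + ½P(tie)` computed through midranks; Kaplan–Meier
product-limit curves per group with the two-group log-rank χ² (1 df).
No multiple-testing correction is applied anywhere. For patient-level
models the per-vein deltas are summarized as their mean; the per-vein
table is also emitted so users can choose otherwise. Survival strata
follow presence/absence of at least one PV without an ostial increase.

## Synthetic phantom

The phantom is an ellipsoidal atrial shell (default semi-axes 26/22/20
mm, wall 3 mm) with four tubular veins (lumen radius 6 mm, length 16
mm), built by analytic inside-tests at voxel centers on a 96³, 1 mm
grid — deliberately idealized so every truth quantity is available in
closed form and by exact voxel recount. Ablation fibrosis is a ring
sector in the vein wall at each ostium (angular coverage fraction ×
axial extent); optional diffuse baseline patches approximate pre-existing
fibrosis. The angio volume is rendered directly at rigidly misaligned
sample points (default: 5° about z plus (4, −2, 3) mm, about the volume
center), so its truth segmentation is exact in angio space and no
resampling interpolation blurs the ground truth.

Default LGE class means are background 10, healthy wall 60, blood 100,
fibrotic wall 170, with additive Gaussian noise SD 10 (a Rician option
exists for magnitude-MRI realism). Enhancing fibrosis must clear the
blood mean + 2·SD cutoff to be detectable at all under the threshold
rule, so the fibrotic mean sits 5 noise-SD above the cutoff (blood SNR
10, fibrosis/threshold contrast 5σ); healthy wall sits far below blood.
On the angio rendering blood is bright (200) and fibrosis is
indistinguishable from healthy wall, as in the real sequences. One seed
drives geometry, per-timepoint noise and cohort sampling through
independent derived streams, so every stage replays in isolation and
identical seeds give bit-identical volumes.

What the phantom does **not** emulate: realistic atrial shape and wall
thickness variation, partial-volume effects at tissue interfaces, bias
fields and coil-profile inhomogeneity, motion/flow artifacts, k-space /
inversion-recovery signal formation, and extracardiac anatomy. Passing
the phantom suite therefore demonstrates the pipeline's correctness and
its noise behavior under the stated contrasts — not clinical accuracy on
patient data, where segmentation quality and image artifacts dominate.

Longitudinal pairs share geometry and differ only in added ring coverage
(day-30 coverage may never decrease) and noise realization. Cohorts link
recurrence to the cohort-standardized true mean per-vein delta through
`logit p = β₀ + effect · z` with β₀ matched to a 33% base rate;
follow-up uses exponential event times (median 16 months) with an
administrative 24-month cap and optional random censoring. The default
cohort mode computes per-patient deltas from the analytic truth volumes
plus a small measurement-noise term (SD 0.02 on fractions) — no voxel
grids — so 200-seed null studies run in seconds; `volumes=True`
materializes full image pairs. Per-patient geometry is jittered (±8%
semi-axes, baseline coverage U(0, 0.15), added coverage U(0, 0.8)).

## Problem sizes and numerical choices

The validation suite runs phantoms at 96³ × 1 mm (the default study
geometry) and 64³ scaled-down variants for unit-level checks; the
registration recovery checks use 5 seeded cases and the noisy recovery
checks 20 seeded longitudinal pairs. Grid-metadata equality uses a 1e-6
tolerance; rigid matrices are re-orthonormalized by SVD after
optimization; Dice of two empty masks is defined as 1. Degenerate inputs
raise typed errors (too-thin segmentation, infeasible sphere, disk
missing the wall, zero-baseline delta, single-class outcomes) rather
than producing numbers.

## Known limitations

* The wall shell is a morphological surrogate (6 mm band for radius 3);
  it overstates true wall volume, so fibrosis *fractions* are diluted
  relative to an anatomically exact wall. Volumes are the primary
  output.
* The mean + 2 SD rule fixes the blood false-positive tail at ~2.3%
  regardless of noise level (see above).
* Disk placement is trusted; a disk near two ostia can capture a
  neighboring vein's fibrosis. The pipeline surfaces marker snapshots
  for review rather than validating placement automatically.
* Only rigid/affine registration is provided; breath-to-breath
  deformation between sequences is not modelled.
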