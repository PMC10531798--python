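# lafq — left-atrial & pulmonary-vein ostial fibrosis quantification

`lafq` implements a semi-automatic workflow for measuring
ablation-induced fibrosis of the left atrium (LA) and the pulmonary-vein
(PV) ostia from paired cardiac MRI, for researchers studying atrial
fibrillation (AF) ablation outcomes. After cryoballoon pulmonary-vein
isolation, the intended lesion is a circumferential fibrotic ring at
each PV ostium; this package quantifies that fibrosis from a bright-blood
angiographic volume (anatomy + segmentation) and a late-gadolinium-
enhancement (LGE) volume (fibrosis signal), and relates longitudinal
change to arrhythmia recurrence.

## The method

Per patient and timepoint, with the LGE volume as the fixed image:

1. **Registration** — the angio volume and its LA+PV segmentation are
   aligned onto the LGE volume by multi-resolution Mattes mutual
   information (rigid by default, affine optional); the segmentation is
   propagated with nearest-neighbor resampling.
2. **Wall extraction** — with a Euclidean-ball structuring element of
   radius 3 voxels: blood pool = erode(seg), wall shell =
   dilate(seg) ∖ erode(seg).
3. **Threshold** — the fibrosis cutoff is per-scan:
   `T = μ + 2σ` over a 10 mm diameter sphere placed inside the blood
   pool (auto-placed at the distance-transform argmax).
4. **Volumetry** — fibrosis volume = (# wall voxels with gray level
   > T) × voxel volume, over the whole wall and inside a 2 mm-thick disk
   at each of the four PV ostia (LSPV, LIPV, RSPV, RIPV).
5. **Deltas** — ΔLA = (V_post − V_pre)/V_pre on wall fibrosis volumes;
   Δ_PV per vein = change in ostial fibrosis fraction; and the count of
   veins with a strictly negative Δ_PV ("PVs without an increase").
6. **Outcome statistics** — Student's t and Fisher's exact tests,
   logistic regression (odds ratios with Wald 95% CIs), ROC with exact
   tie-corrected AUC, Kaplan–Meier and the log-rank test.

A fully synthetic atrial phantom (ellipsoidal shell, four tubular veins,
ostial fibrosis rings, known rigid misalignment, seeded noise) provides
closed-form ground truth for every stage, including whole synthetic
cohorts with a controllable fibrosis–recurrence link. See
`docs/methods.md` for assumptions, parameters and limitations.

## Worked example

`examples/01_phantom_pipeline.py` builds a baseline/day-30 phantom pair
(ablation rings added to all four veins at day 30), registers the
misaligned angio volume, and runs the full quantification:

```
registration converged=True, Dice vs truth = 0.985
baseline: threshold 121.9, wall fibrosis 1729 mm3 (truth 1433 mm3)
day30: threshold 120.4, wall fibrosis 4676 mm3 (truth 4612 mm3)
delta LA fibrosis (baseline-normalized): +1.70
  LSPV: ostial fraction delta +0.297
  LIPV: ostial fraction delta +0.295
  RSPV: ostial fraction delta +0.295
  RIPV: ostial fraction delta +0.225
PVs without an increase: 0
```

The Dice score gauges registration quality against the phantom's truth
segmentation. Each scan gets its own blood-pool threshold (≈ 120 = blood
mean 100 + 2 × noise SD 10). Day-30 wall fibrosis lands within ~1.5% of
truth; the baseline overshoot illustrates the method's floor — ~2.3% of
blood-side shell voxels exceed a mean + 2 SD cutoff by construction,
which matters when true fibrosis is small. All four ostial deltas are
positive, so no vein counts as "without an increase".

`examples/02_wall_and_threshold.py` walks the morphology and threshold
steps; `examples/03_cohort_statistics.py` contrasts a null cohort
(AUC ≈ 0.5, OR CI covering 1) with a strong-effect cohort.

The same pipeline is scriptable from the shell via the `lafq` CLI
(`lafq register | wall | threshold | quantify | run | cohort-stats |
phantom`), with exit codes 2 for input errors and 3 for stage failures.

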