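# Methods

`lvtrab` quantifies the left-ventricular (LV) trabecular layer from
bright-blood cine CMR frames at end-diastole (ED) and end-systole (ES). This
note describes the measurement model, the synthetic phantoms that stand in
for patient scans, the numerical choices, and what the tests do and do not
demonstrate.

## The measurement model

Each analyzed frame is partitioned into five labels: compact wall,
trabeculations (tissue ridges of the inner wall), intertrabecular recesses
(IR — blood clefts between them), central cavity (CC), and papillary muscles.
From per-phase label volumes *V*<sub>ED</sub>, *V*<sub>ES</sub> (Simpson
slice summation over short-axis stacks: pixel count × pixel area × slice
thickness) or areas (four-chamber views) the package derives:

* **SFVC / SFAC** = *V*<sub>ES</sub>/*V*<sub>ED</sub>, the systolic fractional
  volume/area change of a label. For any blood pool, SFVC = 1 − EF exactly.
* **EF** = (EDV − ESV)/EDV per pool and for the pooled total cavity under
  three conventions:
  * *guidelines* — trabecular tissue counted inside the blood pool
    (cavity = CC + IR + trabeculations, at per-phase measured tissue values);
  * *jacquier* — recesses counted as trabecular myocardium (cavity = CC);
  * *contour* — trabeculations contoured out, recesses kept as blood
    (cavity = CC + IR); the reference convention.
* **Trabecular mass** = mean of the ED and ES tissue volumes; LV mass =
  mean-phase compact + trabecular tissue, with the papillary roll-up
  configurable because conventions differ on whether papillary volume belongs
  to the denominator (both roll-ups are computable; the default excludes it).
  The Jacquier criterion flags trabecular mass > 20% of LV mass.
* **MAPSE** (per-wall ED−ES apex-to-annulus length change, global = mean of
  the six walls over the three long-axis views) and **GL-shortening** =
  100 × (LV length ED − LV length ES)/LV length ED on view-averaged lengths.

Percentages are stored as fractions internally and rendered as percent only
at the reporting layer.

### Threshold calibration and locking

Segmentation follows a calibrate-then-lock protocol. On one reference ED
frame (mid-ventricular short-axis when a stack is available, otherwise the
four-chamber frame) a single intensity threshold is chosen so that the
trabecular layer splits into approximately equal parts tissue and recess;
whether ≥90% of (hinted) papillary pixels classify as tissue at that
threshold is recorded. The tissue-fraction-vs-threshold curve is a monotone
step function of the sorted annulus intensities, so the optimum is computed
exactly by order-statistic inversion (the converged limit of a bisection on
that curve), taking the midpoint of the optimal plateau. The threshold is
then locked and applied to every ED and ES frame of the study — the same
threshold in both phases. A per-phase threshold exists only as an
experimental flag; the single lock is the protocol being modelled, with its
known weaknesses.

If no threshold achieves an annulus tissue fraction in [0.3, 0.7], the
calibration records a warning in the lock rather than failing.

### Morphological partition

Within each binarized frame (tissue = below threshold and above a background
cutoff; the cutoff separates air from myocardium by Otsu on the sub-threshold
histogram unless given):

1. the **compact wall** is the largest connected tissue component surviving a
   morphological opening of radius `r_open` (default 4 mm), which removes
   the trabecular spokes — `r_open` must exceed half the widest expected
   spoke, and spokes *widen* at ES as conserved tissue crowds a smaller
   annulus, which is why 4 mm rather than a value tuned to the ED appearance;
2. the wall's endocardial boundary is regularized by closing the enclosed
   region with radius `r_endo` (default 9 mm): the opening leaves shallow
   spoke-root stubs attached to the wall, and the closing reassigns them to
   the trabecular label (the "common-sense" smooth-ring assumption made
   explicit);
3. wall-connected tissue inside the wall is **trabeculation**; detached
   interior tissue is **papillary**;
4. the cavity-side boundary of the trabecular layer is the inner edge of a
   closing (radius `r_close`, default 6 mm) of the wall-connected myocardium
   — papillary discs are excluded from this closing so they cannot bridge to
   the spoke tips and fragment the cavity;
5. enclosed blood inside that boundary is **central cavity** (largest
   connected component; a multi-component pool logs an ambiguity); enclosed
   blood outside it is **recess**.

All structuring-element radii are physical (mm), converted per frame through
the pixel spacing, because spoke widths and recess mouths scale with anatomy,
not with the grid. Frames where no closed ring encloses a blood pool raise a
named error; a study run reports per-frame failures and continues.

### Mislabeling sensitivity

The exact published perturbation scheme for deliberate CC-deflation /
IR-inflation is not available; two declared reconstructions are implemented.
The *symmetric* scheme moves equal ED and ES fractions of the CC into the IR
label; the perturbed IR EF is then a mediant of the two original EFs and can
never cross below the CC EF when it starts above it. The *ES-only* scheme
moves only ES volume and admits a crossing; the crossing transfer is solved
in closed form. All outputs label these as reconstructions.

## The theoretical ventricle

A schematic LV clamps papillary + CC + trabeculations + recesses at ED to
150 mL, with a normal baseline (5/120/10/15 mL) and an
excessive-trabeculation baseline (5/70/30/45 mL), both pools at EF 60%.
Three sweeps probe measurement distortion: growing the trabecular tissue
volume (recess volume tied to tissue at ratio 1.5 — the ratio shared by both
baselines; the redistribution rule is an inference and is exposed as a
parameter), varying the recess EF at fixed volumes, and mis-measuring the ED
tissue volume with the ES measurement held at truth. All model arithmetic is
closed-form; infeasible sweep points are dropped with a warning.

The recess-EF sweep spans a contour-convention total EF of 40.4%–71.7% and a
guidelines-convention 32.1%–56.9%; which convention the original figure used
is not stated, so both curves are emitted and no intent is guessed.

## Synthetic phantoms

No patient images are deposited, so every image-level claim is validated on
phantoms with exact ground truth.

**Short-axis**: per slice, an annular compact wall, a trabecular annulus of
radial tissue spokes, a circular cavity, and papillary discs detached from
the wall. The ES geometry is solved in closed form from the analytic
disc/annulus areas: the cavity radius from the CC EF target, the layer outer
radius from exact tissue conservation (spokes thicken angularly), the
epicardial radius from compact conservation (the wall thickens inward, the
epicardium moves slightly in). Labels are rasterized first — they are the
ground truth — then intensities (blood 1000 a.u., myocardium 300 a.u.,
background 0) are blurred (σ 0.8 px) and degraded with additive Gaussian
noise (sd 35 a.u. = 5% of the blood–myocardium gap) from the spec's seed.

Default geometry: 8 slices × 8 mm on a 128² grid at 0.8 mm pixels;
epicardial radius 42 mm, wall 10 mm, layer 13 mm, 20 spokes, ED tissue
fraction 0.5. The pixel size and spoke count were chosen so that both phases
stay resolvable: under the cohort EF targets the ES recess mouths narrow to
≈1.5–2 mm and the ES spokes widen to ≈6 mm, and the grid must resolve the
former while the opening removes the latter. The default stack is
cylindrical (no apical taper) for the same reason; a per-slice radius
profile is supported. The ED tissue fraction of 0.5 matches the calibration
protocol's equal-parts assumption — with a substantially different fraction
the locked threshold mislabels part of the layer *by design*, a property of
the protocol the package reproduces rather than hides (the tabular cohort
keeps the published 37.3 ± 7.4% distribution).

**Four-chamber**: a single long-axis slice, bullet-shaped (half-ellipse,
38 × 80 mm semi-axes) with the trabeculated band spanning the half-ellipse
below the valve plane, papillary discs, and a schematic tissue cap closing
the base so the blood pool is enclosed (the real mitral valve is out of
scope). Ground truth is area-based; apex and annulus landmarks are emitted
per phase with the long axis shortening by the GL-shortening target (default
15%).

Realized ground truth matches the targets within discretization: EF targets
to ≤0.01 absolute at 128², area-change targets to ≤0.02, myocardium
conserved exactly in the analytic solution and to ≤1% on the grids.

**Tabular cohorts** sample layer volume (130 ± 48.9 mL), tissue fraction of
the layer (37.3 ± 7.4%), tissue fraction of LV mass (36.3 ± 8.3%), CC EDV
(120 ± 35 mL; no published distribution — chosen as realistic for
excessively trabeculated ventricles), and the two pool EFs (43.8 ± 15.8%,
61.0 ± 16.7%, truncated to (1, 99)%) as truncated normals, then derive the
remaining volumes so each row is internally consistent (recess EDV = layer −
tissue; compact wall from the mass fraction; ES blood from the EFs;
myocardium phase-equal unless a measurement-jitter parameter is set). The
two EFs are coupled by a Gaussian copula (ρ = 0.8): both pools share the
subject's global contractile state, and the published subgroup means (CC EF
30.6→55.4% against recess EF 45.9→74.3% across the LVEF split) move
together; without the coupling the paired recess-vs-cavity contrast loses
the decisive significance the cohort shows.

**Sampling design.** Cohort draws use randomized quantile stratification
(Latin-hypercube style: permuted strata midpoints plus uniform jitter through
the inverse CDF). Marginals are exactly the configured truncated normals,
while the realized n = 15 mean sits close to the configured mean — the
generator's purpose is to pin known ground truth under the published cohort
conditions, so recovery experiments measure the pipeline rather than
sampling luck. Plain iid sampling is available by flag.

## What passing tests show — and what they do not

The phantoms share the segmentation's core assumptions: a closed, roughly
annular compact wall, radial spokes, two-level contrast with Gaussian blur
and noise. Passing recovery tests therefore shows the chain — calibration,
locked labelling, volumetry, convention pooling, statistics — is correct and
robust to the modelled degradations (on the default noisy phantoms,
per-region volumes stay within 10% of truth and cohort-mean EFs within ~2
points). It does **not** show robustness to real-world effects the phantoms
omit: coil-intensity shading, partial-volume and motion artifacts, banding,
non-annular wall shapes, right-ventricular structures entering the frame, or
observer variability in the coarse LV localization. Cohort-level replication
of the published statistics is *calibration recovery* — the generator is set
to the printed distributions and the pipeline recovers them — never a
reproduction of the patient data, which are not deposited.

## Numerical and design choices

* Degenerate inputs are errors with named causes: empty or all-blood
  calibration annulus, open myocardium, cavity-free slices, zero LV mass,
  zero-ED-volume fractional changes (flagged NaN, not computed).
* ESV > EDV yields a negative EF with a warning (possible mislabeling), not
  an error.
* EF categories: <40%, 40–50% (boundaries in the middle bin), >50%.
* Two-sided tests throughout; α = 0.05; no multiple-testing correction (the
  modelled protocol applies none); when Shapiro–Wilk and Lilliefors disagree
  the non-parametric summary is used (conservative). Lilliefors needs n ≥ 4;
  below that the gate falls back to Shapiro–Wilk and flags it.
* Determinism: one seed drives each generator; identical spec + seed
  reproduce frames bit for bit; pipeline reruns with identical config are
  byte-identical apart from log timestamps.
* Problem sizes: recovery experiments use 15 subjects per cohort (the
  modelled study's n), 128² grids, 8 slices; the Monte-Carlo noise envelope
  uses 20 seeds on 2-slice stacks.

## Known limitations

* The compact/trabecular interface is defined morphologically (smooth-ring
  regularization); on anatomies whose wall genuinely undulates at the
  `r_endo` scale the split is biased toward the trabecular label.
* Recesses narrower than ~2 pixels at ES are partially lost to partial
  volume, biasing per-subject recess EF upward at extreme recess EF (visible
  as a ≈1–2 point cohort-mean overestimate).
* Four-chamber SFAC carries a ≈1–2 point downward bias from the
  cavity/recess mouth boundary; it is stable across noise levels.
* The theoretical model is volumetric bookkeeping, not hemodynamics; the
  systolic recess-to-cavity conduit flow is outside its scope.
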