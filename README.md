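# lvtrab

Quantification of the left-ventricular (LV) trabecular layer from cine
cardiac MR, for researchers studying excessive trabeculation
("noncompaction") and the biases that trabeculae introduce into routine
functional readouts.

On bright-blood cine frames at end-diastole (ED) and end-systole (ES), the
LV is partitioned — with a single per-study intensity threshold, calibrated
once and then locked — into compact wall, trabeculations, intertrabecular
recesses (IR), central cavity (CC), and papillary muscles. From the
per-phase label volumes *V*<sub>ED</sub>, *V*<sub>ES</sub> the package
computes, per region:

* systolic fractional volume/area change, SFVC = *V*<sub>ES</sub>/*V*<sub>ED</sub>
  (= 1 − EF for a blood pool),
* ejection fraction, EF = (EDV − ESV)/EDV,

and pools the total cavity three ways, because conventions disagree on where
the trabecular layer belongs:

| convention  | total cavity            | trabecular tissue counted as |
|-------------|-------------------------|------------------------------|
| guidelines  | CC + IR + trabeculations| blood                        |
| jacquier    | CC only                 | myocardium (with the IR)     |
| contour     | CC + IR                 | myocardium                   |

Also included: trabecular mass and the Jacquier criterion (trabecular
myocardium > 20% of LV mass), MAPSE and global longitudinal shortening from
apex/annulus landmarks, EF-category reclassification (<40% / 40–50% / >50%),
a mislabeling sensitivity analysis, a clamped-volume theoretical ventricle
(150 mL total) with parameter sweeps, and cohort statistics
(normality-gated summaries, one-sample and paired *t*-tests, Pearson
correlation).

Because no patient images are deposited, the package ships a synthetic-data
module: short-axis and four-chamber cine phantoms with exact ground-truth
label maps and prescribed per-region EFs, plus tabular cohorts calibrated to
the published population statistics. Every pipeline stage is validated
against that ground truth. See `docs/methods.md` for the model, parameter
defaults and limitations.

## Worked example

Generate a default noisy short-axis phantom (8 slices, 128², EF targets at
the cohort means: CC 43.8%, recesses 61.0%) and measure it end to end:

```python
import lvtrab as lt

study = lt.generate_short_axis_phantom(lt.default_short_axis_spec(seed=42))
quantities, diag = lt.analyze_frames(list(study.gray_frames))
row = lt.study_metrics_row(quantities)

print(round(diag["threshold"], 1), round(diag["achieved_fraction"], 3))
print(round(row["ef_cc"], 3), round(row["ef_ir"], 3), round(row["sfc_ir"], 3))
print(round(row["ef_contour"], 3), round(row["ef_guidelines"], 3),
      round(row["ef_jacquier"], 3))
```

prints

```
676.9 0.5
0.441 0.622 0.378
0.53 0.368 0.441
```

Read: the calibration locked a threshold of 676.9 a.u. at exactly the
equal-parts layer split; the measured central-cavity EF is 44.1% and the
recess EF 62.2% (generated truth: 44.6% and 60.7%) — the recesses empty
substantially more than the central cavity, and their SFVC of 0.378 is
1 − EF to machine precision. The same ventricle reads a total EF of 53.0%
when the trabeculations are contoured out, but only 36.8% when they are
pooled into the blood per guidelines; the Jacquier-convention EF equals the
central-cavity EF by construction. The stroke volume (`row["sv_contour"]`,
69.8 mL here) is identical under guidelines and contour pooling because the
tissue volume is measured equal in both phases.

The calibrate-then-lock segmentation is also exposed as a scikit-learn-style
estimator:

```python
seg = lt.ThresholdSegmenter().fit(reference_ed_frame)   # threshold_, lock_
labels = seg.predict(list(study.gray_frames))
```

From the shell, `lvtrab phantom | cohort | segment | metrics | theory |
report | run` cover the same stages over NIfTI studies and YAML manifests
(`lvtrab --help`).

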