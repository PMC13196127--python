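# fracaug

Toolkit for **MR-guided online adaptive radiotherapy (oART)** contouring
research in limited-data settings. In abdominal (e.g. pancreatic)
MR-Linac treatment, organs of interest (OoIs) must be re-contoured on
every session image while the patient is on the couch; training
auto-segmentation models for this is hard because cohorts are tiny and
anatomy shifts between fractions. `fracaug` provides the data-side
machinery around such a model:

* **`fracaug.phantom`** — synthetic abdominal session images with a
  9-organ label map (duodenum, large/small bowel, liver, both kidneys,
  spleen, stomach, spinal canal; optionally a missing kidney), dose
  grids with a 40 Gy prescription, and whole multi-session cohorts, so
  every other module is testable end-to-end with no patient data.
* **`fracaug.deform`** — structure-guided inter-fraction anatomy
  simulation: for each organ label `L_k` a bounded random similarity
  motion is drawn and turned into a localized displacement vector field
  (DVF) `u_k(x) = ϕ(L_k(x), p)`, with bounds
  `p = {p_disp, p_exp, p_shrink, p_rot}`; the per-organ fields are
  composed iteratively, `u_tot = u_N ∘ … ∘ u_1`, each organ's mask first
  warped by the already-composed field, and the session image/labels are
  warped once by `u_tot` (`I'(x) = I(u_tot(x))`, linear for the image,
  nearest for labels).
* **`fracaug.mraug`** — MR acquisition-variability augmentations:
  random monotone histogram shifts, random intensity scaling, and
  random Gibbs (k-space truncation) ringing.
* **`fracaug.conditioning`** — organ-conditioned dataset arrangement:
  ordered within-patient session pairs `(m, n)`, three-channel cases
  `D_{mn,o} = [I_m, L_{m,o}, I_n]` with target `L_{n,o}`, resampling to
  a common grid, patient-level leave-one-out cross-validation folds, and
  a channel-suffix raw-dataset layout with manifest.
* **`fracaug.metrics`** — contour evaluation: DSC, average surface
  distance (ASD) and 95th-percentile Hausdorff distance (HD95) on pooled
  bidirectional surface distances; DVH, D0.1cm³ and D50%, their
  discrepancies as a percentage of the prescribed dose (dPD), and a
  dose-gradient-weighted Dice (mDice) emphasising agreement near steep
  dose falloff.

The segmentation network itself (training and inference) is out of
scope; predicted label volumes enter this toolkit only as inputs to the
metrics module.

## Worked example

```python
import fracaug as fa

spec = fa.CohortSpec(
    patients=(("P1", 2), ("P2", 2)),
    phantom=fa.PhantomSpec(grid_shape=(48, 48, 32)),
    deform_params=fa.DeformParams(p_disp_mm=5.0, p_exp=0.1, p_shrink=0.1,
                                  p_rot_deg=5.0),
    seed=11,
)
registry = fa.make_cohort(spec, "cohort")           # sessions + DVFs on disk
pairs = fa.enumerate_pairs(registry)                # ordered within-patient pairs
cases = fa.build_conditioned_cases(registry, pairs) # one case per (pair, organ)
print("images:", registry.n_images, "pairs:", len(pairs), "cases:", len(cases))

gt = fa.LabelVolume.load(registry.record("P1", 1).labels)
sim = fa.LabelVolume.load(registry.record("P1", 2).labels)
dose = fa.make_dose_phantom(gt, tuple(gt.mask(1).centroid_mm()), 40.0)
report = fa.evaluate_contours(sim, gt, dose)
print(report[["organ", "dsc", "asd_mm", "hd95_mm",
              "d_hotspot_dpd_pct", "mdice"]].round(3).to_string(index=False))
```

prints

```
images: 4 pairs: 4 cases: 36
       organ   dsc  asd_mm  hd95_mm  d_hotspot_dpd_pct  mdice
    duodenum 0.035   6.467   10.954              0.740  0.003
 large_bowel 0.074   6.268   11.899              8.666  0.042
 small_bowel 0.164   3.967   10.000              2.702  0.162
       liver 0.455   4.625   10.198              2.298  0.502
 left_kidney 0.317   3.599    6.633              3.513  0.276
right_kidney 0.335   3.376    7.483              9.172  0.270
      spleen 0.475   2.606    4.899             11.177  0.428
     stomach 0.354   3.918    8.865              2.325  0.365
spinal_canal 0.325   2.632    5.657              0.584  0.322
```

Here the "prediction" is simply the simulated later session's
ground-truth labels scored against session 1, so the numbers quantify
how much inter-fraction anatomical change the simulator injected: small
mobile structures (duodenum, bowel) move most, and dPD/mDice show how
those geometric changes would read dosimetrically near a 40 Gy target
placed at the duodenum. With two 2-session patients the pair law gives
2 × 2·1 = 4 ordered pairs and 4 × 9 = 36 conditioned cases.

The same pipeline is available from the shell:

```bash
fracaug phantom cohort --out cohort --seed 11 --patients P1:2,P2:2
fracaug condition build --registry cohort/registry.json --fold-root dataset --fold 0
fracaug evaluate --pred cohort/P1_s2_labels.nii.gz --gt cohort/P1_s1_labels.nii.gz
```

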