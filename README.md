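# meiotrack

4D chromosome-dynamics analysis for *C. elegans* meiosis-I oocytes.

During female meiosis I, six holocentric bivalents (pairs of homologous
chromosomes) must orient along the spindle axis, congress to the metaphase
plate, and segregate one homolog to each spindle pole. Kinetochore
perturbations disrupt each of these steps and produce aneuploid eggs.
`meiotrack` turns two-channel 3D+t recordings of such divisions — or tabular
XYZT point tracks exported from them — into quantitative per-chromosome
metrics, per-timepoint state classifications, anaphase segregation-fate
calls, ploidy verdicts, and an angle–fate association statistic. A
ground-truthed synthetic-cohort simulator stands in for raw microscopy, so
every stage of the pipeline is testable against known truth.

## The measurements

With pole positions **A**, **B** per frame, the spindle frame is the unit
long axis **u** = (**B** − **A**)/|**B** − **A**| and equator center
**m** = (**A** + **B**)/2. For a bivalent with homolog centroids **h₁**,
**h₂** (homolog 1 = nearer pole A at the first tracked frame) and center
**c** = (**h₁** + **h₂**)/2:

- orientation angle θ = arccos(**v**·**u**/|**v**|), **v** = **h₂** − **h₁**;
  the folded angle min(θ, 180° − θ) is used for classification, the labeled
  angle for detecting orientation reversions (crossings above 90°);
- congression distance d_eq = |(**c** − **m**)·**u**| (to the equator plane);
- compaction distance d_ax = |(**c** − **m**) − ((**c** − **m**)·**u**)**u**|
  (to the long axis);
- oscillation osc(t) = |d_eq(t + 10 s) − d_eq(t)|;
- stretching metrics from the four endpoint markers: homolog lengths,
  inter-homolog distance, and bivalent length (maximum pairwise endpoint
  distance).

A bivalent is *oriented* / *congressed* / *compacted* at a timepoint when the
relevant metric is at or below its threshold. The default thresholds are the
published control-cohort values — 22.5°, 0.5 µm and 1.6 µm — and
`calibrate_thresholds` re-derives them from any control cohort as the mean
over oocytes of the per-oocyte maximum (angle at anaphase onset; distances
over the metaphase window).

After anaphase onset each homolog's signed equator coordinate
s(t) = (**pos** − **m**)·**u** classifies the bivalent's fate: `normal`
(opposite sides, both cleared), `co_segregating` (same side — an
aneuploidy-generating error), `lagging_correct` / `lagging_missegregated`
(still near the equator at mid-anaphase, resolving to the correct or wrong
side). An oocyte is euploid iff no bivalent co-segregated or mis-segregated.
The link between the folded angle at onset and mis-segregation is quantified
by logistic regression with a seeded label-permutation test.

## Worked example

```python
import numpy as np
import meiotrack as mt

# control cohort: calibrate thresholds
cfg = mt.SyntheticCohortConfig(n_oocytes=20, seed=1)
tracks, truth = mt.simulate_cohort(cfg)
metrics = mt.compute_metrics(tracks)
cal = mt.calibrate_thresholds(metrics)
print(f"calibrated: theta_max = {cal.theta_max_deg:.1f} deg, "
      f"d_eq_max = {cal.d_eq_max_um:.2f} um, d_ax_max = {cal.d_ax_max_um:.2f} um")

# kinetochore-null cohort: classify fates and ploidy
kcfg = mt.SyntheticCohortConfig(n_oocytes=20,
                                preset=mt.PRESETS["knl1_null"], seed=2)
ktracks, ktruth = mt.simulate_cohort(kcfg)
kmetrics = mt.compute_metrics(ktracks)
at_onset = kmetrics[np.isclose(kmetrics["time_s"], 0.0)]
print(f"oriented at onset: "
      f"{100 * (at_onset.theta_folded_deg <= cal.theta_max_deg).mean():.1f}%")
fates, ploidy = mt.classify_fates(ktracks, metrics=kmetrics)
print(fates["fate"].value_counts().to_dict())
print(f"aneuploid oocytes: {100 * (ploidy.ploidy == 'aneuploid').mean():.0f}%")
assoc = mt.angle_fate_association(fates, seed=3)
print(f"logistic slope = {assoc['slope']:.3f} per degree, "
      f"permutation p = {assoc['p_value']:.2e}")
```

prints

```
calibrated: theta_max = 17.7 deg, d_eq_max = 0.51 um, d_ax_max = 1.64 um
oriented at onset: 65.8%
{'normal': 87, 'lagging_missegregated': 13, 'lagging_correct': 10, 'co_segregating': 10}
aneuploid oocytes: 75%
logistic slope = 0.079 per degree, permutation p = 1.00e-04
```

The control cohort calibrates close to the published thresholds; the
kinetochore-null preset loses orientation (65.8% oriented at onset vs ~94%
in controls), produces all three error categories, makes three quarters of
oocytes aneuploid, and shows a strongly positive angle–fate slope: bivalents
at higher angles at onset mis-segregate more often.

The same pipeline runs from a shell:

```sh
meiotrack simulate --preset knl1_null --n-oocytes 20 --seed 2 --out cohort/
meiotrack analyze --tracks cohort/tracks.csv --out cohort/metrics.csv
meiotrack classify --metrics cohort/metrics.csv --tracks cohort/tracks.csv \
    --seed 2 --out cohort/cls/
meiotrack report --metrics cohort/metrics.csv --out cohort/angles.svg
```

`meiotrack simulate --render` also writes two-channel TIFF stacks
(T×C×Z×Y×X with a YAML sidecar); `meiotrack pair` runs the full
image-to-tracks pipeline (LoG spot detection, tubulin-PCA pole localization,
mutual-nearest-neighbor linking with gap closing, minimum-distance homolog
pairing) and emits the same track-table schema as the simulator.

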