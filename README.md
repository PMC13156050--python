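# callothick

Corpus callosum (CC) thickness profiling and age-moderated group analysis.

Morphometric differences of the corpus callosum in psychiatric cohorts —
here, treatment-naïve first-episode schizophrenia (FES) versus healthy
controls — are often inconsistent across studies. One proposed resolution
is that the group difference is *age-dependent*: patients are thinner than
controls at younger ages and thicker at older ages, so studies that sample
different age ranges see different signs. `callothick` implements the full
analysis chain needed to test that hypothesis and to relate the
age-dependent thickness signal to symptom severity:

1. **Thickness profiling** (`callothick.thickness`). A 2-D binary
   midsagittal CC mask is split at its bottommost posterior and anterior
   extremities into a superior and an inferior contour. A harmonic
   potential ψ is solved between them (Laplace's equation, ψ = 0 inferior,
   ψ = 1 superior); the 0.5 equipotential is the callosal midline; at 100
   equal-arclength stations, streamlines are integrated along ∇ψ to both
   contours, and the streamline length in mm is the local thickness.
   Node 0 is posterior, node 99 anterior.
2. **Johnson–Neyman moderation** (`callothick.moderation`). Per node or
   region, OLS of thickness on group, age, group × age and nuisance
   covariates (sex, education years, total intracranial volume). The
   conditional group effect is θ(age) = b₁ + b₃·age with
   SE(age) = √(v₁₁ + 2·age·v₁₃ + age²·v₃₃); the JN boundaries — the ages
   at which |θ/SE| crosses the critical t — come from the closed-form
   quadratic. Pointwise scans over the 100 nodes are corrected with
   Benjamini–Hochberg FDR, and significant nodes aggregate into four
   Witelson-anchored regions (I: 73–78 rostral body, II: 51–72 midbody,
   III: 24–32 isthmus, IV: 13–23 splenium).
3. **PLSC** (`callothick.plsc`). Partial least squares correlation between
   the per-patient design X = [region thickness, age, thickness × age]
   (column-standardised) and PANSS-style symptom scores Y:
   R = XᵀY/(n−1), SVD R = U S Vᵀ, permutation p per latent variable
   (add-one rule), bootstrap ratios |BSR| > 2 per salience element,
   behaviour scores Y·V, BH-FDR across the four region-level analyses, and
   a JN follow-up of behaviour score ~ thickness × age.
4. **Synthetic cohorts** (`callothick.simulate`). Because the cohort the
   design mirrors is not publicly deposited, a first-class generator
   plants a known crossover group × age effect and a rank-1 brain–symptom
   latent, so every stage is testable end to end with known ground truth.
5. **Demographics and orchestration** (`callothick.demographics`,
   `callothick.pipeline`, `callothick` CLI). Welch/pooled t-tests and
   chi-square from raw rows *or* printed summaries, and a deterministic
   simulate → scan → regions → JN → PLSC → report pipeline with a JSON
   manifest.

## Worked example

```bash
python examples/02_simulate_and_scan.py
```

```
FDR-significant nodes: [13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23]
planted nodes:         [13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23]
region IV crossover estimate: 25.33 years (planted 25.0)
  ages 11.0-24.6: conditional group effect negative
  ages 24.6-26.0: conditional group effect ns
  ages 26.0-42.0: conditional group effect positive
```

A 400-subject synthetic cohort carries a planted patient-vs-control
difference on the splenium nodes that changes sign at 25 years. The
pointwise interaction scan recovers exactly the planted nodes after FDR;
the region-level JN analysis estimates the crossover at 25.3 years and
reports the two significance boundaries (24.6 and 26.0 years) that bracket
it: patients are significantly *thinner* below 24.6 years and
significantly *thicker* above 26.0.

`examples/01_thickness_from_mask.py` shows the solver recovering the known
4 mm thickness of a half-annulus mask at every node to within 1.5%;
`examples/03_plsc_symptoms.py` recovers a planted brain–symptom latent
(salience alignment 0.98, permutation p ≈ 0.001);
`examples/04_demographics_from_summaries.py` reproduces published-style
group statistics from printed summaries alone; and
`examples/05_full_pipeline.py` runs everything end to end into a run
directory with a report and manifest.

There is also a thin CLI:

```bash
callothick simulate --out sim/ --seed 1
callothick jn-scan --profiles sim/thickness_profiles.csv --cohort sim/cohort.csv --out scan.csv
callothick run --simulate --out run1/ --seed 1
```

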