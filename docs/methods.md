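# Methods

## Thickness model

The cross-sectional thickness model treats the CC on the midsagittal plane
as a ribbon between two contours. The closed outer boundary of the binary
mask is traced (Moore neighbourhood) and split at the two *bottommost
extremities* — the lowest boundary pixel within the posterior third of the
bounding box and the lowest within the anterior third, ties broken toward
the extreme column. The arc containing the topmost boundary pixel is the
superior contour; the other is the inferior contour; both are ordered
posterior → anterior and share the endpoints.

A discrete harmonic potential is solved on the foreground with Dirichlet
values 0 on the inferior contour and 1 on the superior contour (red–black
successive over-relaxation on the 5-point stencil, ω = 2/(1 + sin(π/N)),
tolerance 1e-6 on the maximum deviation of any free pixel from the mean of
its foreground neighbours; non-convergence raises with the final
residual). The callosal midline is the 0.5 level set (marching squares
with the background masked), ordered posterior → anterior; thickness is
measured at the midpoints of 100 equal-arclength bins by integrating the
normalised gradient (fixed-step RK2, 0.25 px, bilinear interpolation)
from each station to both contours and summing the two path lengths.
Thickness is therefore *streamline length*, not chord length; in
high-curvature zones the streamlines are genuinely curvilinear and the two
notions differ — a modelling choice, not an approximation.

### End caps

Where the superior and inferior contours converge (the posterior and
anterior junctions), clamping Dirichlet values right up to the junction
creates a boundary layer: the midline dives into the junction corner and
streamlines seeded nearby collapse. The solver therefore *insulates* the
junction faces: starting from the medial axis (skeleton, pruned to its
longest geodesic path and trimmed where the local half-width falls below
80% of its interior median), the boundary is walked from each endpoint in
both directions and pixels are left free — a natural zero-flux condition —
for as long as the boundary runs transverse to the medial direction
(|tangent · medial direction| < cos 45°). On a rectangular band this
insulates exactly the vertical sides and the discrete potential is exactly
linear; on a half-annulus it insulates the flat end faces and the polar
closed form ln(r/r₁)/ln(r₂/r₁) is recovered, making streamlines radial at
every node.

### Sub-pixel stop surfaces

A binary mask represents its boundary only to ±½ px, and the raw 0.5 level
of a lightly smoothed mask indicator oscillates by a few tenths of a pixel
with the pixel staircase. Each streamline leg is stopped at the geometric
boundary defined by an arclength-smoothed boundary polyline: the indicator
contour is resampled to uniform arclength, low-pass filtered (periodic
Gaussian, σ = 2.8 px along the contour), and pushed back out along its
normal by κσ²/2 to undo the curvature shrinkage of the filter. Segments
where the filter scale approaches the curvature radius (corners) are not
trusted, and there the leg falls back to the raw indicator crossing. Two
further guards keep grazing legs honest: a leg may only terminate once the
potential has essentially reached its target value (ψ ≥ 0.98 going up,
≤ 0.02 going down, or a decisive exit of the mask), and while unarmed a
step that would leave the mask is slid along the wall — the continuum
streamline never exits except at its target contour.

### Accuracy

Validated against the two closed-form fixtures at 0.25 mm pixels: every
node within 2% of truth (band 0.5%, half-annulus 1.5% worst node), and the
worst-node error decreases monotonically with pixel size (half-annulus:
4.4% at 0.5 mm, 1.5% at 0.25 mm, 0.9% at 0.125 mm). The 0.5 mm figure is a
floor imposed by mask quantisation — at 8 px thickness a half-pixel
staircase is already ~4% — not by the solver; profiles at 0.25 vs
0.125 mm agree node-wise within 1.8%. Stations that sit a fraction of a
pixel from a *sloped* end face (e.g. a 90°-extent arch) measure grazing
streamlines and can err by ~10% at the two extreme nodes; interior nodes
are unaffected. Numerical parameters (indicator smoothing σ = 1.0 px,
contour smoothing σ = 2.8 px, curvature trust 0.35 rad/σ, RK2 step
0.25 px) were fixed by validation against the analytic fixtures.

## Moderation and Johnson–Neyman

Per outcome, OLS of y on [1, X, M, X·M, covariates] with X the focal
predictor (group 0 = control / 1 = patient, or a continuous predictor) and
M the moderator (age in years, uncentred — centring changes b₁'s meaning
but not the JN solution). The conditional effect is θ(M) = b₁ + b₃M with
variance v₁₁ + 2Mv₁₃ + M²v₃₃ from the coefficient covariance σ̂²(XᵀX)⁻¹.
JN boundaries solve (t_c²v₃₃ − b₃²)M² + 2(t_c²v₁₃ − b₁b₃)M +
(t_c²v₁₁ − b₁²) = 0 with t_c the two-tailed critical value at the fit's
own residual df; real roots inside the observed moderator range partition
it into intervals labelled negative / not significant / positive from
θ at the interval midpoint. The solver is verified against a dense
(0.001-year) grid scan of the conditional-effect t statistic as an
independent oracle, and against a re-centring identity (θ(M) equals the
group coefficient after refitting with age − M).

The pointwise scan fits all 100 nodes in a single multi-RHS least-squares
solve (the design is shared), collects the interaction p-values, and
applies Benjamini–Hochberg across the 100 nodes; q ≤ 0.05 is the
significance mask. FDR is applied to the interaction scan only — the
conditional-effect p-values inside the JN step are not additionally
corrected. Region means average nodes within the inclusive Witelson-anchored
windows I = 73–78, II = 51–72, III = 24–32, IV = 13–23. At the region level
two multiplicity reports are available: the per-region JN solutions as-is,
and BH across the four region-level tests (`fdr_across_regions`).

## PLSC

X = [region thickness, age, interaction] per patient, where the
interaction column is the product of the standardised thickness and age
columns, itself re-standardised (bounding collinearity with the main
effects); Y holds the PANSS-style items plus the four factor scores,
z-scored by default (raw scores via a flag). R = XᵀY/(n−1) — the 1/(n−1)
scale makes R a cross-correlation matrix; the scale cancels in permutation
p-values and bootstrap ratios. SVD with a deterministic sign convention
(largest-magnitude element of each design salience positive).

Permutation test: rows of Y are permuted and the full model refit; the
default null compares the k-th permuted singular value with the k-th
observed one, p = (1 + #{S_k^perm ≥ S_k^obs})/(1 + n_perm) (never exactly
zero). A stricter maximum-statistic null (every observed value compared
with the largest permuted one) is available behind `collective=True`; the
per-rank reading is the default because it is the simplest defensible
interpretation of a collective null over all singular values.

Bootstrap: patients resampled with replacement, each resample
re-standardised and refit, saliences sign-aligned per LV to the observed
ones (reflection indeterminacy); BSR = observed salience / bootstrap SE,
|BSR| > 2 significant. Degenerate resamples (a constant column) are
redrawn and counted. Behaviour scores project symptom rows onto the
symptom-side saliences (scores = Y·V); their cross-products with the
design-side scores recover (n−1)·S — asserted as an identity test. The JN
follow-up models behaviour score ~ thickness × age with age as moderator;
the sensitivity variant adds illness duration, age of onset, sex and
education as covariates.

## Synthetic cohorts

The generator emulates the structure of an FES/control morphometry study;
defaults are the study-like conditions (151 patients, 278 controls, ages
uniform on 11–42, education and TIV normal with group-specific means/SDs
matching the demographic table the demographics module reproduces, sex
Bernoulli(½)). Node thickness = a fixed smooth baseline template (thick
splenium and genu humps, thinner isthmus dip; 4–9 mm, documented in
`baseline_profile`) + linear covariate effects (0.15 mm for male sex,
0.02 mm per education year, 0.001 mm per cm³ TIV — small, plausible-scale
nuisance structure) + the planted group effect slope·(age − a*) on the
affected nodes (default: splenium window 13–23, a* = 25 years,
slope 0.05 mm/year — chosen once as a moderate, detectable-at-n≈400
effect; no published effect sizes exist to calibrate against) + i.i.d.
Gaussian node noise (SD 0.5 mm).

Patient symptoms: 30 PANSS-style items (P1–P7, N1–N7, G1–G16) around a
mean of 3.5 with unit-variance-scale noise (SD 0.8), plus a planted rank-1
term v·ℓ where v is a fixed unit salience loading on negative and general
items and ℓ = s·η + √(1−s²)·ε with η the standardised thickness × age
interaction — so corr(ℓ, η) is exactly the configured latent strength s.
Items are clipped to the 1–7 PANSS range (a ≳3σ event; the slight
truncation is ignored). Four factor scores are uniform-weight means of
fixed item groups (positive / negative / affective / cognitive); the true
factor loadings of the four-factor model are not public, so uniform
weights are a documented simplification. A single `SeedSequence` is
spawned into demographics / thickness-noise / symptom streams so identical
seeds give byte-identical tables.

What the generator does **not** emulate: spatial noise correlation along
the profile, scanner/site effects, non-linear age trajectories,
segmentation failures, ordinal item distributions, or realistic symptom
factor structure. Passing tests therefore demonstrate correctness of the
estimators under the planted model, not robustness to those real-data
features.

## Demographics

Continuous variables use a two-sample t from (mean, SD, n) per group —
hence raw-data and summary modes agree exactly. Welch's unequal-variance
form is used when the larger/smaller sample-variance ratio reaches 1.30
(configurable), else the pooled form; the threshold reproduces the
apparent convention of the reference demographic table (its age row
matches Welch, its education and TIV rows match pooled, and the education
variance ratio of 1.27 sits just below the gate). Sex uses Pearson's
chi-square without continuity correction. Which t-variant the original
analysis used per row is not printed anywhere; the variance-ratio rule is
a documented inference.

## Problem sizes and determinism

Monte-Carlo checks use sizes chosen for tight-but-affordable calibration:
the null scan 200 replicate cohorts of 120 subjects (20 000 node-tests,
binomial 99% half-width ±0.4%), crossover recovery 100 cohorts of 400,
PLSC recovery 40 cohorts of 137 patients at 500 permutations, the JN/grid
oracle 1000 random fits at 0.001-year resolution. All randomness flows
from explicit seeds (`numpy` `SeedSequence`/`default_rng`); the pipeline
records seeds, configuration and package version in its manifest, and
rerunning any stage from the written CSVs reproduces the results.

## Known limitations

- Streamline thickness at the two extreme nodes is ill-defined when the
  end face is strongly sloped relative to the pixel grid (grazing
  stations); see the accuracy note above.
- The analytic-recovery guarantee is stated at 0.25 mm pixels; at 0.5 mm
  mask quantisation dominates for structures ≤ ~10 px thick.
- The moderation model is strictly linear in age (no quadratic terms, no
  mixed effects, no site harmonisation) and the PLSC is plain (no
  sparsity, no cross-validated prediction) — both by design.
- The endpoint rule ("bottommost extremities", ties toward the extreme
  column) assumes a roughly horizontal, downward-opening arch; shapes
  without bottom tips (a disk) still run, via the tie rule, but node
  indexing on such shapes is arbitrary.
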