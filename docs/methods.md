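# Methods

This note documents the models and numerical choices behind
`morphomotion`, the defaults that matter, and what the synthetic data do
and do not establish about real data.

## Box-counting fractal dimensionality

For a binary occupancy set, the box count `N(s)` at edge length `s` is
the number of axis-aligned boxes of an `s`-spaced grid containing at
least one occupied voxel; the dimensionality is the negated OLS slope of
`log2 N(s)` on `log2 s`. The OLS fit over all provided size points
reduces to the two-point Δlog ratio exactly when the points are
collinear, and the slope is computed in closed form
(`Σ dx·dy / Σ dx²`) rather than via a general least-squares solver so
that exactly collinear integer logs (filled cube, Menger sponge) return
the analytic dimension with no rounding residue. `fit_r2` of a constant
count series is defined as 1 (the flat line is an exact fit).

**Grid anchoring.** Grids tile all of space — a partial box overhanging
the array border counts — and are anchored at the corner of the occupied
bounding box, with the `offset` argument shifting the grid relative to
that anchor. Anchoring to the structure rather than the array makes
counts independent of how much padding surrounds the phantom, which is
what lets a padded filled 16³ cube count exactly (16/s)³ boxes at every
power-of-two size.

**Dilation variant.** Single-grid counts depend on grid alignment. The
dilation count is *defined* as the mean of the grid count over all `s³`
offsets; it is *computed* by dilating the occupancy set with a cube of
edge `s` (scipy binary dilation on an array padded by `s`) and dividing
the dilated voxel count by `s³`. The identity between the two is exact —
each dilated voxel marks one (offset, box) incidence — and is enforced
by test against the brute-force offset enumeration at tolerance 1e-9.
Only filled (solid) structures are supported; surface-only
dimensionality is out of scope.

Default sizes are {1, 2, 4, 8, 16}; triadic ladders {1, 3, 9, 27} suit
the Menger phantom, whose level-L construction has exactly 20^L voxels
and analytic dimension log 20 / log 3.

## Framewise displacement and motion rates

Rotations (rp-file columns 4–6) are converted to millimetres as arc
length on a sphere of radius 50 mm (default, configurable); framewise
displacement for each transition is the sum of the six absolute
parameter differences. The first `drop_initial = 5` volumes are
excluded, and the transition crossing the drop boundary is discarded so
excluded frames contribute nothing.

The scalar summary is `mean displacement per transition / TR × 60`
(mm/min). The per-time normalisation is a deliberate dialect: it is the
only reading that makes scans with different repetition times (rest
1.970 s vs movie 2.470 s) comparable, which the rest-vs-movie contrast
requires. Group time-courses average the per-transition series across
subjects with a normal-approximation 95% band (mean ± 1.96 SE;
Student-t quantiles available for small groups), timestamped on the
full-trace clock so stimulus events keep their real latencies.

The rp-file angle unit has **no default** anywhere in the package.
rp files conventionally store radians, but preprocessed data releases
sometimes re-export degrees, and a silent mix-up scales rotational
displacement by ~57×; the reader and CLI therefore force the caller to
state the unit.

## Average edge strength

The AES literature names a toolbox rather than a formula, so this
package fixes a deterministic dialect and documents it as such:

* normalise intensities by the 99th percentile of nonzero voxels
  (robust to hot voxels) and clip to [0, 1] — AES becomes invariant to
  global intensity scaling;
* detect edge pixels per 2D slice with a Canny detector, smoothing
  σ = 1 px, hysteresis thresholds 0.1/0.2 in normalised units;
* measure the central-difference gradient magnitude (one-sided at
  borders) and average it over edge pixels — a clean unit step yields
  exactly (1−0)/2 = 0.5;
* skip slices with no detected edges (background-only slices would
  dilute the metric), and combine the rest weighted by edge-pixel count
  (`slice_weighting="uniform"` gives the unweighted alternative, since
  the original toolbox's choice is unknown).

This dialect preserves the operative property — blur strictly lowers
AES, verified on a shell phantom over σ ∈ {0,…,4} in all three planes —
without claiming bit-level replication of any particular toolbox.
`apply_blur` uses reflective boundaries, conserving total intensity.

## The hierarchical model comparison

Eight linear models per morphology outcome: age; BMI; age+BMI;
age+motion(rest); age+motion(movie); the movie model plus its
age-interaction; age+AES(axial); and that plus its age-interaction.
Interaction columns are products of mean-centred main effects (reduces
collinearity with the mains; centring is a package choice). Fits are
ordinary least squares (statsmodels) after listwise deletion of rows
missing any involved variable; rank-deficient designs raise with the
offending column list.

BIC uses the least-squares form `n·ln(RSS/n) + p·ln(n)` with `p`
counting intercept and slope terms; the error-variance parameter and
the Gaussian constant are shared by all compared models and drop out of
ΔBIC (verified against statsmodels' likelihood-based BIC up to that
constant). Because BIC is not comparable across different data rows,
models requiring BMI (fit on the BMI-complete subset) form their own
ΔBIC set by default; `paper_compat=True` forces the classic all-eight
table and warns. ΔBIC < 2 is flagged as model equivalence. Pearson
p-values are computable but never used for gating; the package's checks
are estimation-based.

## The synthetic cohort generator

The generator emulates the statistical structure of a lifespan ageing
study at n = 640: age uniform on [18, 88]; BMI Gaussian
(mean 26.5, SD 4.4) with age correlation .274 and 81/640 ≈ 12.7% of
values missing; motion rates lognormal with rest mean 3.1 mm/min,
rest − movie mean difference 1.528 mm/min, paired Cohen's d 0.99, and
raw-scale correlation targets age↔rest .351, age↔movie .430, BMI↔rest
.456, BMI↔movie .335, rest↔movie .484; AES loads on age (.493 axial,
.525 sagittal, −.131 coronal, axial↔sagittal .702) and is independent
of motion given age, mirroring the observed dissociation between
image-derived and fMRI-derived motion estimates.

Motion is generated on the log scale — matching the right-skewed,
log-axis presentation typical of motion data and guaranteeing
positivity. Because correlations of lognormal variables attenuate
relative to their Gaussian latents, the latent loadings are calibrated
analytically: a Gaussian variable at latent correlation ρ with the log
shows raw correlation `ρσ/√(e^{σ²}−1)`, and two lognormals at latent ρ
show `(e^{ρσ²}−1)/(e^{σ²}−1)`; both maps are inverted so the *raw*
correlations land on target (infeasible requests raise). The common
log-SD σ = 0.5294 is itself solved from the contrast targets
(mean difference, Cohen's d, inter-scan correlation) rather than chosen
freely. Across 100 seeds at n = 640, all correlation targets are
recovered within ±0.01 on average.

Morphology outcomes are linear:
`outcome = intercept + slope_age·age + slope_motion·motion_movie + ε`,
with age slopes −0.00432 mm/yr (thickness), −0.00097/yr (fractal
dimensionality), −0.00372/yr (gyrification) and movie-motion effects
−0.0135 mm/(mm/min), −0.003/(mm/min), −0.012/(mm/min). The motion
effect attaches to the movie scan because the movie-motion model is the
structure of interest in the comparison. The two smaller motion effects
are package choices scaled to keep the motion-to-age contribution ratio
comparable to thickness's.

**Noise SDs and statistical power.** The residual SDs (0.05 mm
thickness, 0.012 FD, 0.05 GI) are set so the design has high power
(noncentrality ≈ 20–30) to identify the generating model by BIC at
n = 640 — the point of the recovery tests is that the machinery finds
the right model when one exists. This makes simulated R² values
(≈ 0.7–0.8 for thickness) higher than those typical of real cohorts
(≈ 0.4), where residual anatomy dominates. Consequently, passing
model-recovery tests demonstrates correctness of the estimator and
comparison machinery, not that real effects of this size are always
detectable in real noise.

Synthetic realignment traces are random walks with half-normal
increment magnitudes, the first five transitions inflated 5× (the
scan-start artefact the drop rule exists for) and single-transition 10×
bursts at requested spike times. They reproduce the *features* the
motion pipeline must handle — settling frames, stimulus-locked spikes,
group-level rate differences — not the spectral content of real head
motion, nor k-space artefacts, nor any anatomy; AES-vs-motion coupling
is likewise injected statistically in the cohort, not simulated
physically.

## Problem sizes and runtime choices

Test and acceptance runs use phantom arrays ≤ 81³, traces of 210–264
frames, cohorts of n = 640, and 50–100 simulation seeds; these sizes
give sampling error comfortably inside every asserted tolerance while
keeping the whole suite in the minutes range on one CPU. Oracle
equivalences (dilation vs offset mean; displacement vs double-loop sum)
are asserted at 1e-9 or tighter since they are exact identities.

## Known limitations

* Only filled-structure FD; no surface FD or multifractal spectra.
* AES is a documented dialect, not a replication of any released
  toolbox; absolute AES values are not comparable across dialects.
* No volume realignment, DVARS, scrubbing, skull stripping, or surface
  reconstruction — the pipeline starts from rp files and (already
  masked) volumes.
* The cohort generator draws sex but models no sex effects, and its
  lognormal motion family is a modelling choice, not an empirical fit.
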