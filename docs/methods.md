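# Methods

## Phantom model

A cell phantom is an axis-aligned ellipsoid of cytoplasm RI containing a
concentric ellipsoid nucleus (semi-axes a fixed fraction of the cell's),
embedded in medium RI, on a regular voxel grid with physical spacing in µm.
Membership is decided at voxel centers: a voxel belongs to a compartment iff
its center lies inside the ellipsoid.  This rule is unambiguous, exactly
reproducible by a brute-force lattice-point count, and makes volume,
translation (by whole voxels), and axis-aligned rotation tests exact rather
than approximate.  Optional i.i.d. Gaussian RI noise (default sd 0.002, a
realistic reconstruction-noise scale relative to the ~0.02 cell–medium
contrast) is added last and clipped below at RI 1.0.

Peripherally displaced dense material — the survivor/non-survivor contrast —
is modelled as a rim band of the cytoplasm (normalized ellipsoidal radius
0.72–0.95) whose RI is raised linearly from cytoplasm toward nucleus RI by a
weight in [0, 1].  Weight 0 leaves the cytoplasm homogeneous.

All RI values are validated to lie in [1.30, 1.45]; defaults are medium
1.337 (saline), cytoplasm 1.356, nucleus 1.385, straddling the nuclear
threshold 1.38.

## Synthetic cohort

Four status groups: healthy controls (H) and sepsis time points T1/T2/T3,
with T1 split into survivors and non-survivors.  The default layout mirrors
a small clinical cohort (20 healthy subjects, 8 sepsis subjects per time
point, tens to hundreds of cells per group).  Group effects are a radius
scale, an additive RI offset, and a peripheral weight; the defaults order
the groups T1 > T2 > T3 ≈ H in size and RI and give non-survivors at T1 the
higher peripheral weight.  No measured effect magnitudes exist for these
contrasts, so the defaults encode direction with magnitudes chosen once to
be comfortably detectable at ~100 cells/group; analyses in this package test
recovery of *configured* values, not agreement with clinical measurements.

Subject-level random effects are Gaussian on log-radius (sd 0.04, keeping
radii positive) and additive on RI (sd 0.0015); cells add smaller jitter of
the same form (0.03 / 0.0008).  With group effects zeroed and one cell per
subject, downstream tests reject at their nominal level (verified by
simulation).

Clinical covariates (CRP, WBC, neutrophil %, lymphocyte %, CCL2/MCP-1,
IL-10, IL-2, TNF-α) are per-subject values `a · (subject mean RI) + ε`.  The
slope and noise variance follow in closed form from the target correlation ρ
and the marginal sd; the noise is additionally orthogonalized against the
latent RI in-sample, so the realized Pearson correlation equals the target
exactly (up to degeneracies at fewer than three subjects).  The lymphocyte
percentage carries a negative target by default — it rises during recovery
while the inflammatory markers fall.

What the generator does **not** emulate: optical diffraction and
missing-cone reconstruction artifacts, organelle texture, irregular cell
shapes, and imaging drift.  Passing tests therefore demonstrate correctness
of the analysis pipeline under the stated statistical structure, not
robustness to real instrument physics.

## Quality control

The study this models filtered images manually; here an automated, pure
function stands in.  A volume is rejected when (i) more than one connected
foreground component exceeds 20% of the largest (adjoined cells), (ii) the
largest component touches the volume border (truncated cell), or (iii) the
foreground fraction falls outside [0.1%, 60%].  Thresholds are configurable;
the defaults are stated choices, not inferred from data.

## Morphometry

Segmentation thresholds RI at `τ_seg` (default `medium + 0.005`, robust to
noise sd ≤ 0.002) and keeps the largest 26-connected component.  Features:

- `V = N_vox · v_z v_y v_x` in fL;
- `C = 100 (⟨n⟩_cell − n_m)/α` in g/dL, with `α` defaulting to 0.19 mL/g
  (the protein refraction increment range is 0.18–0.21; the value is a
  convention, so it is configurable);
- `m = C·V·10⁻²` in pg, stored to hold exactly;
- overall and nuclear (RI > 1.38) mean RI.

Mean-RI features are measured on the central cross-section through the cell
centroid by default, because that is how sectional color maps are read in
practice; a full-3D variant (`feature_space="full_3d"`) exists for
sensitivity analysis — on zero-noise phantoms the two differ only through
the nucleus/cytoplasm area-vs-volume weighting.  The cell center is the mask
centroid (real-valued); the radius is the maximum centroid-to-voxel
distance, computed in physical units by default so anisotropic spacings are
handled.  RI means use float64 accumulation over the float32 volumes.

## Shell analysis

The section's pixels are ranked by Euclidean distance from the cell center
(physical units, so anisotropic spacing yields elliptical iso-distance
contours) and the ranked list is cut into eight contiguous blocks whose
sizes differ by at most one; a remainder of r pixels gives one extra pixel
to each of the r innermost shells.  Distance ties are broken by row-major
pixel index via a stable sort — deterministic and documented.  The shell
density is the fraction of pixels above a threshold: the segmentation
threshold for the "overall" component, 1.38 for the "nuclear" component.

Two analysis modes exist because the operative definition ("sort all the
voxels") does not say whether background pixels participate: the default
ranks the full rectangular section; `restrict_to_cell=True` ranks only
in-mask pixels.  Background dilutes outer-shell densities in the default
mode, which is why a larger cell raises mid/outer-shell densities — the
contrast the group comparisons pick up.

Two useful exact properties: the partition equals an independent
sort-and-split construction, and any indicator that is non-increasing in
distance yields a non-increasing density profile d₁ ≥ … ≥ d₈.

## Cohort statistics

One-way ANOVA across the status groups per feature, with all-pairs
post-hoc Student's t-tests (pooled variance — the classical form; Welch via
a flag) and Bonferroni adjustment `min(1, m·p)` over the pairs.  Per-shell
families run an 8-shell ANOVA across H/T1/T2/T3 and an 8-shell
survivor-vs-non-survivor t-test within T1, each family Bonferroni-corrected
over its shells.  Degenerate inputs are conventions, not errors: zero
within-group variance reports F = ∞, p = 0 when means differ and F = 0,
p = 1 when all values are identical; zero pooled variance flags the pair as
degenerate.  Significance stars follow * < 0.05, ** < 0.01, *** < 0.001.

The unit of analysis is the cell, matching per-cell boxplot practice; this
ignores within-subject correlation, so a per-subject aggregation mode is
provided (off by default) for sensitivity checks.  Feature–covariate
correlation defaults to pairing per-time-point means (3–4 points — tiny n,
interpret descriptively); a per-subject mode pairs subject means.

## Classifier

Preprocessing: each cell is centre-cropped to its own bounding box (center ±
radius per axis, padded with medium RI where the box leaves the volume),
min–max normalized per image (a constant crop maps to zeros by convention),
and trilinearly resized to a fixed target — by default the per-axis median
of the training-set crop shapes, rounded to the network's pooling
granularity and frozen before training.

The model is a DenseNet-style 3D network — stem convolution, four dense
blocks (each layer BN → ReLU → 3×3×3 conv on the concatenation of all
earlier features), 1×1×1 compression transitions with 2× average pooling,
global-average-pool head — implemented directly in NumPy with explicit
im2col convolutions and analytic gradients.  The implementation is verified
against central-difference gradients layer-by-layer and end-to-end.  The
desk-scale default (8 dense layers, growth 4, 16³ inputs) trains in well
under a minute per run on one CPU; a full-scale 82-layer configuration is
expressible in `ModelConfig` but is not exercised by the test suite.

Training: cross-entropy, SGD with momentum 0.9, cosine-annealed learning
rate (protocol default lr₀ = 0.001 with period 64; desk runs raise lr₀ to
0.05 and cap epochs), batch size 16, per-epoch augmentation by random
axis-aligned 90° rotations and flips (interpolation-free by default),
8:1:1 train/val/test split, early stopping on validation loss with patience
30 (desk: 8), restoring the best epoch's parameters.  Splits are cell-level
by default, reproducing common practice; a by-subject split is provided
because cell-level splitting risks subject leakage when cohorts are small —
with class-pure subjects it needs at least two subjects per partition.

Evaluation: the few-cell bootstrap.  Per iteration, k cells are sampled per
subject (without replacement when enough cells exist, with replacement
otherwise) and their positive-class probabilities averaged (majority vote
via a flag) into one score per subject; AUROC is computed across subjects by
pairwise concordance with ties 0.5, and the 95% CI is the 2.5/97.5
percentile over 1000 iterations.  Without subject ids each class is a
single sampling unit, so per-iteration AUROC takes values in {0, ½, 1} and
the mean over iterations estimates the aggregated concordance probability.
The permuted-label control is evaluated at k = 1 with class units: its CI
excludes 0.5 only under near-perfect discrimination, which is exactly what a
label-permuted model must not achieve — aggregation over k > 1 cells would
amplify the residual chance correlation a finite permutation retains with
the true labels and turn the control into a coin flip.

Grad-CAM saliency backpropagates a class logit to a chosen dense block's
feature maps (last by default), weights channels by spatially averaged
gradients, rectifies, upsamples trilinearly, and max-normalizes to 1.  A
constant input returns an all-zero map.  At 16³ inputs the last block is
spatially 2³, too coarse to localize; the first block (8³) is the useful
choice there and is what the localization test uses.

## Orchestration and problem sizes

`pipeline.run_all` executes simulate → qc → extract → shells → stats →
train → eval from one config; per-stage seeds derive from the single global
seed by fixed offsets, and a JSON manifest (config hash, seeds, outputs,
timings) lets completed table-producing stages be skipped on re-run.

Problem sizes used throughout the tests and the acceptance script are desk
scale, chosen so the full suite runs in a few minutes while keeping every
statistical check well-powered: grids of 24³–64³ voxels at 0.2 µm spacing,
cohorts of 100–240 cells, 10–200 subjects, classifier inputs resized to
16³, and 300–1000 bootstrap iterations.  All randomness flows through
seeded `numpy.random.default_rng` generators; identical configs and seeds
reproduce every table byte-for-byte.

## Known limitations

- Phantoms are piecewise-constant ellipsoids; none of the texture,
  aberration, or reconstruction physics of real holotomography is modelled.
- The nuclear-component proxy (RI > 1.38) shares its threshold between
  simulation and analysis; real nuclei are not uniform-RI ellipsoids.
- Cell-level statistics ignore within-subject correlation (the subject-level
  mode exists but is not the default, to match common practice).
- The per-time-point correlation mode pairs 3–4 aggregate points; its ρ
  values are descriptive, not inferential.
- The NumPy network is single-threaded BLAS-bound; it is sized for 16³–32³
  inputs, not for full-resolution volumes.
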