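# Methods

This note documents the models, conventions and design choices behind
`lesionmeter`: what each stage assumes, which knobs matter, and what the
phantom-based validation does and does not demonstrate.

## Measurement model

The unidirectional (longest in-plane diameter) measurement is recast as
scale estimation through binary classification. For a lesion of diameter
`d` cm at pixel spacing `s` cm/px, the pixel size is `M_px = d/s` and
the canonical magnification `32/M_px` renders it at exactly 32 px inside
a 128×128 frame (one quarter of the frame side). A classifier `f`
returning `P(apparent size > 32 px | frame)` then defines the
measurement implicitly: if `f` flips at magnification `m*`, the lesion
spans `32/m*` pixels, i.e. `d̂ = (32/m*)·s`.

The identity `d̂ · m* / s = 32` is maintained exactly in every reported
result; it couples the three public quantities and is tested to 1e-9.

Assumptions:

* the lesion is brighter than its local background at display
  windowing, and the seed point lies inside it;
* pixels are square (the reader enforces this by resampling non-square
  inputs to the finer spacing, bicubic);
* the true size lies within the ladder range — sizes outside
  [min_size, max_size] are flagged `out_of_range`, not guessed.

## Scale search

`LadderConfig` defaults: 16 rungs, hypothesized sizes 1.0–5.5 cm on a
**geometric** grid. Geometric spacing makes the rung-to-rung step a
constant *relative* size change (~12% at 16 rungs), matching the percent
scale on which agreement is later judged. Per rung the windowed slice is
rescaled (bicubic; `scipy.ndimage.zoom` with grid-cell semantics, so
distances scale by the magnification), the seed is mapped with
round-half-away-from-zero, and a 128×128 frame is cropped with
air-value padding (0.0 after windowing).

Flip localization fits the 16 probabilities with isotonic regression
over log-magnification — the least-squares monotone reconstruction — and
interpolates the 0.5-crossing linearly between the bracketing rungs.
Isotonic projection is the principled way to resolve non-monotone
(noisy) label sequences; on already-monotone responses it is a no-op and
the flip reduces to plain first-crossing detection. Its crossing is
verified in the tests against an exhaustive search over all monotone
step functions (every block partition, depth-first with pruning), which
is the same projection computed without any isotonic machinery.

When `refine` is on (default), the bracketing interval is bisected in
log-magnification — each midpoint is one extra classifier query — until
the implied apparent-size uncertainty is below `refine_tol_px`
(0.25 px, i.e. ~0.8% relative). 16 rungs alone resolve ~6% relative
(half a geometric step); refinement is what brings the oracle-classifier
error below 1%. All-SMALLER / all-LARGER sequences clamp to the ladder
end with an `out_of_range` flag; an `interpolate=False` option snaps to
the nearest rung instead of interpolating, for comparison.

## Frames, augmentation, labels

`M_px` conversions and the canonical magnification are pure arithmetic
(`cm_to_pixels`, `canonical_magnification`). Training frames perturb the
canonical state: zoom factors `z` on a geometric grid over [0.5, 2.0]
(apparent sizes 16–64 px, symmetric about the boundary in log-scale) and
per-axis uniform integer shifts up to 32 px (off-center resilience; the
seed never leaves the frame). The apparent size of a zoomed frame is
`z·32` px by construction, so labels are exact: LARGER iff apparent
size > 32 px, ties (exactly 32) break to LARGER by convention. Frames
within `exclusion_band_px` (default 0.5 px) of the boundary are dropped
— their labels would be meaningless at rasterization precision. With
`balance` enabled the majority class is subsampled (seeded) to give
exactly equal SMALLER/LARGER counts, the structure a balanced training
corpus should have.

## The size classifier

Two implementations sit behind one contract (`predict_prob: Frame →
[0,1]`, pure):

**Analytic oracle.** Ground truth apparent size comes from a lookup
(for phantoms: `(d/s)·magnification`, exact arithmetic); hard variant
thresholds at 32 px, soft variant is a logistic in (apparent − 32) with
configurable slope — monotone, 0.5 at the boundary. The oracle isolates
the scale-search machinery from perception: with it, measurement error
is pure search resolution.

**Trainable reference model.** A deliberately small, CPU-trainable
network: a *fixed geometric front end* — the 4×4 average-pooled patch
(1024 features) concatenated with max-projection profiles at 8
orientations (64 bins each, light Gaussian pre-smooth; 512 features) —
feeding a 128-unit single-hidden-layer network (scikit-learn
`MLPClassifier`, adam, learning rate 3e-3). The projection profiles
expose directional extents, which is what a longest-diameter decision
needs and what plain pooled pixels encode only weakly at this training
scale; the pre-smooth keeps single noise pixels out of the max. Features
are standardized with statistics frozen from the training set (this also
removed a training-divergence failure mode observed with raw features).

Training follows a fixed protocol: 500 mini-batch updates of batch 32
(samples drawn with replacement, seeded), validation accuracy evaluated
every 10 updates, and the checkpoint with the highest validation
accuracy returned (earliest on ties). "Iteration" means one parameter
update. The protocol, seed and best-validation statistics are stored in
the model metadata.

For deployment the package provides a cascade wrapper combining three
independently-seeded members; the default soft vote averages
probabilities (keeping the combined response smooth for interpolation),
a hard majority vote is available. The cascade damps the residual
calibration wobble between individual 500-iteration runs.

## Phantoms

Phantoms exist so every stage can be tested against exact ground truth.
A lesion mask is built analytically at the requested diameter: smooth
ellipse (aspect ratio 0.4–1, arbitrary rotation), spiculated mass (base
ellipse plus triangular spikes; two opposite spikes reach the full
radius so the tip-to-tip chord is the requested diameter), adjacent pair
(two disjoint lobes whose outer tips span the diameter, each lobe
strictly smaller — the classic merged-lesions failure substrate), and
central density (ellipse with a brighter core). The recorded
`true_diameter_cm` is the **exact longest chord over mask pixel centers**
(convex hull + pairwise over hull vertices), so it can differ from the
requested value by a fraction of a pixel: ground truth is what a perfect
reader of the rasterized image could measure. An independent all-pairs
oracle in the tests confirms the chord for every shape family.

Rendering uses an HU-like linear scale: background −700 with smoothed
correlated texture (SD 30, correlation ~3 px), lesion 20 (core +60),
then white noise (default SD 40) and rounding to integers. The lesion
sits ≥5 noise SDs above background before noise — a figure/ground
contrast assumption, checked at synthesis. Intensities are arbitrary
but windowed downstream with a conventional lung window (center −600,
width 1500) when no tags are present.

Cohort sampling draws diameters and spacings uniformly (defaults
1.37–5.44 cm and 0.051–0.137 cm/px, the measurement range and in-plane
resolutions typical of public lung-CT collections), cycles the four
shape families, and attaches the six invasion-type group labels
round-robin. The labels are deliberately arbitrary — phantoms have no
anatomy — and exist to exercise the group-comparison statistics, not to
model invasion. Sampling is bit-reproducible from a master seed
(per-case child seeds via `SeedSequence.spawn`).

What phantoms do **not** emulate: anatomical context (vessels, pleura,
atelectasis), 3-D partial-volume effects, contrast phases, or reader
disagreement about what counts as lesion boundary. Passing the phantom
suite therefore demonstrates the *mechanics* — framing, search,
statistics, and the learnability of the 32-px decision at realistic
noise — not clinical performance.

## Agreement statistics

* Percent difference: `200·(m_dl − m_human)/(m_dl + m_human)` —
  symmetric in the pair mean, antisymmetric under reader swap, bounded
  in (−200, 200).
* Bland-Altman: mean and sample SD (n−1) of percent differences; limits
  of agreement at mean ± 1.96·SD; outliers are pairs strictly outside
  the closed interval.
* Pixel differences: `|m_dl − m_human|/s`, mean and sample SD; a signed
  variant is available. The companion conversion
  `100·(diff_px·s)/size` makes explicit why pixel scores flatter
  large-lesion datasets (5 px is 10% of a 5 cm lesion but 25% of a 2 cm
  one).
* ICC(2,1): two-way random effects, absolute agreement, single
  measurement, computed from the ANOVA mean squares; 95% CI by the
  standard F-based method with Satterthwaite degrees of freedom. The
  single-measurement absolute-agreement form is the one that penalizes
  systematic bias between readers, which is the property of interest
  when comparing an algorithm to a human. Degenerate inputs: an
  all-identical matrix reports ICC 1 with a degenerate flag; identical
  raters with varying targets give exactly 1. Cross-checked in tests
  against an explicit sums-of-squares implementation (1e-10) and
  against pingouin's ICC(A,1).
* Group comparisons: Welch's unequal-variance t-test on signed percent
  errors for every unordered group pair, Bonferroni adjustment
  `min(1, p·n_pairs)`, significance at adjusted p < 0.05. Welch is used
  because group sizes and variances differ by construction; groups with
  fewer than two observations are skipped.

## End-to-end study conditions

The acceptance workflow (`workflows.run_end_to_end`) fixes the study
conditions: 120 training + 30 validation phantoms, 100 held-out test
phantoms, diameters 1.5–5.0 cm, spacings 0.06–0.13 cm/px, noise SD 40;
augmentation 32 frames/image for training and 16 for validation, shifts
up to 24 px; the three-member soft-vote cascade trained at the standard
protocol (500 × 32). Measured against exact truths this yields ICC
≈ 0.95–0.96 with a systematic difference within ±5% and a mean pixel
difference of 2–3 px, varying a little with the cohort/training seed.
The cohort sizes were chosen to keep the full study in a few minutes on
one CPU; they are study conditions, not tuned quantities.

## Numerical conventions and edge cases

* Coordinates are 0-based `(row, col)` everywhere.
* DICOM PixelSpacing (mm) ↔ internal cm; rescale slope/intercept
  applied on read; phantom DICOMs round-trip bit-exactly (int16,
  identity rescale).
* Mask inclusion uses a 1e-9 relative slack so pixels at exactly the
  nominal radius survive floating-point division.
* Windowing: `clip((p − (c − w/2))/w, 0, 1)`; idempotent on normalized
  input with the unit window.
* Resampling: output dimensions `round(shape × magnification)`; the
  fast seed-centered path pre-crops a sufficient window before zooming
  and is equivalent to full-image resampling up to the global spline
  prefilter (≤1e-5) and far-boundary padding.
* Exactly-32-px frames: dropped by the default exclusion band; with a
  zero band the tie labels LARGER (fixed, documented, arbitrary).

## Known limitations

* The longest diameter of a *non-convex* lesion (deep spiculation,
  adjacent pair) is a property of two boundary points the classifier
  never sees explicitly; the learned model approximates it from
  appearance, and per-shape biases of a few percent remain at this
  training scale.
* The method is semi-automatic by design: seed selection, and hence
  which of several lesions is measured, is the operator's
  responsibility. Adjacent lesions in one frame can be merged into one
  measurement — reproduced, not solved, here.
* No endpoint coordinates are produced, only the scalar diameter; the
  flip magnification localizes scale, not direction.
* Trained-model persistence uses pickle; artifacts are
  environment-bound and not a distribution format.
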