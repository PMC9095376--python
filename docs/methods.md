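# Methods

## Scope and data model

`ctaseg` segments bright tubular structures (contrast-filled vessels) in
3D CT-angiography-like volumes.  Arrays are indexed `(z, y, x)` with `z`
the axial slice index; `spacing` is per-axis voxel size in mm, and all
geometric parameters (scales, radii, drift tolerances) are physical
(mm), converted to voxel units through the spacing.  Masks are strict
{0, 1} volumes.  NIfTI is the canonical on-disk format, with MetaImage,
NRRD and raw `.npy` (spacing defaults to 1 mm isotropic, with a warning)
as alternates; SimpleITK handles all header I/O.

## Scale-space Hessian

Second derivatives at scale ω are computed by separable correlation with
sampled Gaussian-derivative kernels (per-axis voxel sigma = ω /
spacing), truncated at 4σ.  The sampled kernels are corrected for
*polynomial exactness*: the smoothing kernel has unit mass, the
first-derivative kernel zero mass and exact unit response on a ramp, and
the second-derivative kernel zero mass, no odd residue, and exact unit
response on x²/2.  Without the zero-mass correction the truncation
residue (~e⁻⁸) makes a constant image produce a non-zero "second
derivative", which downstream turns into spurious vesselness; with it, a
flat volume has an exactly zero Hessian.  An intensity offset (the
volume minimum) is subtracted before filtering — derivatives are
invariant to it, and it makes the constant-volume case exact in floating
point as well.  Boundaries use edge replication (`nearest`), so tubes
running out of the field of view behave like infinite tubes; `reflect`
is available.

Derivatives are γ-normalised: each component is multiplied by ω^γ with
default γ = 2.  For a Gaussian-profile tube of cross-sectional standard
deviation s this puts the maximum normalised axial response exactly at
ω = s (closed form: the smoothed profile is Gaussian with variance
s² + ω², so the normalised curvature is ω² s²/(s² + ω²)², maximal at
ω = s).  For a hard-edged (top-hat) tube of radius r the maximum is at
ω = r/√2 instead — a property of the profile, not an implementation
artifact (derivable via the Hankel transform of the disc indicator).

Eigenvalues are sorted by magnitude, |λ₁| ≤ |λ₂| ≤ |λ₃|, ties broken by
signed value ascending; eigenvectors are column-matched and unit norm.
The ordering is by "intensity" (magnitude) because the vesselness ratios
require λ₃ to be the strongest curvature regardless of sign.

## Vesselness

The score is zero wherever λ₂ > 0 or λ₃ > 0 (dark-on-bright polarity; a
`polarity="dark"` flag negates the volume for dark vessels) or where the
structureness W is at the numerical floor, and otherwise

v = (1 − exp(−S_B²/2α²)) · exp(−S_C²/2β²) · (1 − exp(−W²/2ε²)),

with S_B = |λ₂|/|λ₃|, S_C = |λ₁|/√(|λ₂λ₃|) (magnitudes throughout —
signed ratios would be imaginary when λ₂λ₃ < 0), and W the Frobenius
norm of the eigenvalue vector.  Flat voxels (|λ₃| = 0) define all three
ratios as 0.  Each factor lies in [0, 1], so v does.

Parameter defaults and rationale:

- **α = β = 0.5** — the standard sensitivity choices for the
  plate/blob discriminants; both dimensionless and contrast-free.
- **ε = HALF_MAX_NORM** — data-driven: half the maximum W.  W scales
  with image contrast, so no fixed number transfers across
  acquisitions.  In multiscale fusion ε is resolved **once over the
  whole scale ensemble**, not per scale.  This matters: a per-scale ε
  renormalises every scale by its own strongest structure, which
  cancels the γ-normalisation at the dominant structure's axis (the
  W-factor saturates at every scale) and destroys scale selectivity —
  the per-voxel argmax then degenerates to the tie-break.  With one ε
  shared across scales, v is monotone in the normalised W at each
  voxel and the winning scale tracks the local radius.
- **scale grid** — log-spaced; the generic default is max(spacing) to
  4 mm in 5 steps (coronary calibre).  The grid must span the radii of
  the structures actually sought: segmenting the ascending aorta
  (~15 mm) requires scales up to that radius, since at coronary scales
  a large vessel's interior is flat and produces no response at all.
  The phantom suite therefore attaches a grid to each phantom.
- **fusion** — voxelwise maximum over scales, smallest scale winning
  ties (favours thin-structure attribution); `best_scale` records the
  argmax and defaults to the smallest scale where v = 0.
- **numerical floor** — voxels with W below 1e-10 · max|I| · ω^γ /
  min(spacing)² are treated as structureless.  Round-off dust from
  near-zero Hessians otherwise forms random eigenvalue ratios that can
  score up to ~0.1 on constant volumes.

## Seeding

The ascending aorta is found with a circle Hough transform per axial
slice.  Each slice is binarised at 10% of the volume-wide maximum (the
*support* of the structure) before Canny edge detection: the enhanced
response of a large vessel fades gradually, and its raw gradient ring
sits well inside the anatomical radius that the search range (default
10–20 mm, 0.5 mm accumulator steps) encodes.  Accumulator scores are the
fraction of the circle's circumference that voted; detections below 0.25
are dropped, and near-concentric detections at neighbouring radii are
deduplicated by centre distance.  Detections are linked into chains
whose centres stay within a 5 mm drift across consecutive slices; the
chain of length ≥ 3 with the highest summed score wins, and the seed is
the centre voxel of its middle slice.  If no chain exists, a
`SeedingError` instructs the caller to pass a manual seed
(`--seed z,y,x`).  By default Hough runs on the enhanced volume
("enhanced images of each layer"); a config switch selects raw
intensity.  `superimpose_layers` aggregates per-slice detections into 3D
seed candidates and labels them aorta/coronary by a 5 mm radius class
boundary, telling left from right coronary by which side of the aorta
they lie on.

## Region growing and cavity filling

Growing takes the connected component of {v ≥ threshold} containing the
seed, under 26-connectivity by default (thin oblique vessels touch
diagonally; 6 and 18 available).  The default threshold is 0.05 — low,
because the vesselness of genuine vessels is well separated from the
noise floor once the W-term has suppressed unstructured voxels.  A seed
below threshold is forced into the region with a warning (its component
then includes any adjacent supra-threshold voxels); `force_seed=False`
raises instead.  Growth is capped at 10% of the volume as a leak guard —
exceeding it raises an error naming the likely cause (threshold too low).

Cavity filling repairs the dark interiors that enhancement leaves inside
thick vessels.  Per axial slice, every background pixel with at least 4
foreground pixels among its 8 in-slice neighbours (3×3 minus centre;
out-of-slice counts as background) becomes foreground.  Updates within a
pass are *synchronous* — all decisions read the previous state — so the
result is independent of pixel visiting order; passes repeat to a fixed
point.  Foreground is never removed, so filling is monotone (output ⊇
input) and idempotent at convergence.  Filling is strictly 2D: a cavity
must be enclosed within its own slice to fill, which matches the
annular cross-sections thick vessels produce.

## Metrics

Jaccard, Dice, sensitivity and specificity from the voxel confusion
counts, with Dice = 2J/(1+J) holding identically.  0/0 ratios are
defined as 1 when both masks are empty of the relevant class (vacuous
perfect agreement) and 0 otherwise, each with a warning.  Reports carry
the raw counts so any aggregation (per-case or pooled) can be done
downstream; the suite table reports per-phantom (per-case) values.

## Phantoms: what they emulate, and what they do not

The generator renders bright primitives (default 300 intensity units on
a 0 background — HU-like but uncalibrated) with 2× supersampled
occupancy anti-aliasing (staircase edges otherwise contaminate the
eigenstructure) and additive Gaussian noise from a documented per-spec
seed; SNR is contrast/σ.  Ground truth marks tubes and cylinders —
including carved cavities, which model acquisition artifacts the
pipeline must repair — and excludes blob and plate distractors.
Rendering is a pure function of the spec.

The standard suite (each at SNR ∞, 10, 5; sizes chosen to run on one
CPU in seconds per phantom):

| phantom | geometry | exercises |
|---|---|---|
| single_tube | 2 mm tube, 40×64×64 | enhancement, growing |
| two_radius_tubes | Gaussian-profile tubes σ = 1, 3 mm | scale selectivity |
| tube_blob_plate | 2 mm tube + 6 mm blob + 2 mm disc | shape discrimination |
| aorta_branches | 15 mm cylinder + two 2 mm branches, 48×96×96 | Hough seeding, end-to-end |
| hollow_tube | 8 mm tube, 4 mm lumen hole over mid slices | cavity filling |
| rotated_tube | 2 mm tube, 30° oblique | rotation invariance |

Design notes.  The scale-selectivity phantom uses *Gaussian-profile*
tubes (truth = the 1σ disc) because the "winning scale = radius"
statement is exact for that profile at γ = 2; for hard-edged tubes the
peak sits at r/√2 by geometry, which is a statement about top-hat
profiles, not about radii.  Its growing threshold is 0.3 — the
vesselness level at the 1σ truth boundary — since a soft profile has no
intensity edge for the generic threshold to find.  The hollow-tube case
is enhanced at a single 2 mm scale (matched to its wall): that is
exactly the single-scale setting that leaves thick-vessel interiors
dark, i.e. it *creates* the cavity the fill stage must repair.  Phantoms
without an aorta-calibre cylinder carry documented manual seeds, because
automatic seeding searches the 10–20 mm anatomical radius range by
design.

What passing phantoms does **not** show: real CTA has textured soft
tissue, neighbouring bright anatomy (chambers, bone), streak/beam-
hardening artifacts, Poisson-flavoured noise, motion, and anisotropic
slice spacing with imperfect calibration.  The phantoms establish
correctness of the computation (formulas, oracles, invariances,
geometry), not clinical performance.

## Determinism and tolerances

All randomness flows from explicit integer seeds (phantom noise,
test/acceptance field generation); the full suite run twice produces
byte-identical masks and reports (timing is logged, never written into
reports).  Eigen-reconstruction is checked at 1e-8, the Dice–Jaccard
identity at 1e-12, the analytic Hessian limit at 2%, rotation invariance
of the tube response at 20% (trilinear-free nearest-voxel probing on an
oblique axis is the dominant error), and phantom-level segmentation at
Dice ≥ 0.90 / specificity ≥ 0.99 on the aorta case.

## Known limitations

- The growth predicate is a fixed vesselness threshold; adaptive or
  intensity-based criteria are out of scope.
- Cavity filling is 2D per axial slice; a 3D 26-neighbour variant is not
  provided.
- No DICOM series reading, resampling, HU calibration, centerline or
  tree topology extraction, and no learned enhancement.
- Anatomical labelling of seeds is a radius heuristic plus a left/right
  side convention, not ostium detection.
- The ε = HALF_MAX_NORM default couples the score to the strongest
  structure in the volume; on volumes dominated by a single very bright
  object, weaker distal vessels score lower than with a hand-set ε.
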