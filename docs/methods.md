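# Methods

This note documents the models, parameter choices and numerical conventions
behind `clearcount3d`, and what the synthetic-data tests do and do not
demonstrate about real cleared-brain data.

## Image model and restoration

The raw volume is modelled as `I = B · (1 + F) + ε`, where `B` is a smooth
autofluorescence background varying on length scales much larger than a
cell, `F` the fractional foreground contribution (cells, vessels), and `ε`
additive camera noise. Under this model, dividing by an estimate of `B`
recovers `1 + F` regardless of local background level or global gain —
which is why foreground amplitudes are specified as multiples of the local
background throughout the package.

The background estimate is a convolution with a truncated Gaussian:
weights ∝ exp(−(i²+j²+k²)/2σ²) on the cube i, j, k ∈ [−w, w], normalized so
the discrete sum over the cube is exactly 1. Parameters:

- `sigma_bg` (default **10 voxels**): must sit between the cell radius
  (3–5 voxels here) and the scale of background variation. This is the
  scale at which the separation-of-scales premise holds for the data the
  pipeline targets.
- `w` (default **ceil(3σ) = 30**): captures > 99.7% of the Gaussian mass
  per axis; the truncation is then renormalized, so the unit-sum property
  is exact by construction, not approximate.
- `padding` (default **reflect**): mirrors interior samples at the faces,
  preserving local intensity statistics so that I_n ≈ 1 at the borders.
  Periodic and nearest modes are available; periodic conserves the volume
  mean exactly and is used in tests for that property.
- Division floor: where I_σ < 10⁻¹² × mean(I_σ) (empty padding corners,
  all-zero inputs), I_n is set to 1 — the background level — instead of
  performing 0/0.

The kernel is separable (the cube normalization factors into three 1D
unit-sum kernels), so both convolutions run as three 1D passes; tests verify
equality with a brute-force cubic triple-loop convolution at 1e−10.

Denoising is a second Gaussian convolution of I_n with `sigma_denoise`
(default **1 voxel**): wide enough to suppress single-voxel digitization
noise, narrow enough not to blur 4–8 voxel cells. `sigma_denoise = 0`
disables it.

## Detection

`I_LoG = −∇²I_d` is computed by 3D central finite differences with h = 1
voxel per axis (a physical-spacing mode divides by the squared µm spacing
instead; the default matches the single-resolution use case where the
constant factor is absorbed by the thresholds). Boundary voxels replicate
the nearest interior value, which cannot create new threshold crossings at
the faces. For a Gaussian blob of scale s the continuum response is
positive for r < s√3, zero on that shell and negative outside — the
property the acceptance checks verify on a rendered blob.

Candidates are connected components of `I_LoG > α`:

- `alpha` (default **10⁻³**): the response of a unit-contrast blob of scale
  s peaks at 3/s² ≈ 0.1, so 10⁻³ is two orders below signal while well
  above the float-level ripple of flat backgrounds. The threshold is
  dimensionless because I_n is.
- `connectivity` (default **26**): the threshold field encloses convex blob
  interiors, where 26-connectivity is the least fragmenting choice.
- `min_voxels` (default **2**): single voxels carry an all-zero gyration
  tensor and hence undefined shape.
- `i_d_min` (default **1.1**): minimum per-object maximum of I_d. The
  restoration stage pins background to 1, so this reads as "at least 10%
  above background at the brightest voxel".

Touching structures are reported as single objects (conglomerates); no
watershed splitting is attempted. Object ids are assigned in lexicographic
order of each component's minimum (z, y, x) voxel, making outputs
deterministic independent of labelling internals.

## Morphology

The gyration tensor uses unweighted voxel-center coordinates in voxel
units; intensity information enters the feature vector separately
(mean/max I_d). Descriptors follow the standard polymer-physics
definitions (asphericity b = λ1 − (λ2+λ3)/2, acylindricity c = λ2 − λ3,
κ² = (b² + ¾c²)/R_g⁴). Two conventions worth noting:

- Tiny negative eigenvalues from `eigvalsh` round-off are clipped to 0, and
  κ² is clipped to 1 from above; degenerate objects (R_g² = 0) get
  κ² = 0 and sphere ratio 0 by convention.
- The sphere ratio is the *literal* ratio of object volume to the volume of
  a sphere of radius R_g. A continuum solid ball has R_g² = 3R²/5, so a
  true ball scores (3/5)^(−3/2) ≈ 2.15, not 1. The offset is constant and
  irrelevant to a relative discriminator, so the named quantity is kept
  as-is rather than "corrected".

## Classification

A random forest (100 trees, unlimited depth, √p features per split, fixed
seed) discriminates cells from non-cells. Splits are stratified 80%:20% by
default — stratification protects small labeled sets from single-class
splits; plain random splitting is available by flag. Because a single
split's accuracy is noisy, `evaluate_repeated` repeats the
split-train-score cycle over k derived seeds (default 10) and reports
per-split values plus mean ± SD.

The pipeline trains its forest on candidates detected in independently
seeded synthetic scenes, labeled by ground-truth overlap
(`build_training_table`) — a self-consistent substitute for a manually
labeled object table. The parametric feature fixture
(`make_feature_fixture`) serves a different purpose: a controlled
two-class distribution for unit-testing the classifier itself. Its
`separation` knob interpolates the vessel class's log-eigenvalue means from
identical-to-cells (0) to fully elongated (1). At separation 0 accuracy is
chance by construction; the "moderate" setting 0.5 was designed to yield
held-out accuracy in the mid-0.9s, qualitatively mirroring a
strong-but-imperfect manual-label regime; accuracy is monotone in
separation.

## Quantification

Each classified cell voxel contributes its full physical volume
(z·y·x spacing product, e.g. 3 × 3.26 × 3.26 µm³) to the 25 µm coarse voxel
containing its center — whole-voxel assignment, no partial-volume
splitting. The map accumulates integer voxel counts and scales once by the
voxel volume, so conservation (Σ cell volumes = Σ density map = Σ region
totals including the unassigned bucket) holds to 64-bit rounding; tests
assert it at 1e−12 relative.

Atlas registration is consumed, not computed: the package expects an
integer label grid congruent with the coarse map plus a TSV mapping labels
to (region, super-region). Label 0 accrues to "unassigned". A per-centroid
assignment mode exists for comparison (each cell's whole volume to the
region under its centroid); the per-voxel mode is the default because it
splits boundary-straddling cells consistently with the density map. Group
summaries use sample SD (N − 1), appropriate to the 2–8 samples-per-group
regime this serves; single-sample groups report SD = NaN rather than a
fabricated 0. Region exclusion (e.g. a cerebellum dominated by
autofluorescent Purkinje cells) drops the region from tables and records it
in the report.

## Validation

Manual cell/background annotations have uncertain boundaries, so the
metrics ignore boundary mismatches symmetrically:

- **TP**: each truth component's core is its erosion by a ball of
  `core_radius` (default 1 voxel), falling back to the innermost voxel
  (distance-transform argmax) if erosion empties it. If the prediction
  intersects the core, the component's entire volume is credited. Note the
  direction: a *larger* core radius shrinks the core and makes matching
  more demanding — tp is non-increasing in `core_radius`, with radius 0
  meaning any overlap counts.
- **TN**: counted over background voxels outside the dilation of the truth
  mask by `band_radius` (default 1); `band_radius = 0` recovers strict
  per-voxel accounting.

The convergence series recomputes both fractions on the cumulative prefix
of k z-slices, k = 1..Z; its terminal entry equals the whole-volume metrics
by construction.

## Synthetic scenes

The generator emulates exactly the features the pipeline's stages respond
to: multiplicative Gaussian-blob cells (peak amplitude × exp(−r²/2s²),
s = radius/2), Gaussian-profile tubes along random polylines for vessels, a
smooth background field (base level × (1 + amplitude × unit-normalized
white noise smoothed at a length scale ≫ σ_bg)), and additive Gaussian
camera noise, clipped at 0. Truth masks are the half-peak isosurfaces —
well-defined, resolution-independent volume ground truth. Defaults encode
the study conditions the tests run under: 128³ grid at 3 × 3.26 × 3.26 µm,
20 cells of radius 3–5 voxels at amplitude 4–6× background, 5 vessels at
amplitude 2.5–3.5, background level 100 with 20% field amplitude at scale
40 voxels, noise SD 2% of base.

Planted structures are mutually non-overlapping by rejection sampling —
cells keep twice the summed radii from other cells *and* from vessel
centerlines — so every truth object has an unambiguous identity. Real
tissue contains cells abutting vasculature; such contacts produce merged
candidates whose class is genuinely mixed, and the non-splitting design
reports them as single objects. The generator excludes that regime on
purpose: recall/precision and TP/TN properties measured on these scenes
certify the chain's behavior on well-separated structures, not its
conglomerate handling.

Also not emulated: optical PSF anisotropy, light-sheet striping, tile
seams, Poisson (signal-dependent) noise, and autofluorescence textures at
cell-like scales. Passing tests therefore demonstrate correctness of the
computation, not robustness to those acquisition artifacts.

## Determinism and problem sizes

A single global seed is fanned out to per-stage seeds (scene rendering,
training-scene rendering, split, forest) through a fixed `SeedSequence`
derivation, all below 2³¹. Identical config + seed reproduces every output
table bit-identically; tests verify this by checksum. The test suite and
demo run at 128³ (the scale at which the background field, kernel width and
cell sizes are all well separated) with 64³–96³ grids for unit fixtures;
these sizes were chosen so each property is measured in the regime its
stage assumes while keeping the whole suite in the low minutes on one CPU.
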