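# Methods

## The model

`topowarp` segments 2D images by *deforming a prior shape* rather than
labelling pixels.  A prior `P` is a binary (possibly multi-channel) mask
whose Betti numbers `(b0, b1)` — connected components and enclosed holes —
match the known topology of the target anatomy: a mid-ventricular
myocardium slice is an annulus `(1, 1)`, the left ventricle a disc `(1, 0)`,
and so on.  An encoder–decoder network `g_θ(X) = [u¹_bulk, u¹_ft]` predicts
two small displacement fields from the image; each passes through a
*topology-preservation layer* and the resulting deformations warp the prior:

```
Ŷ = Φ_ft( Φ_bulk( P ) ),    Φ(x) = u(x) + x
```

The coarse **bulk** field positions and scales the prior; the finer
**fine-tuning** field refines its boundary.  If both deformations are
smooth and free of folding (Jacobian determinant > 0 everywhere), the
warped output is a continuous deformation of the prior and inherits its
topology.

### The topology-preservation layer

Discrete fields stored on a grid lose the guarantees of their continuous
counterparts: interpolation plus re-storing can manufacture steep
gradients that fold the field.  Three counter-measures are applied in
sequence to each raw head output:

1. **Bounded activation** `a(u) = tanh(u)/2`, applied per component, caps
   every displacement strictly below half a grid space so adjacent grid
   points cannot cross in one composition step.
2. **Scaling and squaring with inter-step smoothing.**  The activated
   field is amplified through `h` composition layers
   (`Φ^{2h} = Φ^{2h-1} ∘ Φ^{2h-1}`, so `h = 8` realises 256 unit
   compositions; a constant field grows exactly 2^h-fold).  After every
   composition — including the last — the displacement is convolved with a
   normalised `k × k` Gaussian (σ in voxels) to erase the artificial
   gradients introduced by interpolating and re-storing.  Smoothing after
   the final step (rather than strictly between steps) keeps the layer
   uniform; the σ-sweep property tests cover both behaviours of interest.
3. **Field upsampling.**  The final composite field is re-expressed on a
   grid twice the input resolution (displacements interpolated and scaled
   ×2), which reduces the grid spacing describing the transform and acts
   as an extra smoothing step.  Both the gradient penalty and the folding
   audit operate on these final `2H × 2W` fields.

The prior is backward-warped (output pixel samples the source at the
mapped coordinate, linear interpolation, background 0 outside), then
downsampled to the input resolution — max pooling for single structures,
2×2 averaging ("linear") for multi-structure scenes, where max pooling
would create channel overlaps — and thresholded at `T`.

### Coordinate conventions

Grids are 0-based `(row, col)` voxel centres; displacements are stored in
voxels of the field's own grid.  Conversions between grids of different
resolution use the voxel-centre rule `coarse = (fine + 0.5)/f − 0.5`.
This choice is load-bearing: with it, the identity deformation reproduces
the prior *exactly* after warping at double resolution, downsampling and
thresholding (pixel-exact for linear downsampling at `T = 0.3`, and for
max pooling at `T = 0.5`; under max pooling at `T = 0.3` only concave
boundary corners gain one pixel, which cannot change Betti numbers of the
priors used here).  Zero-initialised 1×1 head convolutions therefore make
every model start at the identity — the prior itself — which stabilises
the bulk/fine-tune decomposition.

### Loss

```
L = L_Dice(Y, Ŷ) + α·L_Grad(Φ_ft) + β·L_Grad(Φ_bulk)
```

`L_Dice` is soft Dice with ε = 1e-6, averaged over channels.  `L_Grad`
sums squared forward differences of the displacement (not the absolute
field, so the identity transform costs nothing) over the final
`2H × 2W` grids and divides by the number of grid points.  Displacements
are first expressed in **normalized grid coordinates** (grid extent 2,
i.e. `u_r · 2/(H−1)`): this is the convention of grid-sample-based
spatial-transformer implementations, and it is the only scaling under
which the default weights `α = β = 10⁴` are coherent — in voxel units
that weight pins the model at the identity (verified empirically: Dice
collapses while the gradient terms vanish), while in normalized units it
yields an O(1) smoothness pressure under which the model deforms freely
yet folding is suppressed.  `grad_loss(..., normalize_coords=False)`
exposes the raw voxel-unit variant.

### Training

Adam, single seed controlling weight initialisation, batch order and
augmentation.  Per-epoch history records the loss components, validation
Dice, validation topology accuracy (output Betti = prior Betti on every
channel) and the worst folding percentage; the best-validation-Dice
snapshot is restored at the end.  Training aborts on non-finite loss.

## Evaluation

* **Dice** `2|A∩B|/(|A|+|B|)` (1.0 when both masks are empty).
* **Hausdorff distance**: symmetric, between boundary voxel centres
  (8-connected erosion residue), Euclidean, optionally scaled by voxel
  spacing; the plain 100th-percentile definition.
* **Betti numbers**: `b0` = foreground components (4-connectivity by
  default, 8 available); `b1` = 4-connected background components that do
  not touch the image border (the operational reading of "background
  surrounded by foreground").  A segmentation is *topologically correct*
  when every channel's Betti pair equals the prior's.
* **Scene topology** (multi-structure): Betti numbers of the channel
  union plus the count of voxels claimed by ≥ 2 channels; correct means
  union Betti as expected and zero overlap.
* **Folding**: Jacobian determinants by central differences (one-sided at
  borders) of the absolute mapping; the reported number is the percentage
  of grid points with det ≤ 0.
* **Perimeter**: exposed 4-neighbourhood voxel faces (outer and hole
  boundaries both counted, image border included), an integer in
  voxel-edge units; relative perimeter error is the absolute difference
  as a percentage of the reference perimeter (undefined → NaN for an
  empty reference).

The Euler-characteristic cross-check in the test suite uses the
closed-pixel complex (`χ = V − E + F` over pixel corners, sides and
faces), which pairs 8-connected foreground with 4-connected background
holes; that is the digitally consistent pairing for our hole definition.

## Synthetic phantoms

The generator manufactures study conditions with *known* topology, so no
external data is needed:

* **Labels**: the canonical prior is warped with a random smooth
  deformation — Gaussian noise smoothed at σ = 6 voxels, scaled to a peak
  pre-activation magnitude of 0.35, passed through the bounded activation
  and h = 6 squaring layers (σ = 2, k = 3) — that is *verified fold-free*
  (any non-positive determinant → regenerate with the next seed, max 10
  tries).  A warped label whose Betti numbers differ from the prior's is
  rejected likewise.  Labels are therefore topology-correct by
  construction, the synthetic analogue of selecting only slices with the
  expected anatomy.
* **Images**: piecewise-constant intensities per structure (defaults
  0.75/0.2 foreground/background for single structures; 0.85/0.55/0.35
  over 0.15 for the cardiac scene) plus Gaussian noise (sd 0.06), clipped
  to [0, 1].
* **Corruption and augmentation**: the digit-style task zeroes 1–8 random
  Fourier lines (Hermitian-symmetrically, so the image stays real); the
  cardiac-style tasks apply rotations ±5°, translations ±5 voxels,
  vertical/horizontal flips and ±30% resizing to image and label jointly
  (linear/nearest interpolation respectively; the prior is never
  transformed).  Augmentations that break the label's Betti numbers are
  redrawn.
* **Splits**: 75/15/10 train/validation/test assigned at the family
  level, so no family straddles splits.

At the default strength the labels remain clearly deformed (mean
Dice(prior, label) ≈ 0.8 before augmentation, ≈ 0.4 after, always
< 0.95), so the task is non-trivial.  What the phantoms do *not* emulate:
MRI contrast and texture, bias fields, motion artefacts, anatomical shape
statistics, or inter-subject variability; passing on phantoms shows the
machinery preserves topology under realistic geometric nuisance, not that
segmentation quality transfers to clinical data.

## Study sizes and presets

The packaged synthetic studies run at desk scale on one CPU:
64×64 phantoms, 400 families (300/60/40), encoder depth l = 3 with f = 8
initial features, branches l_bulk = 3 and l_ft = 2, h = 8, σ = 2, k = 3,
α = β = 10⁴, T = 0.3, Adam at lr 1e-3, batch 5, 30 epochs (≈ 6–8 minutes
per study).  The learning rate is 10× the full-scale configurations'
1e-4, compensating for the 30-epoch budget.  The `mnist_digits` and
`acdc_myo` presets record the full-scale configurations (28×28 single
branch l = 2, f = 12, α = 150; 144×208 dual branch l = 4, f = 12,
l_bulk = 4, l_ft = 2, T = 0.3, α = β = 10⁴, 200 epochs) for use with
externally supplied data; nothing is downloaded.

The test suite exercises the same pipelines at a further reduced size
(48×48, 120 families, 10 epochs) so the whole suite stays fast.

## Numerical choices and degenerate inputs

* All sampling is linear by default (composition, upsampling, prior
  warping); nearest and cubic are selectable on the numpy-side
  operations.  Out-of-range composition samples clamp to the border
  (keeping constant-field squaring exactly 2^h·c); warping returns
  background 0 outside the source.
* Gaussian kernels are truncated at k×k and renormalised to sum exactly
  1; σ = 0 is a strict no-op.  Smoothing pads by edge replication, so
  constant fields are preserved exactly.
* The training-side engine works in float32; the numpy-side field
  operations in float64 (the composition oracle agrees to ≤ 1e-6).
* Degenerate guards: non-finite field values are rejected with the
  offending index; priors self-check their Betti numbers at construction
  and refuse degenerate geometry (wall ≥ radius, overlapping holes, rv
  disc leaving the grid); empty predictions score Dice 0 with missing
  Hausdorff; an empty-perimeter reference yields NaN, not 0.
* Betti ties: foreground connectivity defaults to 4 to match the hole
  definition and the 4-neighbourhood contouring; masks are required to be
  strictly binary.

## Known limitations

* Topology preservation is strongly encouraged, not guaranteed: the
  folding audit, not a proof, is the evidence — and downsampling plus
  thresholding can in principle still break topology even with fold-free
  fields, which is why Betti numbers are always measured on the final
  binary output.
* The smoothing that suppresses folding also limits boundary detail;
  thin structures tend to be slightly over-segmented.
* Multi-channel outputs are thresholded independently, so channel
  overlaps and inter-channel gaps are possible and are reported rather
  than prevented.  In the synthetic cardiac study the per-channel
  topology is fully preserved, but hairline gaps at structure interfaces
  commonly break the *union* Betti numbers, so the scene-topology rate is
  substantially lower than the per-structure rates — scene topology is
  the harder criterion by design.
* 2D only; fields are stationary (no time-varying velocity integration);
  no inverse-field computation.
* The prior's topology must be known in advance; images whose true
  topology differs from the prior will be forced to the prior's.
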