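# Methods

This note documents the model behind `c8morph`, the numerical choices the
implementation makes where the procedure leaves them open, what the
synthetic phantoms do and do not emulate, and the known limitations.

## Input contract and coordinates

The pipeline consumes a 3D WM probability volume (values in [0, 1]) already
affine-normalized to MNI space at roughly 1 mm isotropic resolution. World
coordinates are MNI millimetres, RAS+ (x right, y anterior, z superior);
voxel indices are 0-based and refer to voxel centers. Values outside [0, 1]
are clamped rather than rejected (segmentation tools emit small
interpolation overshoots), and integer-scaled maps (max > 1.5) are divided
by 255. An optional plain-text 4×4 matrix supplies the native→MNI affine
when the image header no longer encodes it; with no matrix the identity is
used and native-space outputs equal MNI outputs.

Para-midsagittal slices (default x = −1, 0, +1 mm) are resampled onto
regular (y, z) grids by trilinear interpolation, so oblique header affines
are handled uniformly rather than by taking raw index planes.

## Callosal isolation

Four mechanisms suppress fornix / pericallosal-artery adhesions:

1. **Orientation filter** (3D, before slicing). A supra-threshold voxel is
   kept only if some straight line probe of radius 3 mm through it, within
   a 45° cone about the left–right axis, has mean probability ≥ the WM
   threshold. The cone is quantized (axis plus 3 polar × 8 azimuthal
   directions); probing mean *probability* rather than a binarized mask
   keeps the test stable at partial-volume boundaries.
2. **Fixed threshold + seeded growing.** Seeds drop from the top of an
   MNI bounding box (default y ∈ [−55, 50], z ∈ [−5, 40] mm — a generous
   callosal envelope standing in for a probabilistic location atlas); the
   8-connected supra-threshold components containing seeds are grown, and
   the cluster maximizing (AP extent, voxel count, probability mass)
   lexicographically is kept. The threshold defaults to 0.5, the natural
   posterior decision boundary; all of this is configurable.
3. **Inferior-branch pruning.** Within mid-body columns (default
   y ∈ [−30, 10] mm), where a column's supra-threshold voxels split into
   runs separated by sub-threshold gaps, every run below the superior-most
   run is erased; connectivity is re-checked and the main component kept.
   Branches outside the stated y-window are retained — a documented
   limitation of the windowed rule.
4. **Median over three slices** of all final derived quantities, which
   discounts an adhesion or failure confined to one slice.

The anterior–posterior extent that anchors the partition cuts is refined
to sub-voxel precision by linearly interpolating where the per-column
probability maximum crosses the threshold. Without this refinement the
extent is quantized to the voxel grid and the compartment cuts jump by a
full voxel between resolutions or noise realizations.

## Median line

Rays at 1.65° steps (219 rays) emanate from the centroid — AP midpoint of
the cluster, at the minimum z over the posterior 20% of the extent (the
splenium region; the fraction is configurable since "splenium" has no
hard definition). Rays sample bilinear probability every 0.25 mm (≤ ¼
voxel, for sub-voxel median stability) from probabilities masked to the
cluster plus a 2 mm partial-volume rim, so unrelated structures elsewhere
on the slice cannot perturb the medians.

On each ray the median WM location uses probability² weights, pooled over
all samples of the rays within ±5.775° (the 11.55° wedge = a symmetric
7-ray stencil at 1.65° spacing). Pooling the wedge samples, rather than
averaging per-ray medians, is the simpler reading of a "median within a
neighborhood" and is what we implement; ties resolve to the smaller
radius. Tip angles are refined by bisection on the interpolated
along-ray maximum probability between the last intersecting and first
non-intersecting ray. Anchor positions at the 50 equal-angle values are
linear interpolations of the per-ray median points over angle.

Internal length is the chord sum over the 49 anchor gaps. For a
semicircular centerline the chord sum underestimates arc length by the
closed form 1 − 2k·sin(π/2k)/π with k = 49, about 0.01% — negligible
against voxel-scale effects.

## Thickness

Thickness at an anchor is the minimum over a 180° sweep (1° steps) of the
probabilistic traversal: marching from the anchor in both directions at
ds = 0.1 mm, accumulating bilinear probability × ds. A march direction
terminates once probability stays below the exit level (half the WM
threshold) for a confirmation run of 10 consecutive samples (1 mm), and a
25 mm cap flags non-terminating directions. No perpendicularity constraint
to the boundaries or the median line is imposed; the minimum is fully
local.

Two numerical choices matter and were set by measurement on phantoms:

- **Confirmation run = 1 mm.** The march must keep integrating beyond the
  exit crossing, because for a partial-volumed boundary the sub-exit tail
  carries genuine mass: truncating after 0.3 mm biases thickness by about
  −2% at 0.5 mm blur, while 1 mm integrates a Gaussian tail of σ ≤ 1 mm
  essentially completely yet still terminates inside any true gap wider
  than 1 mm.
- **Sweep discretization.** A 1° sweep at ds = 0.1 mm agrees with a 0.1°,
  ds/4 brute-force oracle (same physical confirmation window) within 2% at
  every anchor of the reference phantom; the worst observed deviation is
  ~0.1%.

The probability-sum definition slightly *underestimates* thickness on
blurred boundaries relative to binary chords — a reproducible property of
the definition, visible in the tests — and the minimum over directions
tends to dodge residual attachments: on the fornix-stub phantom the
attachment-anchor inflation is ~8%, versus +150% for a naive radial chord
through the stub. The inflation floor is set by the attachment's blurred
skirt (any chord exiting the boundary near it integrates ~0.3–0.5 mm of
skirt mass), so one to two anchors adjacent to an attachment may still
read ~10–15% high; misestimation stays local by construction.

Native-space thickness rescales each minimizing segment by the ratio of
its endpoint separation after and before the inverse affine — exact for
affine maps since the segment is straight.

## Partitions and areas

Areas are probability sums over the cluster support (mask + 2 mm dilation
rim; without the rim, the partial-volume mass outside the 0.5 level set is
lost, ≈ −5% for the reference phantom). Compartments cut the refined AP
extent at Hofer–Frahm fractions (1/6, 1/2, 2/3, 3/4) or grouped-Witelson
fractions (1/3, 1/2, 2/3, 4/5) with straight constant-y boundaries; the
Witelson rostrum/genu sub-split, which needs non-vertical boundary
geometry, is reported as the grouped W1+W2+W3 block. Pixels straddling a
cut are split in proportion to the overlap of their y-extent with each
compartment, so compartment areas are continuous in cut position;
center-of-pixel assignment instead lets a whole pixel column (up to ~25%
of a compartment on the small phantom, whose anterior arm is nearly
vertical) flip sides on a 0.1 mm cut shift. Native areas apply the
in-plane Jacobian of the inverse affine (norm of the cross product of the
two transformed in-plane unit vectors); for a pure scale s this gives
exactly area/s² and length/s.

Per-compartment mean thickness averages the anchors whose y falls in the
compartment; an empty compartment yields NaN with a warning.

## Phantoms: what they emulate, and what they do not

`make_arch_phantom` rasterizes an annular-sector band (optionally
linearly thickness-tapered over angle), extruded ≥ 20 mm along x, by
sub-voxel coverage fractions (4× supersampling) — the coverage raster *is*
the partial-volume emulation, and it keeps the discrete probability mass
within well under 1% of the analytic area, where a binary center-in/out
raster of a closed 4 mm band is 5 pixels thick and anisotropically wrong
by up to 18%. Gaussian blur (default σ = 0.5 mm) models segmentation
smoothing and is mass-preserving; clipped additive Gaussian noise models
posterior uncertainty. Ground truth (area = ∫ mid·t(θ) dθ, exact for this
geometry; length; thickness profile; fine-grid compartment areas) is
computed analytically before degradation.

`make_fornix_phantom` attaches a descending stub at the inferior arc —
defaults: 120° attachment (under the posterior body), 1.5 mm wide in y,
6 mm long, and only 2 mm wide in x, since the fornix is a narrow midline
bundle while the callosum extends laterally; the lateral narrowness is
precisely what the orientation filter exploits, and it confines residual
adhesion to a subset of the three slices, the regime the median
aggregation is designed for. An optional `gap_probability` inserts two
sub-threshold rows at the attachment (two rows so 8-connectivity cannot
bridge the stepped oblique boundary), producing a detached branch for the
pruning/exclusion pathway.

The phantoms do **not** model: realistic whole-head anatomy or neighboring
WM structures, MR physics (bias fields, Rician noise), spatially varying
segmentation errors, or the true curved course of the fornix. Passing the
phantom suite therefore demonstrates geometric and numerical correctness
of the measurement chain and its designed failure-mode handling — not
segmentation quality on clinical data, which is inherited from the
upstream tissue segmentation.

Two scale caveats when reading the phantom numbers: the phantom CC is
~24 mm long versus ~70 mm in vivo, so compartment areas are ~10× smaller
than real ones and percentage repeatability under noise is correspondingly
pessimistic (the smallest phantom compartment is ~9 mm²; its area diff
between noise realizations is ~2–5%, scaling as 1/√area); and the
square-cut phantom tips make end anchors read genuinely short chords,
which dominates the −1 to −3% thickness × length vs. area deficit.

## Degenerate inputs and failure handling

4D volumes, singular affines, and unreadable NIfTI files are rejected at
load. Extraction fails cleanly when the bounding box holds no
supra-threshold voxels, when pruning empties the cluster, or when fewer
than 3 rays intersect (and on a closed annulus, where no tips exist). A
thickness anchor whose sweep never terminates becomes NaN; more than 10%
failed anchors aborts the slice. One failed slice is dropped with a
warning and the median is taken over the remaining two; two failures abort
the run (CLI exit code 2; I/O failures exit 3).

## Problem sizes used in validation

The test suite and the acceptance script run on 1 mm phantoms of about
40×44×44 voxels (seconds per full three-slice run), a 20-phantom
radius/taper sweep for the consistency check, and a 0.1° × ds/4
brute-force oracle over all 50 anchors of the reference phantom.
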