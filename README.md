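# c8morph — automated midsagittal corpus callosum morphometry

`c8morph` measures the corpus callosum (CC) — area, regional thickness,
internal length, and standard geometric compartments — fully automatically
from a white-matter (WM) probability volume that has been affine-normalized
to MNI space at ~1 mm isotropic resolution. It is aimed at neuroimaging
researchers who already run a whole-brain tissue segmentation (SPM,
FreeSurfer, or similar) and want reproducible callosal morphometry without
manual tracing. Tissue segmentation and spatial normalization are upstream
of this package and out of its scope.

## Method

The pipeline runs independently on the midsagittal plane and the two
parasagittal slices at x = ±1 mm (MNI), then takes the **median of every
derived quantity over the three slices** for robustness:

1. **Callosal isolation.** WM voxels that cannot lie on a locally linear
   supra-threshold path within 45° of the left–right axis are removed
   (callosal fibers cross the midline mediolaterally; the fornix and the
   pericallosal artery do not). Inside an MNI bounding box, seed points are
   dropped from the superior surface, supra-threshold (p ≥ 0.5) connected
   components are grown, the longest (anterior–posterior), largest cluster
   is kept, and branch runs hanging below the mid body across a
   sub-threshold gap are erased.
2. **Median line.** Radial rays at 1.65° intervals emanate from a centroid
   placed halfway along the AP extent, at the inferior extent of the
   splenium. On each ray, the median WM location is computed with
   *squared* segmentation probabilities as median weights pooled over an
   11.55° neighborhood (a 7-ray stencil). Interpolating these points at 50
   equal-angle anchors from the anterior to the posterior tip gives the
   median line; internal length is the sum of anchor-to-anchor gaps,
   `L = Σᵢ ‖aᵢ₊₁ − aᵢ‖`.
3. **Thickness.** At each anchor, thickness is the **minimum traversal
   distance**: the length of the shortest segment across the callosum
   through that anchor, over a 180° sweep, where segment length is the 1D
   probability sum `t(θ) = Σ p(s)·Δs` along the segment. Summing
   probabilities avoids sub-voxel boundary delineation; the unconstrained
   minimum avoids both perpendicularity conventions and residual fornix
   attachments.
4. **Areas and compartments.** Area is the 2D probability sum times pixel
   area. The AP extent is cut at fixed fractions — Hofer–Frahm (1/6, 1/2,
   2/3, 3/4) and Witelson in its grouped form (1/3, 1/2, 2/3, 4/5) — into
   five compartments each, with per-compartment area and mean thickness.
5. **Native space.** Every length and area is also reported in native
   anatomical space by inverting the affine normalization transform
   (lengths via mapped endpoints, areas via the in-plane Jacobian).

A synthetic phantom generator (`c8morph.phantoms`) produces annular-sector
"arch" volumes with closed-form ground truth (area π(R²−r²)·span/2π,
mid-radius length, analytic thickness profile), optional taper, partial
volume blur, noise, and a fornix-surrogate stub — so every stage is
testable without any external data.

## Worked example

```bash
c8 phantom make --preset arch --out arch.nii.gz --truth truth.json
c8 run --wm arch.nii.gz --out results/
```

prints

```
total area (native): 125.1 mm^2; median length (native): 31.7 mm
wrote results/report.json
wrote results/compartments.csv
wrote results/profile.csv
```

The phantom is a half-annulus band with inner radius 8 mm and outer radius
12 mm: true area 125.66 mm², true mid-radius length 31.42 mm, uniform true
thickness 4 mm. The measured total area (125.1 mm², −0.4%) and length
(31.7 mm, +0.9%) recover these, and `results/report.json` holds the
Hofer–Frahm compartment areas `[24.7, 37.9, 16.4, 9.3, 36.9]` mm² (summing
to the total) with mean compartment thicknesses
`[3.67, 3.98, 3.99, 3.98, 3.75]` mm — the interior compartments sit within
1% of the true 4 mm, while the first and last include the tips, where the
shortest chord through an end anchor is genuinely shorter.
`results/profile.csv` lists the full 50-anchor thickness profile.

For real data:

```bash
c8 run --wm wm_prob_mni.nii.gz --native-affine native_to_mni.txt \
      --config c8.yaml --out results/ --qc
```

where `native_to_mni.txt` is the whitespace-separated 4×4 affine of the
native→MNI normalization and `--qc` writes overlay PNGs of the extracted
cluster and median line per slice.

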