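# Methods

## 2D pipeline: detection, classification, zoning, composition

### Detection

The detector operates only on the pan-macrophage F4/80 channel. The image
is processed in square tiles (default 256 px): each tile is median-filtered
with a circular footprint (default radius 2 px) and binarized, the binary
tiles are assembled into one full-size mask (overlaps combined by logical
OR), components are labeled globally (8-connectivity by default), holes
are filled using the complementary background connectivity, and components
below `min_area` (default 100 px ≈ 25 µm² at the default 0.5 µm/px) are
removed. Each surviving component becomes one cell detection.

Two deliberate choices differ from a naive tile-by-tile workflow:

* **Halo filtering.** Each tile is filtered inside a window expanded by the
  median radius with real image context, so the assembled filtered image is
  exactly the untiled filtered image. Together with global labeling and
  global area filtering this makes the detection set provably independent
  of tile size under `fixed` or `global-otsu` thresholding (the tiling
  invariance exercised in the tests over tile sizes 64/128/256/full).
  A `per-tile-otsu` mode, which derives one threshold per tile and breaks
  that invariance, is retained for comparison with tile-local workflows.
* **Merge-then-filter.** Area filtering runs after global assembly, never
  per tile, so a cell split across a tile border cannot lose fragments to
  the per-tile size filter.

Conventions fixed for exactness: foreground is `intensity >= threshold`;
median-filter edges use edge-repeating reflection; border-touching cells
are kept and flagged `touches_border` rather than dropped, leaving the
edge policy to the caller.

### Classification

The per-cell feature is the arithmetic mean of each channel over the
detection mask (the common digital-pathology default; medians would be a
one-line change). The gate is hierarchical, mirroring cytometry gating
order: CLEC4F status is decided first; TIM4 is only consulted for
CLEC4F-positive cells, so a CLEC4F⁻TIM4⁺ cell is still a CLEC4F⁻ mac.
Ties classify as positive. Threshold modes: `fixed` values,
`otsu-on-cell-means` (default; requires ≥ 3 cells and falls back with an
instructive error otherwise) and `quantile`. No cross-image intensity
normalization is applied by default; image-derived thresholds already
adapt per image.

### Zoning and vessel exclusion

Desmin-high segmentation is a deterministic smooth → threshold → clean
chain: Gaussian smoothing (σ = 2 px), threshold (Otsu default; quantile
and fixed available), morphological closing (disk, radius 2), and
re-labeling of high components smaller than `min_hi_area` (default
100 µm²) as low. A pre-computed zone mask can replace this stage entirely.
When a vessel mask is available, its pixels are excluded from the
data-driven threshold statistics: perivascular Desmin is far brighter than
fibrotic-zone Desmin and would otherwise dominate an Otsu split.

Vessel exclusion defaults to an external (manually drawn) mask, which is
applied after segmentation by setting those pixels to the excluded label.
`auto_vessel_mask` — pixels above the 0.98 quantile in *both* Desmin and
CD31, dilated, hole-filled, size-filtered — is provided as an explicitly
experimental convenience and is logged as such.

### Composition statistics

Cells are assigned the zone of their rounded centroid (majority-overlap
assignment exists behind `assign_zones_majority`; centroid assignment is
cheaper and unambiguous). Two families of percentages are reported per
image: each subset's share of all non-excluded macrophages, and each
subset's split between the Desmin-high and Desmin-low zones. Empty
denominators produce missing values, never zero, so downstream statistics
cannot silently treat an absent subset as an observed 0%. Cross-animal
group statistics are intentionally out of scope; the per-image table is
the product.

## 3D pipeline: droplet volumetry

Input is a probability map in [0, 1]. Stages, in fixed order: threshold at
`prob_threshold` (default 0.5, the canonical probability cut), removal of
connected components smaller than `min_voxels` (default 27 = 3×3×3),
morphological opening with a digital Euclidean ball
{v : ‖v‖₂ ≤ r} of radius `opening_radius` (default 2 voxels), then
labeling and volumetry. Voxel size defaults to 5 nm isotropic (the FIB
milling step); totals are reported in voxels and µm³. Component
connectivity defaults to 26 (6/18 selectable). The structuring element is
isotropic in voxel units by default; an anisotropic (physical-unit) ball
is available via `anisotropic_element`.

Note the stage order means the 27-voxel floor holds *after the removal
stage*: the subsequent opening may legitimately shrink a surviving
component below 27 voxels.

## Synthetic data

The tissue generator plants hard-disk cells (rejection-sampled, no
overlap, with a ≥ 6 px boundary gap so smoothing cannot bridge neighbours)
of four kinds — ResKC, moKC, CLEC4F⁻ mac, and an F4/80⁻ distractor that
must never be detected. Marker foreground intensities default to 200 a.u.
on a 10 a.u. background following the subset logic. Desmin-high patches
are disks whose Desmin signal is multiplied by `desmin_hi_gain` (default
3); CLEC4F⁻ macs are placed with a configurable high/low density ratio
`enrichment_rho` (default 4, i.e. enriched in Desmin-high tissue).
Vessels are annuli co-high for Desmin and CD31 with a signal-free lumen;
the exclusion truth is the full vessel disk. Noise is additive Gaussian,
clipped at zero. Default geometry: 512×512 px at 0.5 µm/px, 110 cells of
radius 10 ± 1 px (a ~10 µm cell radius, macrophage-scale at this
sampling), 3 patches of radius 60 px, 2 vessels of radius 25 px.

The droplet generator places non-overlapping digital balls (default 8 per
stack of 64×128×128 voxels, radius 10 ± 1.5 voxels), blurs them (σ = 1),
rescales to peak 1 and adds 2% Gaussian noise. Truth volumes are exact
lattice-point counts. The default radii keep droplets large relative to
the 27-voxel floor and radius-2 opening — the regime the post-processing
parameters imply, where those operations remove noise rather than droplet
mass. Optional adversarial components are compact scan-order box
prefixes planted as exact binary blocks with pairwise separation, used to
probe size-filter boundaries voxel-exactly.

What the generator does *not* emulate: realistic point-spread functions,
spectral bleed-through, intensity heterogeneity within cells, touching
cells (an `allow_overlap` mode exists, but ground-truth counting then uses
truth rows, not mask components), irregular droplet shapes, or anisotropic
blur. Passing tests therefore demonstrate algorithmic correctness of the
pipeline stages and statistics, not segmentation performance on acquired
micrographs.

## Numerical and design choices

* One `numpy` `default_rng` per generator call, seeded from the spec:
  identical spec + seed ⇒ bit-identical arrays and truth tables.
* All `≥` tie-breaks (thresholds, size floors) are inclusive and tested at
  the boundary.
* GeoJSON polygons trace the union of unit pixel squares, so polygon
  (shoelace) area equals mask pixel count exactly and centroids round-trip
  within 0.5 px; y grows downward, matching pathology viewers.
* Erosion treats out-of-volume voxels as background (objects touching the
  border erode), matching the set definition used by the brute-force
  reference morphology in the tests.
* Problem sizes in the test-suite: recovery checks run on one 1600×1600 px
  image with 500 cells; invariant sweeps use 50 seeds at 256×256 px and
  24³–32³ voxel stacks. These sizes give binomial standard errors well
  inside the asserted ±3 percentage-point bands.

## Known limitations

* Touching cells are not split (no watershed); counts on dense real tissue
  would undercount, as with any pure threshold-and-label detector.
* Otsu-derived thresholds assume a bimodal intensity distribution per
  image; heavily skewed real channels may need fixed or quantile modes.
* The automatic vessel detector is a convenience, not a validated
  replacement for manual vessel annotation.
* Droplet volumetry inherits the bias of thresholding blurred boundaries
  (≈ 1–3% under the default synthetic conditions); the opening further
  shaves strongly curved surfaces, which is material only for droplets
  within a few voxels of the structuring-element radius.
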