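# hepaquant

Quantification of hepatic macrophage subsets in multiplex
immunofluorescence images, and lipid-droplet volumetry in FIB-SEM
segmentation probability maps.

In fatty liver disease the resident Kupffer cell (KC) pool is progressively
replaced by recruited macrophages. In tissue sections the subsets are
distinguished by marker combinations — CLEC4F⁺TIM4⁺ resident KCs (ResKC),
CLEC4F⁺TIM4⁻ monocyte-derived KCs (moKC) and CLEC4F⁻ macrophages — and the
recruited cells accumulate in fibrotic, Desmin-high regions. `hepaquant`
implements the image-analysis side of that biology as a reproducible
pipeline for:

1. **Tiled macrophage detection** on the pan-macrophage F4/80 channel:
   per-tile median filtering and thresholding, assembly into one full-size
   mask, global connected-component labeling, hole filling and
   minimum-area particle filtering. With a fixed or global-Otsu threshold
   the result is provably identical for any tile size.
2. **Marker-gated classification**: per-cell mean intensities feed a
   hierarchical gate — CLEC4F ≥ θ_C4 and TIM4 ≥ θ_T4 → ResKC;
   CLEC4F ≥ θ_C4 and TIM4 < θ_T4 → moKC; CLEC4F < θ_C4 → CLEC4F⁻ mac.
3. **Desmin zoning and vessel exclusion**: smooth → threshold → clean
   segmentation of Desmin-high vs Desmin-low tissue; large vessels
   (Desmin⁺CD31⁺) excluded via a manual mask or an experimental automatic
   detector.
4. **Composition statistics**: per image, each subset's share of all
   macrophages and its split between Desmin-high and Desmin-low zones,
   with vessel-excluded cells removed from every denominator.
5. **Lipid-droplet volumetry** for 3D probability maps (e.g. from a
   trained segmentation network): threshold at p ≥ 0.5, removal of
   components smaller than 27 voxels (3×3×3), morphological opening with a
   spherical structuring element of radius 2 voxels, then per-component
   and total volumes in voxels and µm³.

A synthetic-data module generates both input types with exact ground truth
(cell positions and classes, zone maps, vessel masks, lattice droplet
volumes), so the whole pipeline is testable without any acquired data.

## Worked example

Simulate a default tissue image (60 ResKC, 25 moKC, 15 CLEC4F⁻ macs and 10
F4/80⁻ distractor cells planted; CLEC4F⁻ macs enriched 4× in Desmin-high
patches) and run the full 2D pipeline:

```python
from hepaquant import run_pipeline

config = {
    "simulate": True, "seed": 1,
    "classification": {"threshold_mode": "fixed",
                       "clec4f_threshold": 100.0, "tim4_threshold": 100.0},
}
table = run_pipeline(config, "demo_out")
print(table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
```

```
 image_id zone class_label  count  pct_of_total_macs  pct_of_class_in_zone  n_excluded
synthetic  all       ResKC     60               60.0                   NaN           0
synthetic  all        moKC     25               25.0                   NaN           0
synthetic  all    C4negMac     15               15.0                   NaN           0
synthetic   Hi       ResKC      3                NaN                   5.0           0
synthetic   Hi        moKC      3                NaN                  12.0           0
synthetic   Hi    C4negMac      4                NaN                  26.7           0
synthetic   Lo       ResKC     57                NaN                  95.0           0
synthetic   Lo        moKC     22                NaN                  88.0           0
synthetic   Lo    C4negMac     11                NaN                  73.3           0
```

All 100 planted macrophages are detected and classified correctly
(60/25/15% of total), the distractors are ignored, and the planted
enrichment direction is visible: 26.7% of CLEC4F⁻ macs sit in Desmin-high
tissue versus 5% of ResKCs. `pct_of_class_in_zone` sums to 100 per subset
over the two zones; cells whose centroid falls in an excluded vessel are
counted in `n_excluded` and in no percentage.

The droplet pipeline on a synthetic probability stack (8 blurred spheres,
radius 10 ± 1.5 voxels, 2% noise, 5 nm voxels):

```python
from hepaquant import (DropletSpec, DropletParams,
                       generate_droplet_stack, run_droplet_pipeline)

stack, truth = generate_droplet_stack(DropletSpec(seed=1))
res = run_droplet_pipeline(stack, DropletParams())
print(res.n_components, res.total_volume_voxels, f"{res.total_volume_um3:.4f}")
```

```
8 35345 0.0044
```

All 8 droplets are recovered; the measured 35,345 voxels are within 2% of
the exact lattice truth (35,962), the small deficit being the expected
cost of thresholding blurred surfaces and of the opening.

The same stages are available from the shell:

```sh
hepaquant simulate --seed 1 --out-dir sim/
hepaquant detect --input sim/image.tiff --out det.geojson --mask-out labels.tiff
hepaquant zones --input sim/image.tiff --vessel-mask sim/vessel_truth.tiff --out zonemap.tiff
hepaquant droplets --stack probs.tiff --threshold 0.5 --min-voxels 27 \
    --opening-radius 2 --voxel-size 5,5,5 --out-dir droplets_out/
```

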