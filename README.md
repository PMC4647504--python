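# nucland

Quantitative analysis of nuclear chromatin landscapes in 3D fluorescence
microscopy and 2D TEM images, with a fully ground-truthed synthetic data
generator.

Pipeline stages:

1. **Image model & masks** (`nucland.model`) — OME-TIFF stack I/O with
   physical voxel sizes (nm), and 3D nuclear mask generation from the DAPI
   channel (smoothing, Otsu/absolute threshold, largest 26-connected
   component, closing, exterior-aware hole filling that preserves surface
   invaginations and tunnels).
2. **Density classification** (`nucland.classify`) — equal-variance
   K-component Gaussian mixture EM fit (default K = 7) of masked DAPI
   intensities and per-voxel classification; class 1 is always the
   near-background class. An optional Potts spatial prior (hidden Markov
   random field) is available via `beta > 0` and iterated conditional
   modes; `beta = 0` (the reference setting) is the exact per-voxel
   posterior argmax.
3. **Marker topology** (`nucland.enrichment`) — thresholded marker voxels
   mapped onto density classes; relative enrichment/depletion
   `E_c = (M_c − D_c)/D_c`; Wilcoxon rank-sum comparison (continuity
   corrected) on per-nucleus class-weighted means.
4. **Spot quantification** (`nucland.spots`) — marker-positive pixel counts
   and discrete spots as 26-connected regional maxima above an intensity
   offset (plateaus count once, at their intensity-weighted centroid);
   optional anisotropy-aware minimum-distance suppression.
5. **TEM interface** (`nucland.interface`) — chromatin/IC interface length
   on 2D sections as chromatin perimeter minus nuclear perimeter,
   normalized by nuclear area. Perimeters use a smoothed marching-squares
   contour estimator (documented accuracy: ~0.4 % on digital circles,
   ~1.5 % on axis-aligned rectangles).
6. **Radial distance** (`nucland.radial`) — anisotropic Euclidean distance
   transform to the nuclear border; intensity-weighted relative-distance
   profiles (0 = border, 1 = deepest interior point, per-nucleus
   normalization); Mann–Whitney comparison of per-nucleus mean relative
   distances.
7. **Synthetic data** (`nucland.synth`) — multi-channel nuclei emulating
   progenitor / precursor / monocyte / granulocyte phenotypes with exact
   class-volume, marker-enrichment, spot and radial ground truth; TEM-like
   sections with analytic interface lengths; radial fixtures with designed
   depth profiles. Deterministic per seed.
8. **CLI / orchestration** (`nucland.cli`) — subcommands per stage plus a
   whole-study runner over a YAML manifest.

Conventions: arrays are `(z, y, x)`, 0-based, positions at voxel centers;
foreground connectivity 26, background 6; voxel sizes are `(dz, dy, dx)`
in nanometers.

## CLI

```sh
# generate a synthetic nucleus (stack + mask + truth JSON)
nucland simulate --phenotype granulocyte --seed 7 --out sim/

# 7-class density classification
nucland classify --dapi sim/stack.ome.tif --mask sim/mask.tif -K 7 \
    --out classmap.tif --summary classes.csv

# marker enrichment/depletion over classes
nucland enrich --classmap classmap.tif --dapi sim/stack.ome.tif \
    --marker-channel 1 --mask sim/mask.tif --out profile.csv

# spot and positive-pixel counts
nucland spots --marker sim/stack.ome.tif --mask sim/mask.tif \
    --offset 500 --out spots.csv

# chromatin/IC interface length of a 2D section
nucland interface --section tem.tif --mask mask2d.tif --pixel-size 10 \
    --out interface.csv

# radial profiles to the nuclear border
nucland radial --stack sim/stack.ome.tif --channels 1,2 \
    --mask sim/mask.tif --bins 20 --out radial.csv

# whole study from a YAML config (manifest of per-nucleus stacks)
nucland run --config study.yaml
```

A study config lists nuclei (`id`, `cell_type`, `stack`, `channels`,
optional `mask`/`voxel_size`) plus `K`, `beta`, `bins`, `spot_offset`,
`mask_threshold`, `output_dir`; outputs are per-nucleus and per-cell-type
CSV tables and a JSON provenance record, byte-stable for a fixed config.

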