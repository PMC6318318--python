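# immunoquant

Quantification pipelines for two common immunofluorescence readouts in
B-cell biology, with a seeded synthetic-scene generator providing exact
ground truth for every stage.

**Who this is for.** Labs scoring DNA-damage (γH2AX) foci in cultured
B cells grown on stromal feeders, and labs measuring per-cell marker
levels (e.g. Prmt5) inside germinal centers (GC) versus the surrounding
B-cell follicle (Fo) in tissue sections. Both analyses are simple to
describe and fiddly to implement reproducibly; this package pins every
convention down and tests it against brute-force oracles and planted
ground truth.

## The two pipelines

**1. Foci counting in B-cell nuclei.** Nuclei are found on the DAPI
channel by an Otsu threshold; the binary mask is cleaned of small
objects, hole-filled, and smoothed by morphological closing with a
5-pixel-radius disc. Multinuclear objects are removed by convex-hull
solidity: an object with

  solidity = area / convex-hull area < 0.8

is discarded. Feeder-cell nuclei are removed by keeping only objects of
area < 2% of the image. On the damage channel, contrast is enhanced by
saturating the bottom and top 1% of pixels, and puncta are detected
with a linear band-pass (difference of Gaussians) that keeps objects
bigger than noise up to twice the diffraction limit. Foci are assigned
to the nucleus under their centroid; only foci strictly brighter than
the mean focus intensity of untreated control images are counted, and
the headline statistic is the mean focus count per B-cell nucleus.

**2. GC/Fo marker ratios in tissue.** Cells are segmented by a
Laplacian-of-Gaussian filter, a median filter and a watershed; objects
larger than 5× a manually set typical cell area are discarded and
fragments smaller than 0.5× are fused into their most eccentric
neighbour. Marker signal per cell is the median intensity over a
cytoplasm band of thickness r/3 along the cell edge (r = radius of a
circular cell of typical area). Cells go to the GC or Fo compartment by
majority pixel overlap with the annotation masks; per-image intensities
are normalized to the brightest non-outlier cell (outliers flagged by a
Q3 + 3·IQR fence), averaged per compartment per follicle, then averaged
across follicles per mouse. The headline statistic is the per-mouse
GC/Fo ratio of mean normalized signal.

Both pipelines are validated on scenes from `immunoquant.synthetic`,
which plants B-cell discs, oversized feeder nuclei, low-solidity
dumbbell (multinuclear) objects, Gaussian puncta with known positions,
and GC/follicle tessellations with known per-compartment intensities.

## Worked example

```python
from immunoquant.config import SceneParams, SegmentationConfig, FociConfig
from immunoquant.synthetic import generate_foci_scene
from immunoquant.nuclei import segment_bcell_nuclei
from immunoquant.foci import count_foci_pipeline

params = SceneParams(seed=1, noise_sigma=2000.0)   # 50 B cells, 3 feeders,
dapi, damage, truth = generate_foci_scene(params)  # 2 dumbbells, k=3 foci
nuclei, objects = segment_bcell_nuclei(dapi, SegmentationConfig())
print(f"objects found: {len(objects)}")
print(f"discarded by solidity < 0.8: {sum(not o.passed_solidity for o in objects)}")
print(f"discarded by area >= 2%:     {sum(not o.passed_size for o in objects)}")
print(f"B-cell nuclei retained:      {nuclei.n_objects}")
foci, summary = count_foci_pipeline(damage, nuclei, FociConfig())
print(f"foci detected: {len(foci)}")
print(f"mean foci per B cell: {summary.mean_foci_per_cell:.2f}  (planted: 3)")
```

prints

```
objects found: 55
discarded by solidity < 0.8: 2
discarded by area >= 2%:     3
B-cell nuclei retained:      50
foci detected: 151
mean foci per B cell: 3.00  (planted: 3)
```

The 55 objects are the 50 planted B cells plus 3 feeders (caught by the
2% area rule) and 2 dumbbells (caught by the solidity rule); the
control-free threshold of 0 counts every detected in-nucleus focus, and
the per-cell mean recovers the planted k = 3 exactly despite the added
Gaussian noise.

## Command line

Every stage is also a CLI (`immunoquant --help`): `simulate foci-scene`
/ `simulate follicle-scene` write TIFF channels, masks and ground-truth
CSVs; `segment-nuclei`, `count-foci` and `quantify-follicle` consume
TIFF/PNG images (and GeoJSON polygon annotations for compartment masks)
and write CSV tables plus a JSON manifest with the config hash and
seed. Re-running any command with the same config and seed reproduces
the output tables byte for byte.

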