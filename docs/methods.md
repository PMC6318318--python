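# Methods

This note documents the models, conventions and numerical choices
behind the two quantification pipelines and the synthetic scenes used
to validate them. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Synthetic scenes

The generators exist so that every downstream stage can be tested
against exact ground truth. They emulate the *geometry and intensity
statistics* that matter to the algorithms, not microscope physics.

### Foci scenes (`generate_foci_scene`)

A scene is a pair of 16-bit channels (DAPI, damage) plus truth tables.

* **Objects.** B-cell nuclei are filled discs (a pixel belongs to a
  disc if its center lies within the radius); feeder nuclei are the
  same at a much larger radius; multinuclear objects are two
  B-cell-radius discs at a center distance of 2.8 radii joined by a
  2-px-wide bridge, whose continuous-geometry solidity (~0.76 for the
  defaults) sits below the 0.8 cutoff while a merged pair of discs at
  1.6 radii sits above it (~0.94). Objects are placed by rejection
  sampling with non-intersecting bounding discs separated by
  `min_gap_px` (default 12 px, chosen above the diameter of the
  closing element so that morphological closing can never fuse two
  planted nuclei). Placement failure raises an explicit error naming
  the constraint.
* **Foci.** Per B-cell counts are drawn from a fixed k, Poisson, or
  discrete-uniform spec. Foci are isotropic 2-D Gaussians of amplitude
  `focus_amplitude` and width `focus_sigma_px`, planted at least
  3.5 σ inside the nuclear rim (so ≥ 99.8% of each focus' mass
  integrates inside its nucleus) and `focus_min_separation_px` apart
  (default 8 px). The separation default makes planted constellations
  resolvable by a band-pass whose upper-edge smoothing is ~2.5 px;
  closer pairs are physically uncountable by any linear filter, and
  planting them would test the generator, not the detector. Dense
  constellations are placed with whole-set restarts.
* **Noise and quantization.** Additive Gaussian noise (default off)
  and optional Poisson shot noise, then rounding to 16-bit with
  saturation clipping. Default background 2000 and foreground
  amplitude 20000 leave ample headroom at the tested noise levels.
* **Determinism.** One `numpy` Generator seeded by the scene seed
  drives all draws in a fixed order (feeders, dumbbells, B cells,
  then foci per nucleus in object order, then noise), so identical
  parameters and seed give bit-identical images and tables.

What these scenes do *not* emulate: optical PSF beyond isotropic
Gaussians, intensity gradients, chromatic shifts, nucleus texture, or
touching mononuclear nuclei. Passing tests therefore demonstrate
correctness of the decision rules and robustness to pixel noise, not
performance on textured real-world nuclei.

### Follicle scenes (`generate_follicle_scene`)

Cells sit on a hexagonal lattice with per-cell area equal to
`typical_cell_area_px`, jittered by ±0.15 lattice spacings; the Voronoi
regions of the jittered sites form a contact-packed tessellation. The
`n_cells_gc` sites closest to the image center are the GC, the next
`n_cells_fo` the follicle; the GC mask is the disc bounded midway
between the outermost GC and innermost Fo cell, the Fo mask the
surrounding annulus, so the masks are disjoint and every planted cell
lies in exactly one region. DAPI shows bright cell interiors with 1-px
dark inter-cell boundaries; the marker channel gives every pixel of a
cell one intensity drawn from its compartment mean with the configured
CV (truncated at zero), outlier cells getting mean × multiplier
exactly. Truth records per-cell intensities and the non-outlier
per-compartment means.

Defaults (200 GC + 300 Fo cells of 100 px on a 320×320 field, CV 0.2,
GC/Fo means 20000/10000) are a deliberately reduced-scale version of
tissue fields in which a few thousand cells are typically processed;
they keep a single follicle image at a fraction of a second while
leaving ≥ 200 cells per compartment for stable means.

## 2. Nucleus segmentation

Pipeline: Otsu threshold → binary cleanup → 8-connected labelling →
solidity filter → size filter. Conventions that needed fixing:

* **Otsu** over a 256-equal-width-bin histogram of the observed range;
  foreground is strictly above the threshold; a constant image raises
  an error. Adjacent split bins can tie in between-class variance to
  float precision (e.g. across empty bins); the implementation takes
  the first maximum.
* **Cleanup order**: remove components with area < `min_object_px`
  (default 64 px, about a third of the smallest plausible nucleus at
  the generator's default scale), fill enclosed holes, then close with
  a discrete disc of radius 5 px.
* **Solidity** is computed on the pixel lattice: the convex hull of
  pixel-center coordinates, hull area as the count of lattice points
  inside or on the hull (collinear degenerate objects use the lattice
  points of the hull segment). This makes solidity a deterministic
  rational number, exactly testable against a brute-force half-plane
  hull. Discard iff solidity < 0.8 (strict), matching the rule's
  wording.
* **Size rule**: keep iff area < 0.02 × image area, strict, so an
  object of exactly 2% is discarded.
* Objects touching the border are retained by default
  (`keep_border_objects`); excluding them would bias per-cell counts.
* The returned audit list contains *all* objects with their pass/fail
  flags; the label mask is renumbered consecutively over survivors.

Touching mononuclear nuclei are not declumped (no watershed here):
the foci pipeline's statistics are per retained nucleus and the
generator plants non-touching nuclei, mirroring the sparse plated-cell
geometry this stage is meant for.

## 3. Focus detection and counting

* **Contrast enhancement**: clip at the 1st/99th percentiles and map
  affinely to [0, 1]. Degenerate images (lo == hi) raise an error.
* **Band-pass**: difference of Gaussians with FWHM-matched sigmas,
  σ_low = noise_size / 2.355 and σ_high = (2 × diffraction limit) /
  2.355. `diffraction_limit_px` is a required optics input (default
  3 px matches the generator's focus scale); the lower edge
  `noise_size_px` defaults to 2.5 px so that σ_low ≈ 1.06 px
  meaningfully attenuates single-pixel noise — at 1.5 px (σ ≈ 0.64)
  shot noise passes the filter nearly unchanged and, after percentile
  saturation, rivals true puncta.
* **Candidate segmentation**: connected components of the positive
  response above a threshold, then filtered to equivalent diameters in
  `(noise_size, 2 × diffraction limit]` and to peak response ≥
  `min_peak_prominence`. The threshold is the Otsu split of the
  positive response floored at `min_peak_prominence / 2`. The floor
  matters: when puncta occupy ≪ 1% of pixels the positive-response
  histogram is effectively unimodal noise, Otsu sinks into its tail,
  and candidates merge into sprawling noise components. With the floor
  and a default prominence of 0.25 (on the [0, 1] enhanced scale),
  detection at focus SNR 8 is complete with ≈ 0–2 false positives per
  384² frame (measured in the acceptance checks). Setting
  `min_peak_prominence: 0` restores the pure-Otsu behaviour, and
  `response_threshold` overrides the threshold entirely.
* **Centroids** are response-weighted, giving sub-pixel accuracy
  (≤ 0.2 px on noiseless in-band spots).
* **Control calibration**: the threshold is the arithmetic mean of the
  control detections' mean intensities (mean over member pixels of the
  contrast-enhanced image); sample foci must be *strictly* brighter.
  An empty control set raises an error directing the caller to a
  manual threshold rather than silently counting everything.
* **Assignment**: a focus belongs to the nucleus label under its
  (rounded) centroid — unambiguous for sub-nuclear puncta — and
  zero-focus nuclei are kept in the per-nucleus table so the mean per
  cell is over all analyzed nuclei.

## 4. Follicle quantification

* **Segmentation**: LoG (σ = `log_sigma_px`, default 3 px ≈ half the
  default cell radius) → disc median filter (radius 3 px) → watershed
  flooded from the regional minima of the filtered landscape. Bright
  interiors are minima plateaus; dark boundaries are the ridges. The
  contract is count accuracy (±10% on planted tessellations), not a
  specific basin geometry. Both filter parameters are per-run inputs
  since they track the imaging scale.
* **Prune/fuse**: objects > 5× typical area are discarded first
  (this also swallows the out-of-tissue watershed background basins);
  then fragments < 0.5× typical are merged, single-pass in ascending
  area (label number breaking ties), each into its 8-adjacent
  neighbour of largest eccentricity (second-moment definition),
  evaluated on the current partially merged mask; neighbourless
  fragments are dropped.
* **Cytoplasm band**: pixels of the cell whose exact Euclidean
  distance to the nearest non-cell pixel is strictly below r/3 with
  r = √(typical area / π). The band is measured inward from the
  segmented edge so the median never samples neighbouring cells; a
  cell thinner than the band is used whole. The image border counts
  as boundary.
* **Medians** use the even-count convention (mean of the two central
  order statistics).
* **Compartments** by majority pixel count over the GC/Fo masks; exact
  nonzero ties go to GC (GC annotations are drawn inside follicles, so
  ambiguity is rare and a fixed convention keeps runs deterministic);
  GC also wins overlapping annotation pixels on load. Cells in neither
  mask are excluded from all summaries.
* **Normalization**: per image, cells above Q3 + 3·IQR of the
  median-intensity distribution are flagged as outliers — a
  reproducible surrogate for manual histogram inspection — and the
  rest are divided by their maximum, putting all values in [0, 1] with
  exactly one cell at 1.0 when intensities are distinct. Quartiles are
  order statistics (`method="nearest"`): interpolated quartiles are
  dragged toward the outlier itself on small samples, defeating the
  fence. The fence multiplier is configurable.
* **Aggregation**: unweighted means per compartment per follicle over
  non-outlier cells; unweighted means of follicle means per mouse; the
  GC/Fo ratio is reported absent (not zero) when the Fo mean is zero
  or a compartment is empty.

## 5. Problem sizes and tolerances in the checks

The acceptance checks run nucleus recovery on 512² scenes (50 B cells,
3 feeders > 2% area, 2 dumbbells), focus recovery on 384² scenes
(30 B cells, k ∈ {0..5}, amplitude/noise 8), and ratio recovery on
mice of 4–7 follicles with 200 GC + 300 Fo cells each at CV 0.2 —
sizes chosen to give stable statistics at interactive runtimes.
Tolerances (exact equality for the rule oracles and zero-noise
recovery; ±2% retained nuclei at SNR 5; ≥ 95% exact per-nucleus focus
counts and ±5% mean foci per cell; ±10% on recovered ratios; < 2%
ratio shift from planted 10× outliers) are the contracts the
implementation is required to meet under those conditions.

## 6. Known limitations

* All stages are 2-D; stacks and time series are out of scope.
* No declumping of touching nuclei in the foci pipeline, and no
  automatic GC/Fo delineation — compartment masks are operator input.
* The watershed first approximation over-splits elongated cells at
  aggressive LoG scales; the prune/fuse stage corrects counts but the
  recovered cell boundaries are approximate, which is acceptable
  because downstream statistics are medians over an interior band.
* The focus-detector threshold floor assumes the enhanced image uses
  its full [0, 1] range (true whenever the 1%/99% percentiles
  differ); images whose puncta are dimmer than other structures in
  the same channel would need an explicit `response_threshold`.
* Detection of puncta closer than the band-pass resolution is
  impossible by construction; planted scenes respect this.
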