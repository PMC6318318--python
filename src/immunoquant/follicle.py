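"""Per-cell cytoplasmic marker quantification in tissue sections.

Cells are first approximated by a Laplacian-of-Gaussian filter, a
median filter and a watershed transformation; oversized objects are
discarded and undersized fragments fused into their most eccentric
neighbour. Marker signal is the median fluorescence over a cytoplasm
band of thickness radius/3 along each cell's edge (radius of a circular
cell of the manually set typical area). Cells are assigned to the
germinal-center (GC) or follicle (FO) compartment by majority pixel
overlap with the annotation masks, normalized per image to the maximal
non-outlier cell, then averaged per compartment per follicle and per
mouse; the headline output is the per-mouse GC/FO ratio.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import disk, local_minima
from skimage.segmentation import watershed

from .config import FollicleConfig
from .types import (CellRecord, ChannelImage, FollicleSummary, LabelMask,
                    MouseSummary)


def segment_cells(dapi: ChannelImage, cfg: FollicleConfig) -> LabelMask:
    """First-pass cell segmentation: LoG -> median filter -> watershed.

    The watershed floods the median-filtered LoG landscape from its
    regional minima (one marker per minimum plateau); bright cell
    interiors are LoG minima and the dark inter-cell boundaries form
    the ridges separating basins. The label count, not an exact basin
    geometry, is the contract here.
    """
    cfg.validate()
    pixels = np.asarray(dapi.pixels, dtype=float)
    landscape = ndimage.gaussian_laplace(pixels, sigma=cfg.log_sigma_px)
    landscape = ndimage.median_filter(
        landscape, footprint=disk(cfg.median_filter_radius_px))
    markers = measure.label(local_minima(landscape, connectivity=2),
                            connectivity=2)
    labels = watershed(landscape, markers=markers)
    return LabelMask(labels.astype(np.int32), connectivity=2)


def _eccentricity(coords: np.ndarray) -> float:
    """Elongation from the second moments of a pixel set, in [0, 1)."""
    if len(coords) < 2:
        return 0.0
    cov = np.cov(coords.astype(float).T, bias=True)
    evals = np.linalg.eigvalsh(cov)
    lam2, lam1 = max(evals[0], 0.0), max(evals[1], 1e-12)
    return float(np.sqrt(max(1.0 - lam2 / lam1, 0.0)))


def prune_and_fuse(mask: LabelMask, cfg: FollicleConfig) -> LabelMask:
    """Discard oversized objects; fuse undersized ones into neighbours.

    Objects larger than ``large_object_factor`` x typical area are
    removed first. Each remaining object smaller than
    ``small_object_factor`` x typical is then merged, in a single pass
    in ascending area order, into its 8-adjacent neighbour of largest
    eccentricity (evaluated on the current, partially merged mask);
    small objects with no neighbour are discarded. Output labels are
    renumbered consecutively.
    """
    cfg.validate()
    labels = mask.labels.copy()
    big = cfg.large_object_factor * cfg.typical_cell_area_px
    small = cfg.small_object_factor * cfg.typical_cell_area_px

    areas = np.bincount(labels.ravel())
    for lab in np.nonzero(areas > big)[0]:
        if lab:
            labels[labels == lab] = 0

    footprint = np.ones((3, 3), dtype=bool)
    small_labs = [int(lab) for lab in np.unique(labels)
                  if lab and np.count_nonzero(labels == lab) < small]
    small_labs.sort(key=lambda lab: (np.count_nonzero(labels == lab), lab))
    for lab in small_labs:
        region = labels == lab
        if not region.any():  # may have been absorbed already
            continue
        if np.count_nonzero(region) >= small:
            continue
        ring = ndimage.binary_dilation(region, structure=footprint) & ~region
        neighbours = np.unique(labels[ring])
        neighbours = neighbours[neighbours > 0]
        if len(neighbours) == 0:
            labels[region] = 0
            continue
        best = max(neighbours, key=lambda nb: (
            _eccentricity(np.argwhere(labels == nb)), -nb))
        labels[region] = best

    out = np.zeros_like(labels)
    for new, old in enumerate(sorted(np.unique(labels[labels > 0])), start=1):
        out[labels == old] = new
    return LabelMask(out, connectivity=mask.connectivity)


def cytoplasm_band(cell_mask: np.ndarray, cfg: FollicleConfig) -> np.ndarray:
    """Edge band of thickness radius/3 inside a cell's pixel set.

    ``radius`` is that of a circular cell of the typical area; the band
    holds cell pixels whose Euclidean distance to the nearest non-cell
    pixel is strictly below ``radius * band_fraction``. A cell entirely
    thinner than the band (or a band that would come out empty) returns
    the whole cell.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    if not cell.any():
        raise ValueError("cytoplasm_band requires a non-empty cell pixel set")
    r = np.sqrt(cfg.typical_cell_area_px / np.pi)
    # Pad so the image border counts as boundary.
    dist = ndimage.distance_transform_edt(np.pad(cell, 1))[1:-1, 1:-1]
    band = cell & (dist < r * cfg.band_fraction)
    if not band.any() or band.sum() == cell.sum():
        return cell
    return band


def measure_cell(band_mask: np.ndarray,
                 channels: dict[str, ChannelImage]) -> dict[str, float]:
    """Median intensity per channel over the cytoplasm-band pixels.

    Even-count medians are the mean of the two central order statistics.
    """
    band = np.asarray(band_mask, dtype=bool)
    if not band.any():
        raise ValueError("band is empty")
    return {name: float(np.median(np.asarray(ch.pixels, dtype=float)[band]))
            for name, ch in channels.items()}


def assign_compartment(cell_mask: np.ndarray, gc_mask: np.ndarray,
                       fo_mask: np.ndarray, cfg: FollicleConfig) -> str:
    """Majority-pixel compartment call: GC, FO, or none.

    Cells split between the masks go to the one with more pixels; exact
    nonzero ties go to ``cfg.tie_break_compartment``; cells outside both
    masks return ``"none"`` and are excluded from summaries.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    n_gc = int(np.count_nonzero(cell & (np.asarray(gc_mask) > 0)))
    n_fo = int(np.count_nonzero(cell & (np.asarray(fo_mask) > 0)))
    if n_gc == 0 and n_fo == 0:
        return "none"
    if n_gc > n_fo:
        return "GC"
    if n_fo > n_gc:
        return "FO"
    return cfg.tie_break_compartment


def normalize_cells(cells: list[CellRecord], channel: str,
                    cfg: FollicleConfig | None = None) -> list[CellRecord]:
    """Flag intensity outliers, then normalize to the maximal cell.

    Outliers are cells whose median intensity exceeds ``Q3 + k * IQR``
    of the per-image distribution (k = 3 by default), a reproducible
    surrogate for manual histogram inspection. The remaining cells are
    divided by the maximum remaining intensity, so results lie in
    [0, 1] with the brightest non-outlier cell at exactly 1.0.
    """
    cfg = cfg or FollicleConfig(typical_cell_area_px=1)
    values = np.array([c.median_intensity[channel] for c in cells], dtype=float)
    if len(values) < 2:
        raise ValueError("normalization needs at least two cells")
    # order-statistic quartiles: interpolated ones are dragged toward the
    # outlier itself on small samples, defeating the fence
    q1, q3 = np.percentile(values, [25, 75], method="nearest")
    fence = q3 + cfg.outlier_fence_multiplier * (q3 - q1)
    keep = values <= fence
    if not keep.any():
        raise ValueError("all cells flagged as outliers; cannot normalize")
    vmax = values[keep].max()
    if vmax <= 0:
        raise ValueError("maximal non-outlier intensity is zero")
    for cell, v, k in zip(cells, values, keep):
        cell.is_outlier = not k
        cell.normalized_signal = float(v / vmax) if k else None
    return cells


def summarize_follicle(cells: list[CellRecord],
                       follicle_id: str = "") -> FollicleSummary:
    """Mean normalized signal per compartment over non-outlier cells."""
    means: dict[str, float | None] = {}
    counts: dict[str, int] = {}
    for comp in ("GC", "FO"):
        vals = [c.normalized_signal for c in cells
                if c.compartment == comp and not c.is_outlier
                and c.normalized_signal is not None]
        counts[comp] = len(vals)
        means[comp] = float(np.mean(vals)) if vals else None
    return FollicleSummary(follicle_id=follicle_id, gc_mean=means["GC"],
                           fo_mean=means["FO"], n_gc=counts["GC"],
                           n_fo=counts["FO"])


def summarize_mouse(follicles: list[FollicleSummary],
                    mouse_id: str = "") -> MouseSummary:
    """Unweighted across-follicle averages and the GC/FO ratio."""
    if not follicles:
        raise ValueError("mouse summary needs at least one follicle")
    gc_vals = [f.gc_mean for f in follicles if f.gc_mean is not None]
    fo_vals = [f.fo_mean for f in follicles if f.fo_mean is not None]
    gc = float(np.mean(gc_vals)) if gc_vals else None
    fo = float(np.mean(fo_vals)) if fo_vals else None
    ratio = gc / fo if (gc is not None and fo is not None and fo > 0) else None
    return MouseSummary(mouse_id=mouse_id, gc_mean=gc, fo_mean=fo,
                        ratio=ratio, n_follicles=len(follicles))


def quantify_follicle(dapi: ChannelImage, channels: dict[str, ChannelImage],
                      gc_mask: np.ndarray, fo_mask: np.ndarray,
                      cfg: FollicleConfig, marker_channel: str,
                      follicle_id: str = "",
                      ) -> tuple[list[CellRecord], FollicleSummary]:
    """End-to-end quantification of one follicle image."""
    labels = segment_cells(dapi, cfg)
    labels = prune_and_fuse(labels, cfg)
    cells: list[CellRecord] = []
    for rp in measure.regionprops(labels.labels):
        sl = rp.slice
        cell = labels.labels[sl] == rp.label
        band = cytoplasm_band(cell, cfg)
        medians = {name: float(np.median(
            np.asarray(ch.pixels, dtype=float)[sl][band]))
            for name, ch in channels.items()}
        comp = assign_compartment(cell, np.asarray(gc_mask)[sl],
                                  np.asarray(fo_mask)[sl], cfg)
        cells.append(CellRecord(
            label=int(rp.label), area_px=int(rp.area),
            eccentricity=float(rp.eccentricity),
            cytoplasm_pixel_count=int(band.sum()),
            median_intensity=medians, compartment=comp,
        ))
    normalize_cells(cells, marker_channel, cfg)
    return cells, summarize_follicle(cells, follicle_id)
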