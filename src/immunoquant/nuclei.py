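"""B-cell nucleus segmentation from the DAPI channel.

Pipeline: Otsu threshold -> binary cleanup (small objects, holes,
closing with a 5-px disc) -> connected-component labelling -> discard
multinuclear objects by convex-hull solidity < 0.8 -> discard feeder
nuclei of area >= 2% of the image. Discarded objects are kept in the
audit list with their failure flags.

Solidity convention: the convex hull is taken over pixel-center
coordinates and its area is the number of lattice points (pixel
centers) inside or on the hull polygon, so ``solidity = n_pixels /
n_lattice_points_in_hull`` is deterministic and exactly testable.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .config import SegmentationConfig
from .types import ChannelImage, LabelMask, NucleusObject


class DegenerateImageError(ValueError):
    """Raised when an image has no contrast to threshold."""


def otsu_threshold(img: ChannelImage) -> float:
    """Otsu threshold over a 256-bin histogram of the observed range.

    Foreground is defined as pixels strictly above the returned value.
    Raises :class:`DegenerateImageError` for a constant image, where no
    between-class split exists.
    """
    pixels = np.asarray(img.pixels, dtype=float)
    if pixels.min() == pixels.max():
        raise DegenerateImageError("cannot threshold a constant image")
    return float(threshold_otsu(pixels, nbins=256))


def clean_binary(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Small-object removal, hole filling, then disc closing, in that order."""
    out = np.asarray(mask, dtype=bool)
    # remove components with area < min_object_px (max_size is inclusive)
    out = morphology.remove_small_objects(out, max_size=cfg.min_object_px - 1,
                                          connectivity=cfg.connectivity)
    out = ndimage.binary_fill_holes(out)
    footprint = morphology.disk(cfg.closing_radius_px)
    out = morphology.closing(out, footprint)
    return out


def lattice_convex_area(pixel_coords: np.ndarray) -> int:
    """Lattice-point count of the convex hull of pixel-center coordinates.

    Counts integer points inside or on the hull of ``pixel_coords``
    (an ``(n, 2)`` array of (row, col) pairs). Degenerate objects whose
    pixels are collinear use the lattice points on the hull segment.
    """
    pts = np.asarray(pixel_coords, dtype=float)
    if len(pts) == 0:
        return 0
    lo = pts.min(axis=0).astype(int)
    hi = pts.max(axis=0).astype(int)
    rr, cc = np.mgrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    tol = 1e-9
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # Collinear: count lattice points on the segment between extremes.
        p0, p1 = pts[np.lexsort(pts.T[::-1])][[0, -1]]
        d = p1 - p0
        if not d.any():
            return 1
        cross = (grid[:, 0] - p0[0]) * d[1] - (grid[:, 1] - p0[1]) * d[0]
        t = (grid - p0) @ d / float(d @ d)
        on = (np.abs(cross) < tol) & (t >= -tol) & (t <= 1 + tol)
        return int(on.sum())
    inside = np.ones(len(grid), dtype=bool)
    for a, b, c in hull.equations:  # a*x + b*y + c <= 0 inside
        inside &= grid[:, 0] * a + grid[:, 1] * b + c <= tol
    return int(inside.sum())


def _measure_objects(labels: np.ndarray) -> list[NucleusObject]:
    objs = []
    for rp in measure.regionprops(labels):
        coords = rp.coords
        conv = lattice_convex_area(coords)
        objs.append(NucleusObject(
            label=int(rp.label), area_px=int(rp.area),
            convex_area_px=conv, solidity=rp.area / conv,
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
        ))
    return objs


def _relabel(labels: np.ndarray, keep: set[int],
             connectivity: int) -> LabelMask:
    out = np.where(np.isin(labels, list(keep)), labels, 0)
    # Renumber consecutively from 1, preserving raster order of labels.
    remap = {old: new for new, old in enumerate(sorted(keep), start=1)}
    relabelled = np.zeros_like(out)
    for old, new in remap.items():
        relabelled[out == old] = new
    return LabelMask(relabelled, connectivity=connectivity)


def filter_multinuclear(mask: LabelMask, cfg: SegmentationConfig,
                        objects: list[NucleusObject] | None = None,
                        ) -> tuple[LabelMask, list[NucleusObject]]:
    """Discard objects whose solidity falls below ``cfg.solidity_min``."""
    labels = mask.labels
    objects = objects if objects is not None else _measure_objects(labels)
    for obj in objects:
        obj.passed_solidity = obj.solidity >= cfg.solidity_min
    keep = {o.label for o in objects if o.passed_solidity}
    return _relabel(labels, keep, mask.connectivity), objects


def filter_feeder(mask: LabelMask, cfg: SegmentationConfig,
                  image_area_px: int,
                  objects: list[NucleusObject] | None = None,
                  ) -> tuple[LabelMask, list[NucleusObject]]:
    """Keep only objects of area strictly below 2% of the image size."""
    labels = mask.labels
    objects = objects if objects is not None else _measure_objects(labels)
    cutoff = cfg.max_area_fraction * image_area_px
    for obj in objects:
        obj.passed_size = obj.area_px < cutoff
    keep = {o.label for o in objects if o.passed_size}
    return _relabel(labels, keep, mask.connectivity), objects


def segment_bcell_nuclei(dapi: ChannelImage, cfg: SegmentationConfig,
                         ) -> tuple[LabelMask, list[NucleusObject]]:
    """Full nuclear pipeline; returns B-cell-only labels plus an audit list.

    The audit list records every object found after cleanup, including
    the ones the solidity and size filters discarded, with their flags.
    Retained labels in the returned mask are renumbered consecutively.
    """
    cfg.validate()
    thr = otsu_threshold(dapi)
    binary = np.asarray(dapi.pixels, dtype=float) > thr
    binary = clean_binary(binary, cfg)
    if not cfg.keep_border_objects:
        from skimage.segmentation import clear_border
        binary = clear_border(binary)
    labels = measure.label(binary, connectivity=cfg.connectivity)
    objects = _measure_objects(labels)

    for obj in objects:
        obj.passed_solidity = obj.solidity >= cfg.solidity_min
    cutoff = cfg.max_area_fraction * dapi.pixels.size
    for obj in objects:
        obj.passed_size = obj.area_px < cutoff
    keep = {o.label for o in objects if o.retained}
    return _relabel(labels, keep, cfg.connectivity), objects
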