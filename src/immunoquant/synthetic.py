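"""Seeded synthetic microscopy scenes with exact ground truth.

Two scene families are generated:

* **Foci scenes** emulate the feeder co-culture fields used for DNA-damage
  scoring: densely packed small B-cell nuclei, sparse very large feeder
  nuclei, dumbbell-shaped multinuclear objects, and sub-diffraction
  Gaussian puncta planted inside B-cell nuclei on the damage channel.
* **Follicle scenes** emulate tissue sections: a contact-packed layout of
  a few hundred cells partitioned into a central germinal centre (GC)
  and a surrounding follicle (FO), with distinct mean marker intensities
  per compartment.

All stochastic choices draw from a single ``numpy`` Generator seeded by
the scene seed, in a fixed documented order (feeders, multinuclear
objects, B cells, then foci; lattice jitter then intensities), so
identical parameters and seed give bit-identical images and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import FollicleSceneParams, SceneParams
from .types import ChannelImage, LabelMask

_MAX_PLACEMENT_TRIES = 2000


class PlacementError(RuntimeError):
    """Raised when non-overlapping object placement is infeasible."""


@dataclass
class SceneTruth:
    """Generator ground truth: planted objects, foci, cells and means."""

    objects: pd.DataFrame = field(default_factory=pd.DataFrame)
    foci: pd.DataFrame = field(default_factory=pd.DataFrame)
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    compartment_means: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)


def _quantize(img: np.ndarray) -> np.ndarray:
    """Round to 16-bit unsigned with saturation clipping."""
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def _disc_pixels(shape: tuple[int, int], center: tuple[float, float],
                 radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel (row, col) indices whose centers lie within ``radius``."""
    r0, c0 = center
    rmin = max(int(np.floor(r0 - radius)) - 1, 0)
    rmax = min(int(np.ceil(r0 + radius)) + 2, shape[0])
    cmin = max(int(np.floor(c0 - radius)) - 1, 0)
    cmax = min(int(np.ceil(c0 + radius)) + 2, shape[1])
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    keep = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    return rr[keep], cc[keep]


def _stamp_disc(canvas: np.ndarray, center: tuple[float, float],
                radius: float, level: float) -> None:
    rr, cc = _disc_pixels(canvas.shape, center, radius)
    canvas[rr, cc] = level


def _stamp_bridge(canvas: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                  half_width: float, level: float) -> None:
    """Paint pixels within ``half_width`` of the segment p0-p1."""
    lo = np.maximum(np.floor(np.minimum(p0, p1) - half_width - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + half_width + 2).astype(int),
                    np.array(canvas.shape))
    rr, cc = np.mgrid[lo[0]:hi[0], lo[1]:hi[1]]
    d = p1 - p0
    L2 = float(d @ d)
    t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    dist2 = (rr - (p0[0] + t * d[0])) ** 2 + (cc - (p0[1] + t * d[1])) ** 2
    keep = dist2 <= half_width ** 2
    canvas[rr[keep], cc[keep]] = level


def _place_objects(rng: np.random.Generator, shape: tuple[int, int],
                   specs: list[tuple[str, float, float]]) -> list[dict]:
    """Place objects with non-overlapping bounding discs by rejection.

    ``specs`` holds (class, draw_radius, bounding_radius) per object;
    bounding discs of distinct objects may not intersect and must stay
    inside the image.
    """
    h, w = shape
    placed: list[dict] = []
    for cls, radius, bound in specs:
        if 2 * bound >= min(h, w):
            raise PlacementError(
                f"{cls} object with bounding radius {bound:.1f} does not fit "
                f"in a {h}x{w} image"
            )
        for _ in range(_MAX_PLACEMENT_TRIES):
            r0 = rng.uniform(bound, h - bound)
            c0 = rng.uniform(bound, w - bound)
            ok = all((r0 - o["row"]) ** 2 + (c0 - o["col"]) ** 2
                     > (bound + o["bound"]) ** 2 for o in placed)
            if ok:
                placed.append({"class": cls, "row": r0, "col": c0,
                               "radius": radius, "bound": bound})
                break
        else:
            raise PlacementError(
                f"could not place {cls} object without overlap after "
                f"{_MAX_PLACEMENT_TRIES} tries (scene too crowded)"
            )
    return placed


def _draw_focus_count(rng: np.random.Generator, spec: Any) -> int:
    if isinstance(spec, dict):
        if "poisson" in spec:
            return int(rng.poisson(spec["poisson"]))
        lo, hi = spec["uniform"]
        return int(rng.integers(lo, hi + 1))
    return int(spec)


def generate_foci_scene(params: SceneParams) -> tuple[ChannelImage, ChannelImage, SceneTruth]:
    """Render a DAPI + damage channel pair with planted ground truth.

    The DAPI channel carries filled nucleus discs (a pixel belongs to a
    disc if its center lies within the radius); multinuclear objects are
    two B-cell-radius discs at 2.8x radius center distance joined by a
    2-px-wide bridge, giving continuous-geometry solidity below the 0.8
    cutoff. The damage channel carries isotropic 2-D Gaussian puncta at
    the truth focus positions over a flat background. Foci are planted
    at least ``3.5 * focus_sigma_px`` inside the nuclear rim so their
    mass integrates inside the nucleus, and at
    ``focus_min_separation_px`` mutual distance so planted counts are
    optically meaningful.
    """
    params.validate()
    shape = (params.image_height_px, params.image_width_px)
    image_area = shape[0] * shape[1]

    # Feasibility: total nucleus area must stay under 60% of the image.
    area = (params.n_feeder_nuclei * np.pi * params.feeder_radius_px ** 2
            + (params.n_bcell_nuclei + 2 * params.n_multinuclear)
            * np.pi * params.bcell_radius_px ** 2)
    if area >= 0.6 * image_area:
        raise PlacementError(
            f"requested nuclei cover {100 * area / image_area:.0f}% of the "
            "image; placement requires < 60%"
        )

    rng = np.random.default_rng(params.seed)
    rb = params.bcell_radius_px
    # Largest objects first: feeders, dumbbells, then B cells.
    specs = ([("feeder", params.feeder_radius_px, params.feeder_radius_px + params.min_gap_px / 2)]
             * params.n_feeder_nuclei
             + [("multinuclear", rb, 2.4 * rb + params.min_gap_px / 2)] * params.n_multinuclear
             + [("bcell", rb, rb + params.min_gap_px / 2)] * params.n_bcell_nuclei)
    placed = _place_objects(rng, shape, specs)

    dapi = np.full(shape, params.background_level, dtype=float)
    obj_rows = []
    for i, obj in enumerate(placed):
        if obj["class"] == "multinuclear":
            theta = rng.uniform(0, 2 * np.pi)
            offset = 1.4 * rb * np.array([np.sin(theta), np.cos(theta)])
            center = np.array([obj["row"], obj["col"]])
            p0, p1 = center - offset, center + offset
            level = params.background_level + params.nucleus_amplitude
            _stamp_disc(dapi, tuple(p0), rb, level)
            _stamp_disc(dapi, tuple(p1), rb, level)
            _stamp_bridge(dapi, p0, p1, 1.0, level)
        else:
            _stamp_disc(dapi, (obj["row"], obj["col"]), obj["radius"],
                        params.background_level + params.nucleus_amplitude)
        obj_rows.append({"object_id": i, "class": obj["class"],
                         "row": obj["row"], "col": obj["col"],
                         "radius": obj["radius"], "compartment": "none"})
    objects = pd.DataFrame(obj_rows, columns=["object_id", "class", "row",
                                              "col", "radius", "compartment"])

    # Foci: planted only inside B-cell nuclei, in object order.
    margin = 3.5 * params.focus_sigma_px
    damage = np.full(shape, params.background_level, dtype=float)
    focus_rows = []
    fid = 0
    for _, obj in objects.iterrows():
        if obj["class"] != "bcell":
            continue
        k = _draw_focus_count(rng, params.foci_per_nucleus)
        rmax = max(obj["radius"] - margin, 0.0)
        # Greedy placement can wedge itself for dense constellations, so
        # restart the whole constellation on failure.
        pts: list[np.ndarray] = []
        for _restart in range(200):
            pts = []
            for _ in range(k):
                for _try in range(200):
                    rho = rmax * np.sqrt(rng.uniform())
                    ang = rng.uniform(0, 2 * np.pi)
                    p = np.array([obj["row"] + rho * np.sin(ang),
                                  obj["col"] + rho * np.cos(ang)])
                    if all(np.hypot(*(p - q)) >= params.focus_min_separation_px
                           for q in pts):
                        pts.append(p)
                        break
                else:
                    break
            if len(pts) == k:
                break
        else:
            raise PlacementError(
                f"could not place {k} separated foci within a nucleus of "
                f"radius {obj['radius']:.1f}"
            )
        for p in pts:
            focus_rows.append({"focus_id": fid, "parent_object_id": int(obj["object_id"]),
                               "row": p[0], "col": p[1],
                               "amplitude": params.focus_amplitude,
                               "sigma": params.focus_sigma_px})
            fid += 1
    foci = pd.DataFrame(focus_rows, columns=["focus_id", "parent_object_id",
                                             "row", "col", "amplitude", "sigma"])
    for _, f in foci.iterrows():
        add_gaussian_spot(damage, (f["row"], f["col"]), f["sigma"], f["amplitude"])

    for canvas in (dapi, damage):
        if params.poisson_noise:
            canvas[:] = rng.poisson(np.maximum(canvas, 0)).astype(float)
        if params.noise_sigma > 0:
            canvas += rng.normal(0.0, params.noise_sigma, size=shape)

    truth = SceneTruth(objects=objects, foci=foci, seed=params.seed,
                       params=vars(params).copy())
    return (ChannelImage(_quantize(dapi), "DAPI"),
            ChannelImage(_quantize(damage), "damage"), truth)


def add_gaussian_spot(canvas: np.ndarray, center: tuple[float, float],
                      sigma: float, amplitude: float,
                      truncate: float = 6.0) -> None:
    """Add a 2-D isotropic Gaussian punctum in place."""
    r0, c0 = center
    ext = truncate * sigma
    rmin = max(int(np.floor(r0 - ext)), 0)
    rmax = min(int(np.ceil(r0 + ext)) + 1, canvas.shape[0])
    cmin = max(int(np.floor(c0 - ext)), 0)
    cmax = min(int(np.ceil(c0 + ext)) + 1, canvas.shape[1])
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    canvas[rmin:rmax, cmin:cmax] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma ** 2))


def generate_follicle_scene(params: FollicleSceneParams) -> tuple[
        ChannelImage, ChannelImage, LabelMask, LabelMask, SceneTruth]:
    """Render a tissue field split into a central GC and surrounding FO.

    Cells sit on a jittered hexagonal lattice; the Voronoi regions of the
    jittered sites form a contact-packed tessellation with 1-px dark
    boundaries in the DAPI channel. The marker channel gives every pixel
    of a cell that cell's planted intensity, drawn from its compartment
    mean with the stated coefficient of variation; planted outlier cells
    get ``compartment mean x outlier_multiplier`` exactly. The GC mask is
    the central disc bounded midway between the outermost GC cell and the
    innermost FO cell; the FO mask is the surrounding annulus. Truth
    compartment means are recorded over non-outlier cells.
    """
    params.validate()
    shape = (params.image_height_px, params.image_width_px)
    rng = np.random.default_rng(params.seed)

    # Hexagonal lattice with per-cell area matching typical_cell_area_px.
    a = float(np.sqrt(2.0 * params.typical_cell_area_px / np.sqrt(3.0)))
    row_step = a * np.sqrt(3.0) / 2.0
    ctr = np.array([shape[0] / 2.0, shape[1] / 2.0])
    sites = []
    n_rows = int(shape[0] / row_step) + 2
    n_cols = int(shape[1] / a) + 2
    for i in range(-n_rows, n_rows + 1):
        for j in range(-n_cols, n_cols + 1):
            r = ctr[0] + i * row_step
            c = ctr[1] + (j + 0.5 * (i % 2)) * a
            if a <= r < shape[0] - a and a <= c < shape[1] - a:
                sites.append((r, c))
    sites_arr = np.asarray(sites)
    jitter = rng.uniform(-params.jitter_frac * a, params.jitter_frac * a,
                         size=sites_arr.shape)
    sites_arr = sites_arr + jitter

    n_total = params.n_cells_gc + params.n_cells_fo
    if len(sites_arr) < n_total:
        raise PlacementError(
            f"image holds only {len(sites_arr)} lattice cells; "
            f"{n_total} requested"
        )
    dist = np.hypot(sites_arr[:, 0] - ctr[0], sites_arr[:, 1] - ctr[1])
    order = np.argsort(dist, kind="stable")
    gc_idx = order[:params.n_cells_gc]
    fo_idx = order[params.n_cells_gc:n_total]
    used = np.concatenate([gc_idx, fo_idx])
    cells_xy = sites_arr[used]
    compartments = np.array(["GC"] * len(gc_idx) + ["FO"] * len(fo_idx))

    # Region boundary midway between outermost GC and innermost FO cell.
    if len(gc_idx) and len(fo_idx):
        r_gc = 0.5 * (dist[gc_idx].max() + dist[fo_idx].min())
    elif len(gc_idx):
        r_gc = dist[gc_idx].max() + a / 2.0
    else:
        r_gc = 0.0
    r_outer = (dist[fo_idx].max() if len(fo_idx) else r_gc) + a / 2.0

    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    pix_dist = np.hypot(rr - ctr[0], cc - ctr[1])
    gc_mask = pix_dist <= r_gc
    fo_mask = (pix_dist > r_gc) & (pix_dist <= r_outer)
    tissue = gc_mask | fo_mask

    # Voronoi tessellation of the tissue region over the planted sites.
    tree = cKDTree(cells_xy)
    flat = np.column_stack([rr[tissue], cc[tissue]])
    _, owner = tree.query(flat, workers=1)
    label_img = np.zeros(shape, dtype=np.int32)
    label_img[tissue] = owner + 1

    # Cell boundaries: pixels whose 4-neighbourhood mixes owners.
    pad = np.pad(label_img, 1, mode="edge")
    boundary = np.zeros(shape, dtype=bool)
    for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
        boundary |= pad[1 + dr:shape[0] + 1 + dr, 1 + dc:shape[1] + 1 + dc] != label_img
    boundary &= tissue

    # Per-cell marker intensities, drawn in cell order.
    means = np.where(compartments == "GC", params.marker_mean_gc,
                     params.marker_mean_fo)
    if params.intensity_cv > 0:
        intensities = rng.normal(means, params.intensity_cv * means)
        intensities = np.maximum(intensities, 0.0)
    else:
        intensities = means.astype(float)
    outlier_flags = np.zeros(len(cells_xy), dtype=bool)
    if params.n_outlier_cells:
        out_idx = rng.choice(len(cells_xy), size=params.n_outlier_cells,
                             replace=False)
        outlier_flags[out_idx] = True
        intensities[out_idx] = means[out_idx] * params.outlier_multiplier

    marker = np.zeros(shape, dtype=float)
    inside = label_img > 0
    marker[inside] = intensities[label_img[inside] - 1]
    dapi = np.zeros(shape, dtype=float)
    dapi[inside & ~boundary] = params.dapi_cell_level

    if params.noise_sigma > 0:
        dapi += rng.normal(0.0, params.noise_sigma, size=shape)
        marker += rng.normal(0.0, params.noise_sigma, size=shape)

    keep = ~outlier_flags
    comp_means = {}
    for comp in ("GC", "FO"):
        sel = keep & (compartments == comp)
        if sel.any():
            comp_means[comp] = float(intensities[sel].mean())
    cells = pd.DataFrame({
        "cell_id": np.arange(len(cells_xy)),
        "row": cells_xy[:, 0], "col": cells_xy[:, 1],
        "compartment": compartments, "intensity": intensities,
        "is_outlier": outlier_flags,
    })
    truth = SceneTruth(cells=cells, compartment_means=comp_means,
                       seed=params.seed, params=vars(params).copy())
    return (ChannelImage(_quantize(dapi), "DAPI"),
            ChannelImage(_quantize(marker), "marker"),
            LabelMask(gc_mask.astype(np.uint8), connectivity=2),
            LabelMask(fo_mask.astype(np.uint8), connectivity=2),
            truth)
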