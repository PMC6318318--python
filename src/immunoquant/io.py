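"""Readers and writers for the formats the pipelines touch.

Images are TIFF (single- or multi-page) or PNG; annotation masks may
also arrive as GeoJSON polygons, rasterized on load. Tables go out as
CSV with a JSON manifest recording input paths, the effective config
hash, the seed and package version, so a run is reproducible from its
output directory alone. Any nonzero pixel is foreground when a mask is
read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .synthetic import SceneTruth
from .types import (CellRecord, ChannelImage, FociSummary, FocusRecord,
                    FollicleSummary, LabelMask, MouseSummary, NucleusObject)


class ImageReadError(IOError):
    """Raised when an image cannot be read or has the wrong channel count."""


def read_image(path: str | Path,
               expected_channels: list[str] | None = None) -> list[ChannelImage]:
    """Read a TIFF/PNG into per-channel images, matched to names by order.

    Integer inputs are preserved losslessly; TIFF resolution metadata is
    converted to a pixel size in micrometres when present.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such image file: {path}")
    pixel_size = None
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tf:
                pages = [p.asarray() for p in tf.pages]
                pixel_size = _pixel_size_um(tf.pages[0])
            data = np.stack(pages) if len(pages) > 1 else pages[0]
        else:
            data = iio.imread(path)
    except Exception as exc:
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    if data.ndim == 2:
        planes = [data]
    elif data.ndim == 3:
        # channel axis first for multi-page TIFF, last for RGB PNG
        planes = list(data) if data.shape[0] <= data.shape[-1] else \
            [data[..., i] for i in range(data.shape[-1])]
    else:
        raise ImageReadError(f"unsupported image dimensionality {data.ndim}")
    if expected_channels is not None and len(planes) != len(expected_channels):
        raise ImageReadError(
            f"{path}: expected {len(expected_channels)} channel(s) "
            f"{expected_channels}, found {len(planes)}"
        )
    names = expected_channels or [f"ch{i}" for i in range(len(planes))]
    return [ChannelImage(p, name, pixel_size) for p, name in zip(planes, names)]


def _pixel_size_um(page) -> float | None:
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    per_unit = xres[0] / xres[1] if isinstance(xres, tuple) else float(xres)
    if per_unit <= 0:
        return None
    scale = {2: 25400.0, 3: 10000.0}.get(int(unit))  # inch / cm -> um
    return scale / per_unit if scale else None


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a binary mask: nonzero pixels are foreground.

    PNG/TIFF rasters are thresholded at > 0; ``.json``/``.geojson``
    files are treated as polygon annotations and rasterized (``shape``
    is then required).
    """
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        if shape is None:
            raise ValueError("rasterizing polygon annotations requires a shape")
        return rasterize_polygons(json.loads(path.read_text()), shape)
    planes = read_image(path)
    return np.asarray(planes[0].pixels) > 0


def rasterize_polygons(geojson: dict, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize GeoJSON polygons ((col, row) = (x, y) coordinates)."""
    from skimage.draw import polygon as draw_polygon

    mask = np.zeros(shape, dtype=bool)
    feats = geojson.get("features", [geojson]) if "features" in geojson \
        else [geojson]
    for feat in feats:
        geom = feat.get("geometry", feat)
        polys = [geom["coordinates"]] if geom["type"] == "Polygon" \
            else geom["coordinates"]
        for poly in polys:
            ring = np.asarray(poly[0], dtype=float)
            rr, cc = draw_polygon(ring[:, 1], ring[:, 0], shape=shape)
            mask[rr, cc] = True
    return mask


def write_channel(img: ChannelImage, path: str | Path) -> None:
    """Write one channel as 16-bit grayscale TIFF."""
    data = np.asarray(img.pixels)
    if data.dtype != np.uint16:
        data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    data = np.asarray(mask.labels)
    dtype = np.uint8 if data.max() < 256 else np.uint16
    tifffile.imwrite(str(path), data.astype(dtype))


# ---------------------------------------------------------------------------
# Result tables


def nuclei_table(objects: list[NucleusObject]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"label": o.label, "area_px": o.area_px,
          "convex_area_px": o.convex_area_px, "solidity": o.solidity,
          "centroid_row": o.centroid[0], "centroid_col": o.centroid[1],
          "passed_solidity": o.passed_solidity, "passed_size": o.passed_size}
         for o in objects],
        columns=["label", "area_px", "convex_area_px", "solidity",
                 "centroid_row", "centroid_col", "passed_solidity",
                 "passed_size"])


def foci_table(foci: list[FocusRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"focus_id": f.focus_id, "row": f.centroid[0], "col": f.centroid[1],
          "equivalent_diameter_px": f.equivalent_diameter_px,
          "mean_intensity": f.mean_intensity,
          "parent_nucleus_label": f.parent_nucleus_label,
          "passed_control_threshold": f.passed_control_threshold}
         for f in foci],
        columns=["focus_id", "row", "col", "equivalent_diameter_px",
                 "mean_intensity", "parent_nucleus_label",
                 "passed_control_threshold"])


def foci_summary_table(summary: FociSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [{"nucleus_label": lab, "n_foci": n}
         for lab, n in sorted(summary.per_nucleus_counts.items())],
        columns=["nucleus_label", "n_foci"])


def cells_table(cells: list[CellRecord]) -> pd.DataFrame:
    channels = sorted({ch for c in cells for ch in c.median_intensity})
    rows = []
    for c in cells:
        row = {"label": c.label, "area_px": c.area_px,
               "eccentricity": c.eccentricity,
               "cytoplasm_pixel_count": c.cytoplasm_pixel_count,
               "compartment": c.compartment,
               "normalized_signal": c.normalized_signal,
               "is_outlier": c.is_outlier}
        for ch in channels:
            row[f"median_{ch}"] = c.median_intensity.get(ch)
        rows.append(row)
    cols = (["label", "area_px", "eccentricity", "cytoplasm_pixel_count",
             "compartment"] + [f"median_{ch}" for ch in channels]
            + ["normalized_signal", "is_outlier"])
    return pd.DataFrame(rows, columns=cols)


def follicle_table(summaries: list[FollicleSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"follicle_id": s.follicle_id, "gc_mean": s.gc_mean,
          "fo_mean": s.fo_mean, "n_gc": s.n_gc, "n_fo": s.n_fo}
         for s in summaries],
        columns=["follicle_id", "gc_mean", "fo_mean", "n_gc", "n_fo"])


def mouse_table(summaries: list[MouseSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"mouse_id": s.mouse_id, "gc_mean": s.gc_mean, "fo_mean": s.fo_mean,
          "gc_fo_ratio": s.ratio, "n_follicles": s.n_follicles}
         for s in summaries],
        columns=["mouse_id", "gc_mean", "fo_mean", "gc_fo_ratio",
                 "n_follicles"])


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  inputs: list[str] | None = None,
                  config_hash: str | None = None,
                  seed: int | None = None) -> Path:
    """Write one CSV per table plus a JSON manifest; returns manifest path.

    Re-running with identical inputs and config reproduces identical
    CSV bytes (floats are serialized with ``repr`` round-tripping).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False, lineterminator="\n")
        written[name] = path.name
    manifest = {
        "tables": written,
        "inputs": inputs or [],
        "config_hash": config_hash,
        "seed": seed,
        "package_version": __version__,
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return mpath


def write_scene_truth(truth: SceneTruth, out_dir: str | Path) -> None:
    """SceneTruth as CSV tables plus a JSON sidecar with params and seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("objects", "foci", "cells"):
        table: pd.DataFrame = getattr(truth, name)
        if len(table):
            table.to_csv(out_dir / f"truth_{name}.csv", index=False,
                         lineterminator="\n")
    sidecar = {"seed": truth.seed, "params": truth.params,
               "compartment_means": truth.compartment_means}
    (out_dir / "truth.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True, default=str) + "\n")
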