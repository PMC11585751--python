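"""File readers and writers: images, GeoJSON ROI annotations, CSV tables."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .classification import NucleusRecord, records_to_frame
from .scoring import ROIPolygon, ROIScore
from .stain import RGBImage

logger = logging.getLogger(__name__)

__all__ = [
    "read_image",
    "write_image",
    "read_roi_annotations",
    "write_roi_annotations",
    "write_roi_scores_csv",
    "write_nucleus_csv",
]


def read_image(path: str | Path, mpp: float) -> RGBImage:
    """Load a TIFF or PNG brightfield image.

    ``mpp`` (microns per pixel) must be supplied by the caller — no TIFF-tag
    sniffing.  Grayscale inputs are rejected; an alpha channel is dropped.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3 and px.shape[2] == 4:
        px = px[..., :3]
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {px.shape}")
    return RGBImage(pixels=px, mpp=mpp)


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    path = Path(path)
    pixels = np.asarray(pixels, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


def read_roi_annotations(path: str | Path) -> list[ROIPolygon]:
    """Parse a GeoJSON FeatureCollection of Polygon ROIs.

    The feature ``id`` (or ``properties.id``, or a generated index) becomes
    the ROI id.  Non-polygon features are skipped with a warning; an empty
    collection is an error.  Only exterior rings are used.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    polys: list[ROIPolygon] = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            logger.warning(
                "%s: skipping non-polygon feature %d (%s)",
                path, i, geom.get("type"),
            )
            continue
        roi_id = str(
            feat.get("id") or (feat.get("properties") or {}).get("id") or f"roi{i + 1}"
        )
        ring = geom["coordinates"][0]
        verts = np.asarray(ring, dtype=float)
        if len(verts) > 1 and np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]  # GeoJSON closes rings explicitly; we close implicitly
        polys.append(ROIPolygon(vertices=verts, id=roi_id))
    if not polys:
        raise ValueError(f"{path}: no polygon features found")
    return polys


def write_roi_annotations(path: str | Path, polys: list[ROIPolygon]) -> None:
    """Write ROI polygons as a GeoJSON FeatureCollection."""
    features = []
    for poly in polys:
        ring = [[float(x), float(y)] for x, y in poly.vertices]
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "id": poly.id,
                "properties": {"id": poly.id},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def write_roi_scores_csv(path: str | Path, scores: list[ROIScore]) -> None:
    """Per-ROI results CSV; PI shown at the conventional 0.1 pp precision."""
    import pandas as pd

    rows = []
    for s in scores:
        rows.append(
            {
                "roi_id": s.roi_id,
                "n_pos": s.n_pos,
                "n_neg": s.n_neg,
                "n_total": s.n_total,
                "pi_percent": "" if s.empty else f"{s.pi_percent:.1f}",
                "area_mm2": "" if s.area_mm2 is None else f"{s.area_mm2:.4f}",
                "flags": "no_cells_in_roi" if s.empty else "",
            }
        )
    pd.DataFrame(
        rows,
        columns=["roi_id", "n_pos", "n_neg", "n_total", "pi_percent", "area_mm2", "flags"],
    ).to_csv(path, index=False)


def write_nucleus_csv(path: str | Path, records: list[NucleusRecord]) -> None:
    records_to_frame(records).to_csv(path, index=False)
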