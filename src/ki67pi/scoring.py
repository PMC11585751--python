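"""Per-ROI Ki-67 proliferation index and annotation overlays.

The proliferation index (PI) of a region of interest is the percentage of
Ki-67 positive nuclei among all nuclei whose centroid falls inside the
pathologist-drawn polygon.  Membership is decided by the nucleus centroid
(not any-pixel overlap), so a nucleus is counted by exactly one of several
adjacent ROIs.  An ROI containing no nuclei has an *undefined* PI — flagged
rather than reported as 0 %, since 0 % is a meaningful biological value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage.segmentation import find_boundaries

from .classification import NucleusRecord
from .stain import RGBImage

logger = logging.getLogger(__name__)

__all__ = [
    "ROIPolygon",
    "ROIScore",
    "rasterize_roi",
    "score_roi",
    "roi_area_mm2",
    "render_overlay",
]

#: Observed range of ROI areas in typical Ki-67 studies, used as a sanity
#: band for warnings (not a hard gate).
AREA_SANITY_MM2 = (0.0203, 3.1473)

POSITIVE_COLOUR = (255, 0, 0)  # red contours for DAB-positive nuclei
NEGATIVE_COLOUR = (0, 0, 255)  # blue contours for haematoxylin-only nuclei
ROI_COLOUR = (0, 0, 0)  # black ROI outline


@dataclass(frozen=True)
class ROIPolygon:
    """A pathologist-drawn region of interest.

    ``vertices`` are (x=col, y=row) pairs in pixel coordinates, implicitly
    closed.  The polygon must be simple with nonzero area.
    """

    vertices: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        poly = Polygon(v)
        if not poly.is_valid or poly.area == 0:
            raise ValueError(f"polygon {self.id!r} is degenerate or self-intersecting")
        object.__setattr__(self, "vertices", v)

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class ROIScore:
    """Positive/negative counts and PI for one ROI.

    ``pi_percent`` is None (and ``empty`` True) when no nucleus lies in the
    ROI.  Values are kept at full precision; display rounding to 0.1
    percentage points happens in the writers.
    """

    roi_id: str
    n_pos: int
    n_neg: int
    area_mm2: float | None = None

    @property
    def n_total(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def empty(self) -> bool:
        return self.n_total == 0

    @property
    def pi_percent(self) -> float | None:
        if self.empty:
            return None
        return 100.0 * self.n_pos / self.n_total

    @property
    def neg_percent(self) -> float | None:
        if self.empty:
            return None
        return 100.0 - self.pi_percent


def rasterize_roi(poly: ROIPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the raster pixels whose centre lies in the polygon.

    Pixel (r, c) has its centre at (x, y) = (c + 0.5, r + 0.5); centres
    exactly on a polygon edge count as inside.
    """
    h, w = shape
    geom = poly.as_shapely()
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    xs = cols.ravel() + 0.5
    ys = rows.ravel() + 0.5
    # intersects = inside or on the boundary
    inside = shapely.intersects_xy(geom, xs, ys).reshape(h, w)
    if not inside.any():
        logger.warning("ROI %r does not cover any pixel centre", poly.id)
    return inside


def score_roi(
    records: list[NucleusRecord],
    roi_mask: np.ndarray,
    roi_id: str = "",
    area_mm2: float | None = None,
) -> ROIScore:
    """Count positive/negative nuclei whose centroid pixel lies in the ROI."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    n_pos = n_neg = 0
    for rec in records:
        r = int(rec.centroid[0])
        c = int(rec.centroid[1])
        if 0 <= r < roi_mask.shape[0] and 0 <= c < roi_mask.shape[1] and roi_mask[r, c]:
            if rec.positive:
                n_pos += 1
            else:
                n_neg += 1
    score = ROIScore(roi_id=roi_id, n_pos=n_pos, n_neg=n_neg, area_mm2=area_mm2)
    if score.empty:
        logger.warning("no cells in ROI %r; PI undefined", roi_id)
    return score


def roi_area_mm2(poly: ROIPolygon, mpp: float) -> float:
    """Physical ROI area: shoelace polygon area (px^2) x mpp^2 x 1e-6."""
    if not mpp > 0:
        raise ValueError(f"mpp must be positive, got {mpp}")
    area = poly.as_shapely().area * mpp**2 * 1e-6
    lo, hi = AREA_SANITY_MM2
    if not lo <= area <= hi:
        logger.warning(
            "ROI %r area %.4f mm^2 outside the typical range [%.4f, %.4f]",
            poly.id, area, lo, hi,
        )
    return area


def _paint_boundaries(out: np.ndarray, mask: np.ndarray, colour) -> None:
    out[find_boundaries(mask, mode="inner")] = colour


def render_overlay(
    image: RGBImage,
    labels: np.ndarray,
    records: list[NucleusRecord],
    roi_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Annotated copy of the image: red contours around positive nuclei,
    blue around negative ones, black ROI outline.  The input is untouched."""
    labels = np.asarray(labels)
    if labels.shape != image.shape:
        raise ValueError("label map and image shapes differ")
    out = image.pixels.astype(np.uint8).copy()
    pos_ids = [r.label_id for r in records if r.positive]
    neg_ids = [r.label_id for r in records if not r.positive]
    if neg_ids:
        _paint_boundaries(out, np.isin(labels, neg_ids) * labels, NEGATIVE_COLOUR)
    if pos_ids:
        _paint_boundaries(out, np.isin(labels, pos_ids) * labels, POSITIVE_COLOUR)
    if roi_mask is not None:
        _paint_boundaries(out, np.asarray(roi_mask, dtype=bool), ROI_COLOUR)
    return out
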