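"""Marker-controlled watershed segmentation of nuclei.

The haematoxylin OD channel is thresholded (Otsu or a fixed cut) to a
nuclear foreground mask; the Euclidean distance transform of the mask is
normalised per ROI; its regional maxima seed a watershed flood that splits
touching nuclei; finally implausibly small (debris) or large objects are
removed by a physical-area gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import local_maxima
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMap",
    "threshold_foreground",
    "compute_distance_map",
    "detect_seeds",
    "watershed_segment",
    "filter_nuclei",
    "segment_nuclei",
]


@dataclass(frozen=True)
class DistanceMap:
    """Normalised Euclidean distance transform of a nuclear mask.

    ``values`` lies in [0, 1] (0 on background, 1 at the deepest foreground
    pixel); ``raw_max`` keeps the un-normalised maximum distance in pixels.
    """

    values: np.ndarray
    raw_max: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def threshold_foreground(
    h_channel: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> np.ndarray:
    """Split the haematoxylin channel into nuclear foreground vs background.

    A pixel is foreground iff its value is strictly greater than the
    threshold.  ``method="otsu"`` computes the threshold from the channel's
    256-bin histogram; ``method="fixed"`` uses ``fixed_threshold``.
    """
    h = np.asarray(h_channel, dtype=float)
    if h.min() < 0:
        raise ValueError("haematoxylin channel must be nonnegative")
    if method == "otsu":
        if np.ptp(h) == 0:  # constant channel: Otsu undefined, nothing to split
            return np.zeros(h.shape, dtype=bool)
        t = float(threshold_otsu(h, nbins=256))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        t = float(fixed_threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return h > t


def compute_distance_map(mask: np.ndarray) -> DistanceMap:
    """Euclidean distance of each foreground pixel to the nearest background
    pixel, normalised by the per-ROI maximum.

    Distances are centre-to-centre in pixel units.  An all-foreground mask
    has no background to measure against and yields all ones by convention;
    an all-background mask yields all zeros.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        return DistanceMap(values=np.ones(mask.shape), raw_max=float("inf"))
    raw = ndi.distance_transform_edt(mask)
    m = float(raw.max())
    if m == 0:
        return DistanceMap(values=np.zeros(mask.shape), raw_max=0.0)
    return DistanceMap(values=raw / m, raw_max=m)


def _plateau_representatives(peaks: np.ndarray, connectivity: int) -> list[tuple[int, int]]:
    """One pixel per connected plateau of regional maxima: topmost, then
    leftmost."""
    structure = ndi.generate_binary_structure(2, connectivity)
    lab, n = ndi.label(peaks, structure=structure)
    reps = []
    rows, cols = np.nonzero(lab)
    for k in range(1, n + 1):
        sel = lab[rows, cols] == k
        rr, cc = rows[sel], cols[sel]
        order = np.lexsort((cc, rr))  # row-major: topmost first, then leftmost
        reps.append((int(rr[order[0]]), int(cc[order[0]])))
    return reps


def detect_seeds(
    dmap: DistanceMap | np.ndarray,
    min_distance: int = 6,
    min_height: float = 0.1,
    connectivity: int = 2,
) -> list[tuple[int, int]]:
    """Peaks of the distance map to seed the watershed.

    Candidates are regional maxima (8-connected by default; one
    representative per equal-valued plateau).  Candidates below
    ``min_height`` (relative to the ROI's maximum distance, which is 1 after
    normalisation) are dropped; the rest are accepted greedily in decreasing
    value order subject to pairwise Euclidean separation >= ``min_distance``
    pixels.  Ties in value are broken topmost-then-leftmost, so the result
    is deterministic.
    """
    values = dmap.values if isinstance(dmap, DistanceMap) else np.asarray(dmap, float)
    if min_distance < 1:
        raise ValueError(f"min_distance must be >= 1, got {min_distance}")
    peaks = local_maxima(values, connectivity=connectivity) & (values > 0)
    reps = _plateau_representatives(peaks, connectivity)
    reps = [(r, c) for (r, c) in reps if values[r, c] >= min_height]
    reps.sort(key=lambda rc: (-values[rc], rc[0], rc[1]))
    accepted: list[tuple[int, int]] = []
    min_d2 = float(min_distance) ** 2
    for r, c in reps:
        if all((r - ar) ** 2 + (c - ac) ** 2 >= min_d2 for ar, ac in accepted):
            accepted.append((r, c))
    return accepted


def watershed_segment(
    dmap: DistanceMap | np.ndarray,
    seeds: list[tuple[int, int]],
    mask: np.ndarray,
    connectivity: int = 2,
) -> np.ndarray:
    """Flood the negated distance map from the seeds, restricted to the mask.

    Each seed grows one labelled region (label = 1-based seed index); ties at
    ridge lines are resolved deterministically by flooding order.  An empty
    seed list yields an all-zero label map with a warning.
    """
    values = dmap.values if isinstance(dmap, DistanceMap) else np.asarray(dmap, float)
    mask = np.asarray(mask, dtype=bool)
    if not seeds:
        logger.warning("watershed called with no seeds; returning empty label map")
        return np.zeros(mask.shape, dtype=np.int32)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(seeds, start=1):
        if not mask[r, c]:
            raise ValueError(f"seed ({r}, {c}) lies on background")
        markers[r, c] = i
    return watershed(-values, markers, mask=mask, connectivity=connectivity).astype(
        np.int32
    )


def filter_nuclei(labels: np.ndarray, min_area: float = 0, max_area: float = np.inf) -> np.ndarray:
    """Drop instances outside [min_area, max_area] (in pixels squared) and
    renumber survivors contiguously from 1, preserving original label order."""
    if min_area > max_area:
        raise ValueError("min_area must be <= max_area")
    labels = np.asarray(labels)
    n = int(labels.max())
    if n == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep = (areas >= min_area) & (areas <= max_area)
    keep[0] = False
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
    return remap[labels]


def segment_nuclei(
    h_channel: np.ndarray,
    mpp: float,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_distance_um: float = 3.0,
    min_height: float = 0.1,
    min_area_um2: float = 10.0,
    max_area_um2: float = 400.0,
    connectivity: int = 2,
) -> np.ndarray:
    """Full segmentation chain: threshold -> distance map -> seeds ->
    watershed -> area gate.

    Length/area parameters are physical (um, um^2) and converted to pixels
    via ``mpp``; the area gate (default 10-400 um^2, typical nuclear sizes)
    removes debris specks and merged clumps.
    """
    mask = threshold_foreground(h_channel, method=method, fixed_threshold=fixed_threshold)
    dmap = compute_distance_map(mask)
    min_distance = max(1, round(min_distance_um / mpp))
    seeds = detect_seeds(
        dmap, min_distance=min_distance, min_height=min_height, connectivity=connectivity
    )
    labels = watershed_segment(dmap, seeds, mask, connectivity=connectivity)
    return filter_nuclei(labels, min_area=min_area_um2 / mpp**2, max_area=max_area_um2 / mpp**2)
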