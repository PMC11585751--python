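"""End-to-end scoring: image + ROI polygons -> per-ROI PI results.

Ties the stages together: colour deconvolution, watershed segmentation of
the haematoxylin channel, DAB positivity calls, and per-ROI counting with
overlays.  Nuclei are segmented once over the whole frame and assigned to
ROIs by centroid, so adjacent ROIs never double-count a nucleus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .classification import NucleusRecord, classify_nuclei
from .config import RunConfig
from .io import (
    write_image,
    write_nucleus_csv,
    write_roi_scores_csv,
)
from .scoring import (
    ROIPolygon,
    ROIScore,
    rasterize_roi,
    render_overlay,
    roi_area_mm2,
    score_roi,
)
from .segmentation import segment_nuclei
from .stain import RGBImage, split_rgb

logger = logging.getLogger(__name__)

__all__ = ["ScoreRunResult", "score_image", "run_score"]


@dataclass(frozen=True)
class ScoreRunResult:
    """Everything produced by scoring one image against its ROIs."""

    labels: np.ndarray
    records: list[NucleusRecord]
    scores: list[ROIScore]
    overlays: dict[str, np.ndarray]


def score_image(
    image: RGBImage,
    rois: list[ROIPolygon],
    config: RunConfig | None = None,
    make_overlays: bool = True,
) -> ScoreRunResult:
    """Score one RGB image over a set of ROI polygons."""
    config = config or RunConfig(mpp=image.mpp)
    channels = split_rgb(image, config.stains)
    seg = config.segmentation
    labels = segment_nuclei(
        channels.hematoxylin_od,
        mpp=image.mpp,
        method=seg.method,
        fixed_threshold=seg.fixed_threshold,
        min_distance_um=seg.min_distance_um,
        min_height=seg.min_height,
        min_area_um2=seg.min_area_um2,
        max_area_um2=seg.max_area_um2,
        connectivity=seg.connectivity,
    )
    records = classify_nuclei(
        labels,
        channels.dab_od,
        dab_threshold=config.classification.dab_threshold,
        mpp=image.mpp,
        statistic=config.classification.statistic,
    )
    scores: list[ROIScore] = []
    overlays: dict[str, np.ndarray] = {}
    for poly in rois:
        mask = rasterize_roi(poly, image.shape)
        score = score_roi(
            records, mask, roi_id=poly.id, area_mm2=roi_area_mm2(poly, image.mpp)
        )
        scores.append(score)
        if make_overlays:
            in_roi = [
                r
                for r in records
                if mask[
                    min(int(r.centroid[0]), mask.shape[0] - 1),
                    min(int(r.centroid[1]), mask.shape[1] - 1),
                ]
            ]
            overlays[poly.id] = render_overlay(image, labels, in_roi, mask)
    return ScoreRunResult(
        labels=labels, records=records, scores=scores, overlays=overlays
    )


def run_score(
    image: RGBImage,
    rois: list[ROIPolygon],
    config: RunConfig,
    out_dir: str | Path,
) -> ScoreRunResult:
    """Score an image and write the results CSVs, overlay PNGs and a run
    manifest JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = score_image(image, rois, config)

    scores_csv = out / "roi_scores.csv"
    nuclei_csv = out / "nuclei.csv"
    write_roi_scores_csv(scores_csv, result.scores)
    write_nucleus_csv(nuclei_csv, result.records)
    written = [scores_csv.name, nuclei_csv.name]
    for roi_id, overlay in result.overlays.items():
        name = f"overlay_{roi_id}.png"
        write_image(out / name, overlay)
        written.append(name)

    manifest = {
        "version": __version__,
        "mpp": image.mpp,
        "n_rois": len(rois),
        "n_nuclei": len(result.records),
        "config": {
            "segmentation": vars(config.segmentation).copy(),
            "classification": vars(config.classification).copy(),
        },
        "outputs": written,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    logger.info("scored %d ROIs, %d nuclei -> %s", len(rois), len(result.records), out)
    return result
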