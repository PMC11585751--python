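"""Run configuration: stain vectors, segmentation and classification
parameters, loadable from YAML with strict key validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .classification import DEFAULT_DAB_THRESHOLD
from .stain import HDAB_DEFAULT, StainMatrix

__all__ = ["SegmentationParams", "ClassificationParams", "RunConfig"]


def _from_mapping(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown {context} config keys: {sorted(unknown)}; "
            f"expected a subset of {sorted(known)}"
        )
    return cls(**data)


@dataclass(frozen=True)
class SegmentationParams:
    method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float | None = None
    min_distance_um: float = 3.0
    min_height: float = 0.1
    min_area_um2: float = 10.0
    max_area_um2: float = 400.0
    connectivity: int = 2  # 2 = 8-connected, 1 = 4-connected

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.method == "fixed" and self.fixed_threshold is None:
            raise ValueError("method 'fixed' requires fixed_threshold")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")


@dataclass(frozen=True)
class ClassificationParams:
    dab_threshold: float = DEFAULT_DAB_THRESHOLD
    statistic: str = "mean"  # "mean" | "median"

    def __post_init__(self) -> None:
        if self.statistic not in ("mean", "median"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.dab_threshold < 0:
            raise ValueError("dab_threshold must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """Everything a scoring run needs besides the input files."""

    mpp: float = 0.5
    stains: StainMatrix = field(default=HDAB_DEFAULT)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.mpp > 0:
            raise ValueError(f"mpp must be positive, got {self.mpp}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)}; "
                f"expected a subset of {sorted(known)}"
            )
        if "stains" in data and isinstance(data["stains"], dict):
            sd = data["stains"]
            extra = set(sd) - {"hematoxylin", "dab", "residual"}
            if extra:
                raise ValueError(f"unknown stain config keys: {sorted(extra)}")
            data["stains"] = StainMatrix(**sd)
        if "segmentation" in data and isinstance(data["segmentation"], dict):
            data["segmentation"] = _from_mapping(
                SegmentationParams, data["segmentation"], "segmentation"
            )
        if "classification" in data and isinstance(data["classification"], dict):
            data["classification"] = _from_mapping(
                ClassificationParams, data["classification"], "classification"
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
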