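"""Colour deconvolution of H-DAB brightfield images.

Brightfield immunohistochemistry images mix two chromogens: haematoxylin
(blue, counterstains every nucleus) and DAB (brown, marks Ki-67 positive
nuclei).  Under the Beer-Lambert law the stains add linearly in optical
density (OD = -log10 of transmittance), so an RGB pixel can be unmixed into
per-stain concentrations by projecting its OD vector onto reference stain
direction vectors (Ruifrok & Johnston colour deconvolution).

The module accepts either raw RGB images (deconvolved here with configurable
reference vectors) or images already split into haematoxylin/DAB OD channels
(bypass path, the identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RGBImage",
    "StainMatrix",
    "StainChannels",
    "HDAB_DEFAULT",
    "rgb_to_od",
    "separate_stains",
    "split_rgb",
    "channels_from_arrays",
    "od_to_rgb",
]

#: OD ceiling: the darkest representable intensity is 1/255.
MAX_OD = float(np.log10(255.0))


@dataclass(frozen=True)
class RGBImage:
    """An RGB brightfield region-of-interest snapshot.

    Parameters
    ----------
    pixels : ndarray of shape (H, W, 3)
        Integer intensities in [0, 255].
    mpp : float
        Microns per pixel (isotropic physical resolution), > 0.
    """

    pixels: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if not self.mpp > 0:
            raise ValueError(f"mpp must be positive, got {self.mpp}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("stain vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class StainMatrix:
    """Unit stain direction vectors in RGB-OD space.

    When no residual vector is given, the cross product of the haematoxylin
    and DAB vectors completes the basis, so the 3x3 system is invertible
    whenever the two stain vectors are linearly independent.
    """

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        h = _unit(self.hematoxylin)
        d = _unit(self.dab)
        if self.residual is None:
            r = np.cross(h, d)
            if np.linalg.norm(r) < 1e-12:
                raise ValueError("haematoxylin and DAB vectors are collinear")
            r = _unit(r)
        else:
            r = _unit(self.residual)
        object.__setattr__(self, "hematoxylin", h)
        object.__setattr__(self, "dab", d)
        object.__setattr__(self, "residual", r)
        if abs(np.linalg.det(self.as_array())) < 1e-12:
            raise ValueError("stain matrix is singular")

    def as_array(self) -> np.ndarray:
        """Rows are the (H, DAB, residual) unit vectors."""
        return np.stack([self.hematoxylin, self.dab, self.residual])


#: Ruifrok-Johnston reference vectors for the H-DAB stain combination.
HDAB_DEFAULT = StainMatrix(
    hematoxylin=(0.650, 0.704, 0.286),
    dab=(0.268, 0.570, 0.776),
)


@dataclass(frozen=True)
class StainChannels:
    """Per-pixel haematoxylin and DAB optical-density maps for one ROI."""

    hematoxylin_od: np.ndarray
    dab_od: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        h = np.asarray(self.hematoxylin_od, dtype=float)
        d = np.asarray(self.dab_od, dtype=float)
        if h.shape != d.shape or h.ndim != 2:
            raise ValueError("channel maps must be 2-D and share one shape")
        if h.min() < 0 or d.min() < 0:
            raise ValueError("optical densities must be nonnegative")
        if not self.mpp > 0:
            raise ValueError(f"mpp must be positive, got {self.mpp}")
        object.__setattr__(self, "hematoxylin_od", h)
        object.__setattr__(self, "dab_od", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.hematoxylin_od.shape


def rgb_to_od(image: RGBImage | np.ndarray) -> np.ndarray:
    """Convert RGB intensities to optical density, OD = -log10(max(I,1)/255).

    Intensities are floored at 1 before the log so the output is bounded by
    log10(255); white (255) maps to OD 0.
    """
    px = image.pixels if isinstance(image, RGBImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) array, got shape {px.shape}")
    i = np.maximum(px.astype(float), 1.0)
    return -np.log10(i / 255.0)


def separate_stains(
    od: np.ndarray, matrix: StainMatrix = HDAB_DEFAULT, mpp: float = 1.0
) -> StainChannels:
    """Unmix an (H, W, 3) OD map into haematoxylin and DAB concentrations.

    Solves the per-pixel 3x3 linear system od = c @ M (rows of M are the
    stain vectors) and discards the residual component.  Negative
    concentrations — deconvolution noise — are clamped to 0.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) OD map, got shape {od.shape}")
    inv = np.linalg.inv(matrix.as_array())
    conc = od @ inv
    conc = np.clip(conc, 0.0, None)
    return StainChannels(
        hematoxylin_od=conc[..., 0], dab_od=conc[..., 1], mpp=mpp
    )


def split_rgb(image: RGBImage, matrix: StainMatrix = HDAB_DEFAULT) -> StainChannels:
    """Full path: RGB image -> OD -> per-stain channels."""
    return separate_stains(rgb_to_od(image), matrix, mpp=image.mpp)


def channels_from_arrays(
    hematoxylin_od: np.ndarray, dab_od: np.ndarray, mpp: float
) -> StainChannels:
    """Bypass path for inputs already split into the two stain channels."""
    return StainChannels(
        hematoxylin_od=np.clip(np.asarray(hematoxylin_od, dtype=float), 0, None),
        dab_od=np.clip(np.asarray(dab_od, dtype=float), 0, None),
        mpp=mpp,
    )


def od_to_rgb(
    hematoxylin_od: np.ndarray,
    dab_od: np.ndarray,
    matrix: StainMatrix = HDAB_DEFAULT,
) -> np.ndarray:
    """Compose stain concentration maps into a float RGB image in [0, 255].

    Inverse of the deconvolution under Beer-Lambert: I = 255 * 10**(-OD).
    Used by the synthetic-image generator.
    """
    od = (
        np.asarray(hematoxylin_od, dtype=float)[..., None] * matrix.hematoxylin
        + np.asarray(dab_od, dtype=float)[..., None] * matrix.dab
    )
    return 255.0 * 10.0 ** (-od)
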