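"""Synthetic H-DAB nuclei fields and multi-reader score tables.

Real Ki-67 reader studies rest on whole-slide images and per-ROI
pathologist scores that are rarely shared.  This module emulates both
sides of such a study with pixel-level ground truth:

* ``simulate_roi_image`` renders a field of elliptical nuclei on a white
  background.  Every nucleus carries the haematoxylin optical-density
  level; Ki-67 positive nuclei additionally carry the DAB level.  The OD
  maps are composed into RGB by Beer-Lambert using the same reference
  stain vectors the deconvolution inverts, Gaussian pixel noise is added,
  and optional sub-nuclear DAB-coloured debris specks exercise the
  false-positive failure mode of intensity-based scorers.

* ``simulate_study`` draws a slides x ROIs grid of such fields with true
  PIs from a configurable distribution (default: 70 % of ROIs in the
  0-10 % band, the rest uniform on 10-100, mirroring the observation that
  most clinical ROIs score low).

* ``simulate_reader_scores`` emulates visual scoring: readers report
  truth (or an AI anchor score) plus bias and Gaussian noise, rounded to
  5- or 10-point intervals and clamped to [0, 100].  AI-assisted readers
  are modelled with small noise around the anchor, unassisted readers
  with larger noise around the truth — the two-round study design.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse

from .concordance import ScoreTable
from .scoring import ROIPolygon
from .stain import HDAB_DEFAULT, RGBImage, StainMatrix, od_to_rgb

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ReaderModel",
    "simulate_roi_image",
    "simulate_study",
    "sample_true_pis",
    "simulate_reader_scores",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic ROI image.

    Defaults render a 20x-like field (0.5 um/px) of 150 well-separated
    nuclei with semi-axes 3-5 um, haematoxylin OD 0.7 everywhere and DAB
    OD 0.6 on positive nuclei, and mild sensor noise.
    """

    height: int = 512
    width: int = 512
    mpp: float = 0.5
    n_nuclei: int = 150
    radius_um: tuple[float, float] = (3.0, 5.0)
    positive_fraction: float = 0.1
    min_separation_um: float = 11.0
    axis_ratio: tuple[float, float] = (0.8, 1.0)
    hematoxylin_od: float = 0.7
    dab_od: float = 0.6
    noise_sd: float = 3.0  # additive RGB noise, intensity units
    n_debris: int = 0
    debris_radius_px: float = 1.0
    pleomorphic_fraction: float = 0.0  # fraction of nuclei at 2x radius
    stains: StainMatrix = field(default=HDAB_DEFAULT)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1 or self.mpp <= 0:
            raise ValueError("image dimensions and mpp must be positive")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.n_nuclei < 0 or self.n_debris < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Pixel-level truth for one synthetic ROI image."""

    centers: np.ndarray  # (n, 2) float, (row, col)
    radii_px: np.ndarray  # (n, 2) float, (r_radius, c_radius)
    calls: np.ndarray  # (n,) bool, True = positive
    instance_map: np.ndarray  # int label map, 1..n

    @property
    def n_nuclei(self) -> int:
        return len(self.calls)

    @property
    def n_positive(self) -> int:
        return int(self.calls.sum())

    @property
    def true_pi(self) -> float | None:
        if self.n_nuclei == 0:
            return None
        return 100.0 * self.n_positive / self.n_nuclei


def _place_centers(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample nucleus centres with a minimum pairwise separation."""
    margin = cfg.radius_um[1] * 2 / cfg.mpp  # keep whole nuclei inside the frame
    min_sep_px = cfg.min_separation_um / cfg.mpp
    if cfg.height - 2 * margin <= 0 or cfg.width - 2 * margin <= 0:
        raise ValueError("image too small for the requested nucleus radii")
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 2000 * max(cfg.n_nuclei, 1)
    while len(centers) < cfg.n_nuclei:
        if attempts >= max_attempts:
            raise ValueError(
                f"cannot place {cfg.n_nuclei} nuclei with "
                f"min separation {cfg.min_separation_um} um in a "
                f"{cfg.height}x{cfg.width} px field"
            )
        attempts += 1
        r = rng.uniform(margin, cfg.height - margin)
        c = rng.uniform(margin, cfg.width - margin)
        if all((r - cr) ** 2 + (c - cc) ** 2 >= min_sep_px**2 for cr, cc in centers):
            centers.append((r, c))
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def simulate_roi_image(cfg: SimulationConfig) -> tuple[RGBImage, GroundTruth]:
    """Render one synthetic H-DAB field and its ground truth.

    The number of positive nuclei is exact-count: round(positive_fraction x
    n_nuclei), randomly assigned, so the true PI is known without sampling
    error.  Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.height, cfg.width)
    h_od = np.zeros(shape)
    d_od = np.zeros(shape)
    instance = np.zeros(shape, dtype=np.int32)

    centers = _place_centers(cfg, rng)
    n = cfg.n_nuclei
    n_pos = int(round(cfg.positive_fraction * n))
    calls = np.zeros(n, dtype=bool)
    calls[rng.permutation(n)[:n_pos]] = True

    radii = np.zeros((n, 2))
    for i, (r, c) in enumerate(centers):
        a = rng.uniform(*cfg.radius_um) / cfg.mpp
        if cfg.pleomorphic_fraction > 0 and rng.random() < cfg.pleomorphic_fraction:
            a *= 2.0  # enlarged pleomorphic outlier
        b = a * rng.uniform(*cfg.axis_ratio)
        theta = rng.uniform(0, np.pi)
        rr, cc = ellipse(r, c, a, b, shape=shape, rotation=theta)
        radii[i] = (a, b)
        h_od[rr, cc] = cfg.hematoxylin_od
        if calls[i]:
            d_od[rr, cc] = cfg.dab_od
        instance[rr, cc] = i + 1

    for _ in range(cfg.n_debris):
        r = rng.uniform(0, cfg.height)
        c = rng.uniform(0, cfg.width)
        rr, cc = ellipse(r, c, cfg.debris_radius_px, cfg.debris_radius_px, shape=shape)
        bg = instance[rr, cc] == 0  # debris sits on the background only
        d_od[rr[bg], cc[bg]] = cfg.dab_od

    rgb = od_to_rgb(h_od, d_od, cfg.stains)
    if cfg.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, cfg.noise_sd, rgb.shape)
    pixels = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    image = RGBImage(pixels=pixels, mpp=cfg.mpp)
    truth = GroundTruth(
        centers=centers, radii_px=radii, calls=calls, instance_map=instance
    )
    return image, truth


def sample_true_pis(
    n: int,
    rng: np.random.Generator,
    low_fraction: float = 0.7,
    low_band: tuple[float, float] = (0.0, 10.0),
    high_band: tuple[float, float] = (10.0, 100.0),
) -> np.ndarray:
    """Draw per-ROI true PIs: a low-scoring majority plus a uniform tail."""
    low = rng.random(n) < low_fraction
    pis = np.where(
        low,
        rng.uniform(*low_band, size=n),
        rng.uniform(*high_band, size=n),
    )
    return pis


def simulate_study(
    n_slides: int,
    rois_per_slide: int,
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    render_images: bool = True,
):
    """Simulate a reader study: ``n_slides`` x ``rois_per_slide`` ROIs.

    Yields (roi_id, true_pi, image, truth, polygon) tuples; with
    ``render_images=False`` the image/truth/polygon slots are None and only
    the study structure and true PIs are produced (enough for the
    statistics pipeline, and much faster).  The ROI polygon is the full
    image frame.
    """
    if n_slides < 1 or rois_per_slide < 1:
        raise ValueError("study dimensions must be positive")
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    n_rois = n_slides * rois_per_slide
    pis = sample_true_pis(n_rois, rng)
    roi_seeds = rng.integers(0, 2**31 - 1, size=n_rois)
    k = 0
    for s in range(n_slides):
        for j in range(rois_per_slide):
            roi_id = f"slide{s + 1:03d}_roi{j + 1}"
            if render_images:
                roi_cfg = replace(
                    cfg,
                    positive_fraction=pis[k] / 100.0,
                    seed=int(roi_seeds[k]),
                )
                image, truth = simulate_roi_image(roi_cfg)
                poly = ROIPolygon(
                    vertices=[
                        (0.0, 0.0),
                        (cfg.width, 0.0),
                        (cfg.width, cfg.height),
                        (0.0, cfg.height),
                    ],
                    id=roi_id,
                )
                # exact-count assignment quantises the PI; report the realised one
                yield roi_id, truth.true_pi, image, truth, poly
            else:
                yield roi_id, float(pis[k]), None, None, None
            k += 1


@dataclass(frozen=True)
class ReaderModel:
    """One simulated reader of PI scores.

    ``anchor`` selects the two-round design arm: ``"truth"`` models an
    unassisted visual scorer around the true PI, ``"ai"`` an AI-assisted
    scorer around the automated score.  Scores are biased, jittered,
    rounded to ``rounding`` point intervals (None disables) and clamped to
    [0, 100].
    """

    name: str
    noise_sd: float = 5.0
    bias: float = 0.0
    rounding: float | None = 5.0
    clamp: bool = True
    anchor: str = "truth"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.rounding is not None and self.rounding <= 0:
            raise ValueError("rounding interval must be positive or None")
        if self.anchor not in ("truth", "ai"):
            raise ValueError("anchor must be 'truth' or 'ai'")


def two_round_reader_panel(
    noise_pre: float = 10.0,
    noise_post: float = 1.8,
    biases: tuple[float, float, float] = (5.0, -5.0, 0.0),
    rounding: float | None = None,
) -> tuple[list[ReaderModel], list[ReaderModel]]:
    """Reader panels for the two-round (unassisted, then AI-assisted) design.

    Round 1: three visual scorers around the truth with per-reader noise
    ``noise_pre`` and systematic biases whose pairwise differences echo the
    ~+10/+5/-5 pp mean inter-reader differences typical of unassisted Ki-67
    scoring.  Round 2: the same readers anchored to the automated score with
    small residual noise ``noise_post`` and no bias.  ``rounding`` is off by
    default so the stated noise SDs are the only noise sources; interval
    rounding would stack ~interval^2/12 of quantisation variance on top.
    """
    pre = [
        ReaderModel(name=f"P{i + 1}", noise_sd=noise_pre, bias=b, rounding=rounding)
        for i, b in enumerate(biases)
    ]
    post = [
        ReaderModel(name=f"P{i + 1}-AI", noise_sd=noise_post, rounding=rounding,
                    anchor="ai")
        for i in range(len(biases))
    ]
    return pre, post


def simulate_reader_scores(
    true_pis: np.ndarray,
    readers: list[ReaderModel],
    ai_scores: np.ndarray | None = None,
    seed: int = 0,
) -> ScoreTable:
    """Emulate visual scoring of ``true_pis`` by a panel of readers.

    Readers with ``anchor="ai"`` score around ``ai_scores`` (defaults to the
    truth when not given, i.e. a perfectly accurate automated scorer).
    """
    true_pis = np.asarray(true_pis, dtype=float)
    rng = np.random.default_rng(seed)
    if ai_scores is None:
        ai_scores = true_pis
    else:
        ai_scores = np.asarray(ai_scores, dtype=float)
        if ai_scores.shape != true_pis.shape:
            raise ValueError("ai_scores must match true_pis in length")
    rows = []
    for reader in readers:
        base = true_pis if reader.anchor == "truth" else ai_scores
        s = base + reader.bias + rng.normal(0.0, reader.noise_sd, true_pis.shape)
        if reader.rounding is not None:
            s = np.round(s / reader.rounding) * reader.rounding
        if reader.clamp:
            s = np.clip(s, 0.0, 100.0)
        rows.append(s)
    return ScoreTable(
        reader_ids=[r.name for r in readers],
        roi_ids=[f"roi{i + 1}" for i in range(true_pis.size)],
        scores=np.stack(rows),
    )
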