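import numpy as np
import pytest

from ki67pi import ROIPolygon, SimulationConfig, simulate_roi_image


@pytest.fixture
def small_field():
    """A 256x256 field of 30 well-separated nuclei, 20% positive."""
    cfg = SimulationConfig(
        height=256, width=256, n_nuclei=30, positive_fraction=0.2, seed=7
    )
    image, truth = simulate_roi_image(cfg)
    return cfg, image, truth


@pytest.fixture
def full_frame_roi():
    def make(shape, roi_id="roi"):
        h, w = shape
        return ROIPolygon(
            vertices=[(0, 0), (w, 0), (w, h), (0, h)], id=roi_id
        )

    return make


def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """O(N^2) nearest-zero-pixel Euclidean distance, the oracle for the
    distance transform."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=float)
    zeros = np.argwhere(~mask)
    if zeros.size == 0:
        return out
    for r, c in np.argwhere(mask):
        d2 = (zeros[:, 0] - r) ** 2 + (zeros[:, 1] - c) ** 2
        out[r, c] = np.sqrt(d2.min())
    return out
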