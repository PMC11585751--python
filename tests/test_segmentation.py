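"""Thresholding, distance transform, peak seeding, watershed, size gates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ki67pi import (
    compute_distance_map,
    detect_seeds,
    filter_nuclei,
    segment_nuclei,
    simulate_roi_image,
    threshold_foreground,
    watershed_segment,
)
from ki67pi.simulate import SimulationConfig

from conftest import brute_force_edt


class TestThreshold:
    def test_fixed_all_foreground(self):
        assert threshold_foreground(np.full((3, 3), 0.8), "fixed", 0.5).all()

    def test_fixed_strict_inequality(self):
        # a pixel exactly at the threshold is background
        assert not threshold_foreground(np.full((3, 3), 0.8), "fixed", 0.8).any()

    def test_fixed_checkerboard(self):
        h = np.array([[0.1, 0.9], [0.9, 0.1]])
        np.testing.assert_array_equal(
            threshold_foreground(h, "fixed", 0.5),
            np.array([[False, True], [True, False]]),
        )

    def test_fixed_requires_value(self):
        with pytest.raises(ValueError):
            threshold_foreground(np.ones((2, 2)), "fixed")

    def test_otsu_separates_bimodal(self):
        h = np.zeros((10, 10))
        h[:5] = 0.7
        mask = threshold_foreground(h, "otsu")
        assert mask[:5].all() and not mask[5:].any()

    def test_scale_invariance_with_scaled_fixed_threshold(self):
        rng = np.random.default_rng(1)
        h = rng.random((16, 16))
        m1 = threshold_foreground(h, "fixed", 0.4)
        m2 = threshold_foreground(3.5 * h, "fixed", 3.5 * 0.4)
        np.testing.assert_array_equal(m1, m2)


class TestDistanceMap:
    def test_all_background(self):
        dm = compute_distance_map(np.zeros((4, 4), dtype=bool))
        assert not dm.values.any() and dm.raw_max == 0.0

    def test_single_pixel_normalises_to_one(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        dm = compute_distance_map(mask)
        assert dm.values[2, 2] == 1.0 and dm.raw_max == 1.0

    def test_row_strip(self):
        mask = np.array([[0, 1, 1, 1, 0]], dtype=bool)
        dm = compute_distance_map(mask)
        np.testing.assert_allclose(dm.values[0], [0, 0.5, 1.0, 0.5, 0])
        assert dm.raw_max == 2.0

    def test_all_foreground_convention(self):
        dm = compute_distance_map(np.ones((3, 3), dtype=bool))
        assert (dm.values == 1.0).all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        arrays(
            bool,
            st.tuples(st.integers(1, 12), st.integers(1, 12)),
        )
    )
    def test_matches_brute_force_oracle(self, mask):
        """Raw distances equal an O(N^2) search over all zero pixels."""
        dm = compute_distance_map(mask)
        raw = brute_force_edt(mask)
        if mask.all():
            assert (dm.values == 1.0).all()
        elif raw.max() == 0:
            assert not dm.values.any()
        else:
            np.testing.assert_allclose(dm.values * dm.raw_max, raw, atol=1e-9)
            assert dm.raw_max == pytest.approx(raw.max())


class TestSeeds:
    def test_single_peak(self):
        d = np.zeros((7, 7))
        d[3, 3] = 1.0
        assert detect_seeds(d, min_distance=2, min_height=0.5) == [(3, 3)]

    def test_two_separated_bumps(self):
        # oracle: exhaustive local-maxima search on a small raster
        rr, cc = np.mgrid[0:21, 0:41]
        d = np.exp(-((rr - 10) ** 2 + (cc - 10) ** 2) / 18.0) + np.exp(
            -((rr - 10) ** 2 + (cc - 30) ** 2) / 18.0
        )
        d /= d.max()
        seeds = detect_seeds(d, min_distance=10, min_height=0.2)
        assert sorted(seeds) == [(10, 10), (10, 30)]

    def test_plateau_keeps_topmost_leftmost(self):
        d = np.zeros((7, 7))
        d[2:5, 2:5] = 1.0
        assert detect_seeds(d, min_distance=1, min_height=0.5) == [(2, 2)]

    def test_min_height_filters_low_peaks(self):
        d = np.zeros((9, 9))
        d[2, 2] = 1.0
        d[6, 6] = 0.2
        assert detect_seeds(d, min_distance=2, min_height=0.5) == [(2, 2)]

    def test_min_distance_validation(self):
        with pytest.raises(ValueError):
            detect_seeds(np.ones((3, 3)), min_distance=0)

    def test_greedy_suppression_prefers_higher_peak(self):
        d = np.zeros((5, 11))
        d[2, 3] = 1.0
        d[2, 7] = 0.8
        assert detect_seeds(d, min_distance=5, min_height=0.1) == [(2, 3)]


class TestWatershed:
    def test_single_blob_single_seed(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True
        dm = compute_distance_map(mask)
        labels = watershed_segment(dm, [(4, 4)], mask)
        assert (labels[mask] == 1).all() and not labels[~mask].any()

    def test_two_disjoint_blobs(self):
        mask = np.zeros((9, 19), dtype=bool)
        mask[3:6, 2:7] = True
        mask[3:6, 12:17] = True
        dm = compute_distance_map(mask)
        labels = watershed_segment(dm, [(4, 4), (4, 14)], mask)
        assert set(labels[3:6, 2:7].ravel()) == {1}
        assert set(labels[3:6, 12:17].ravel()) == {2}

    def test_dumbbell_splits_into_two(self):
        """Two discs joined by a thin bridge split at the ridge."""
        rr, cc = np.mgrid[0:21, 0:41]
        disc1 = (rr - 10) ** 2 + (cc - 10) ** 2 <= 64
        disc2 = (rr - 10) ** 2 + (cc - 30) ** 2 <= 64
        bridge = (np.abs(rr - 10) <= 1) & (cc >= 10) & (cc <= 30)
        mask = disc1 | disc2 | bridge
        dm = compute_distance_map(mask)
        seeds = detect_seeds(dm, min_distance=10, min_height=0.3)
        labels = watershed_segment(dm, seeds, mask)
        assert labels.max() == 2
        assert (labels[mask] > 0).all() and not labels[~mask].any()
        assert labels[10, 10] != labels[10, 30]

    def test_empty_seed_list_returns_zeros(self):
        mask = np.ones((4, 4), dtype=bool)
        labels = watershed_segment(compute_distance_map(mask), [], mask)
        assert not labels.any()

    def test_seed_on_background_rejected(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        with pytest.raises(ValueError):
            watershed_segment(compute_distance_map(mask), [(3, 3)], mask)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_labels_partition_foreground(self, seed):
        """With unfiltered seeds, watershed labels exactly the foreground and
        the labelled regions are pairwise disjoint."""
        rng = np.random.default_rng(seed)
        mask = rng.random((20, 20)) < 0.4
        dm = compute_distance_map(mask)
        seeds = detect_seeds(dm, min_distance=1, min_height=0.0)
        labels = watershed_segment(dm, seeds, mask)
        if mask.any() and not mask.all():
            np.testing.assert_array_equal(labels > 0, mask)
            assert labels.max() == len(seeds)


class TestFilterNuclei:
    def _labels_with_areas(self, areas):
        w = sum(areas)
        labels = np.zeros((1, w), dtype=np.int32)
        c = 0
        for i, a in enumerate(areas, start=1):
            labels[0, c : c + a] = i
            c += a
        return labels

    def test_area_gate_and_renumbering(self):
        labels = self._labels_with_areas([3, 50, 5000])
        out = filter_nuclei(labels, min_area=10, max_area=2000)
        assert out.max() == 1
        assert (out[labels == 2] == 1).all()
        assert not out[labels == 1].any() and not out[labels == 3].any()

    def test_identity_with_open_gates(self):
        labels = self._labels_with_areas([3, 50, 5000])
        np.testing.assert_array_equal(
            filter_nuclei(labels, min_area=0, max_area=np.inf), labels
        )

    def test_debris_removed_by_simulator_ground_truth(self):
        """100 debris specks of a few px^2 vanish under the area gate; the
        20 true nuclei survive."""
        cfg = SimulationConfig(
            height=320, width=320, n_nuclei=20, positive_fraction=0.5,
            n_debris=100, seed=11,
        )
        image, truth = simulate_roi_image(cfg)
        from ki67pi import split_rgb

        ch = split_rgb(image)
        labels = segment_nuclei(ch.hematoxylin_od, mpp=cfg.mpp)
        assert labels.max() == truth.n_nuclei


class TestSegmentNuclei:
    def test_recovers_simulated_count(self, small_field):
        cfg, image, truth = small_field
        from ki67pi import split_rgb

        labels = segment_nuclei(split_rgb(image).hematoxylin_od, mpp=cfg.mpp)
        assert labels.max() == truth.n_nuclei
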