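"""Zero-crossing segmentation: edge detection, hole filling and erosion
against brute-force oracles, labeling, per-cell measurement, density."""

from collections import deque

import numpy as np
import pytest

from cellquant.crf import InverseLUT
from cellquant.preprocessing import linearize, subtract_background
from cellquant.segmentation import (
    LabeledMask,
    detect_edges,
    edges_to_mask,
    estimate_density,
    label_cells,
    measure_cells,
    segment,
)
from cellquant.synthetic import AcquisitionSpec, SceneSpec, generate_scene, render_image


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_fill_holes(mask):
    """Flood fill from the border over the complement; unreachable
    background pixels are holes."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    outside = np.zeros_like(mask)
    queue = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and not outside[rr, cc]:
                outside[rr, cc] = True
                queue.append((rr, cc))
    return mask | ~outside


def brute_force_erode_cross(mask, iterations=1):
    """Binary erosion with the 3x3 cross, pixels beyond the border counting
    as background."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    for _ in range(iterations):
        out = np.zeros_like(mask)
        for r in range(h):
            for c in range(w):
                if not mask[r, c]:
                    continue
                ok = True
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        ok = False
                        break
                out[r, c] = ok
        mask = out
    return mask


# ---------------------------------------------------------------------------
# detect_edges
# ---------------------------------------------------------------------------

class TestDetectEdges:
    def test_constant_image_has_no_edges(self):
        img = np.full((64, 64), 0.4)
        assert not detect_edges(img, 2.0, gradient_threshold=0.01).any()

    def test_bright_rectangle_yields_closed_contour(self):
        """The contour around an isolated bright rectangle must be closed:
        flood fill from the border never reaches the interior."""
        img = np.zeros((64, 64))
        img[20:36, 14:50] = 1.0
        edges = detect_edges(img, 2.0)
        filled = brute_force_fill_holes(edges)
        assert filled[28, 32]  # interior captured only if the contour closes

    def test_gradient_threshold_suppresses_noise_edges(self, rng):
        """On a noise-only image the adaptive gate removes nearly all
        zero crossings: ~half the pixels without the gate, a few per mille
        at the default 3x the robust gradient scale, and <0.1% at 4x."""
        noise = rng.normal(0.0, 1.0, size=(128, 128))
        permissive = detect_edges(noise, 2.0, gradient_threshold=0.0)
        assert permissive.mean() > 0.05  # zero crossings everywhere
        gated = detect_edges(noise, 2.0, threshold_multiplier=3.0)
        assert gated.mean() < 0.005
        strict = detect_edges(noise, 2.0, threshold_multiplier=4.0)
        assert strict.mean() < 0.001

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            detect_edges(np.zeros((8, 8)), 0.0)


# ---------------------------------------------------------------------------
# edges_to_mask
# ---------------------------------------------------------------------------

class TestEdgesToMask:
    def test_closed_contour_filled_and_shrunk_one_pixel(self):
        edges = np.zeros((64, 64), dtype=bool)
        edges[10, 10:31] = edges[30, 10:31] = True
        edges[10:31, 10] = edges[10:31, 30] = True
        out = edges_to_mask(edges, erosion_iterations=1)
        oracle = brute_force_erode_cross(brute_force_fill_holes(edges), 1)
        np.testing.assert_array_equal(out, oracle)
        expected = np.zeros((64, 64), dtype=bool)
        expected[11:30, 11:30] = True
        np.testing.assert_array_equal(out, expected)

    def test_broken_contour_not_filled(self):
        edges = np.zeros((64, 64), dtype=bool)
        edges[10, 10:31] = edges[30, 10:31] = True
        edges[10:31, 10] = True  # right side missing: open contour
        out = edges_to_mask(edges, erosion_iterations=0)
        assert not out[20, 20]

    def test_empty_edges_empty_mask(self):
        assert not edges_to_mask(np.zeros((32, 32), dtype=bool)).any()

    def test_matches_brute_force_oracle_on_random_blobs(self, rng):
        """Fill + erode equals the pixel-by-pixel oracle on 64x64 fixtures."""
        for _ in range(5):
            blob = rng.random((64, 64)) > 0.7
            for it in (0, 1, 2):
                out = edges_to_mask(blob, erosion_iterations=it)
                oracle = brute_force_fill_holes(blob)
                if it:
                    oracle = brute_force_erode_cross(oracle, it)
                np.testing.assert_array_equal(out, oracle)


# ---------------------------------------------------------------------------
# label_cells / measure_cells / density
# ---------------------------------------------------------------------------

class TestLabeling:
    def test_two_blobs_two_labels_in_raster_order(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[25:31, 2:8] = True   # later in raster order
        mask[4:10, 20:26] = True  # first pixel comes first
        lab = label_cells(mask, min_area_px=10, max_area_px=100)
        assert lab.n_cells == 2
        assert lab.labels[4, 20] == 1
        assert lab.labels[25, 2] == 2

    def test_area_bounds_inclusive(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[2:7, 2:6] = True  # area 20
        lab = label_cells(mask, min_area_px=20, max_area_px=100)
        assert lab.n_cells == 1
        lab2 = label_cells(mask, min_area_px=21, max_area_px=100)
        assert lab2.n_cells == 0
        assert lab2.n_removed_small == 1

    def test_area_conservation(self, rng):
        mask = rng.random((64, 64)) > 0.8
        lab = label_cells(mask, min_area_px=1, max_area_px=64 * 64)
        assert np.sum(
            np.bincount(lab.labels.ravel())[1:]
        ) == np.count_nonzero(mask)

    def test_pipeline_deterministic(self, small_scene):
        img = render_image(small_scene, AcquisitionSpec())
        irr = linearize(
            subtract_background(img.pixels, 15), InverseLUT.identity(), 10.0
        )
        a = segment(irr, erosion_iterations=2)
        b = segment(irr, erosion_iterations=2)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestMeasure:
    def test_uniform_cell_mean_exact(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:5, 2:5] = 1
        irr = np.where(labels == 1, 0.625, 0.0)
        recs = measure_cells(LabeledMask(labels=labels, n_cells=1), irr)
        assert recs[0].mean_irradiance_per_ms == 0.625
        assert recs[0].area_px == 9

    def test_small_cell_arithmetic(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[0, :] = 1
        irr = np.zeros((4, 4))
        irr[0, :] = [1.0, 2.0, 3.0, 4.0]
        recs = measure_cells(LabeledMask(labels=labels, n_cells=1), irr)
        assert recs[0].mean_irradiance_per_ms == 2.5

    def test_shape_mismatch_rejected(self):
        lab = LabeledMask(labels=np.zeros((8, 8), dtype=np.int32), n_cells=0)
        with pytest.raises(ValueError, match="shape"):
            measure_cells(lab, np.zeros((9, 9)))

    def test_recovery_unbiased_on_synthetic_scene(self):
        """Median relative error of per-cell mean irradiance vs ground
        truth below 5% at high SNR."""
        spec = SceneSpec(n_cells=60, noise_sd=12.75, seed=31)  # SNR 10
        truth = generate_scene(spec)
        img = render_image(truth, AcquisitionSpec())
        irr = linearize(
            subtract_background(img.pixels, 15), InverseLUT.identity(), 10.0
        )
        lab = segment(irr, erosion_iterations=2)
        recs = measure_cells(lab, irr)
        rel = []
        for r in recs:
            lbl = truth.label_map[int(round(r.centroid[0])), int(round(r.centroid[1]))]
            if lbl > 0:
                t = truth.cells[lbl - 1].true_fluorescence
                rel.append((r.mean_irradiance_per_ms * 10.0 - t) / t)
        assert len(rel) >= 0.9 * spec.n_cells
        assert abs(np.median(rel)) < 0.05


class TestDensity:
    def test_zero_cells_zero_density(self):
        lab = LabeledMask(labels=np.zeros((8, 8), dtype=np.int32), n_cells=0)
        assert estimate_density(lab, 3.0).density == 0.0

    def test_count_over_volume(self):
        lab = LabeledMask(labels=np.zeros((8, 8), dtype=np.int32), n_cells=30)
        assert estimate_density(lab, 3.0).density == 10.0

    def test_nonpositive_volume_rejected(self):
        lab = LabeledMask(labels=np.zeros((8, 8), dtype=np.int32), n_cells=1)
        with pytest.raises(ValueError, match="volume"):
            estimate_density(lab, 0.0)


class TestObjectLevelQuality:
    def test_precision_recall_on_sparse_rods(self):
        """100 non-touching rods at SNR 5: object-level precision and
        recall at least 0.95 (match: detected centroid inside a true
        footprint)."""
        spec = SceneSpec(n_cells=100, noise_sd=25.5, seed=33)  # SNR 5
        truth = generate_scene(spec)
        img = render_image(truth, AcquisitionSpec())
        irr = linearize(
            subtract_background(img.pixels, 15), InverseLUT.identity(), 10.0
        )
        lab = segment(irr, erosion_iterations=2)
        recs = measure_cells(lab, irr)
        hit = set()
        tp = 0
        for r in recs:
            lbl = truth.label_map[int(round(r.centroid[0])), int(round(r.centroid[1]))]
            if lbl > 0 and lbl not in hit:
                hit.add(lbl)
                tp += 1
        precision = tp / len(recs)
        recall = tp / truth.n_cells
        assert precision >= 0.95
        assert recall >= 0.95
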