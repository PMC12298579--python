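"""Colour thresholding, mask refinement, polygon rasterisation, full chain."""

import numpy as np
import pytest

from canopyield.fixtures import PRESETS, generate_canopy_scene
from canopyield.segmentation import (
    NoPlantFoundError,
    boundary_contour,
    color_segment,
    contour_to_mask,
    excess_green,
    refine_mask,
    segment_canopy,
)
from canopyield.types import Contour, SegmentationConfig


def jaccard(a, b):
    return (a & b).sum() / (a | b).sum()


class TestColorSegment:
    def test_excess_green_extremes(self):
        image = np.array([[[0, 255, 0], [255, 255, 255]]], dtype=np.uint8)
        exg = excess_green(image)
        assert exg[0, 0] == 510  # pure green
        assert exg[0, 1] == 0  # white

    def test_two_level_image_recovers_exact_region(self):
        image = np.full((64, 64, 3), 235, dtype=np.uint8)
        region = np.zeros((64, 64), dtype=bool)
        region[20:44, 12:52] = True
        image[region] = (60, 140, 50)
        mask = color_segment(image)
        assert np.array_equal(mask, region)

    def test_all_board_image_raises(self):
        rng = np.random.default_rng(0)
        image = np.clip(rng.normal(235, 5, (64, 64, 3)), 0, 255).astype(np.uint8)
        with pytest.raises(NoPlantFoundError):
            color_segment(image)

    def test_constant_image_raises(self):
        image = np.full((32, 32, 3), 100, dtype=np.uint8)
        with pytest.raises(NoPlantFoundError):
            color_segment(image)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            excess_green(np.zeros((10, 10), dtype=np.uint8))


class TestRefineMask:
    def test_interior_hole_filled(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 5:35] = True
        mask[18:21, 18:21] = False  # 3x3 interior hole
        out = refine_mask(mask, SegmentationConfig(se_radius=2))
        assert out[18:21, 18:21].all()

    def test_refine_is_idempotent_on_convex_mask(self):
        mask = np.zeros((60, 60), dtype=bool)
        rows, cols = np.mgrid[0:60, 0:60]
        mask[(rows - 30) ** 2 + (cols - 30) ** 2 <= 20**2] = True
        config = SegmentationConfig(se_radius=1)
        once = refine_mask(mask, config)
        twice = refine_mask(once, config)
        assert np.array_equal(once, twice)
        assert not (mask & ~once).any()  # refinement never removes the plant

    def test_speckles_removed_by_largest_component_rule(self):
        mask = np.zeros((120, 120), dtype=bool)
        rows, cols = np.mgrid[0:120, 0:120]
        rosette = (rows - 60) ** 2 + (cols - 60) ** 2 <= 30**2
        mask |= rosette
        for r, c in [(5, 5), (5, 110), (110, 5), (110, 110), (5, 60)]:
            mask[r : r + 3, c : c + 3] = True  # 9 px speckles
        out = refine_mask(mask, SegmentationConfig(se_radius=2))
        assert (out & ~refine_mask(rosette, SegmentationConfig(se_radius=2))).sum() == 0
        assert out[60, 60]

    def test_empty_mask_raises(self):
        with pytest.raises(NoPlantFoundError):
            refine_mask(np.zeros((10, 10), dtype=bool))


class TestContourToMask:
    def test_axis_aligned_square_pixel_count(self):
        square = Contour(np.array([[0.0, 0.0], [0.0, 9.0], [9.0, 9.0], [9.0, 0.0]]))
        mask = contour_to_mask(square, (12, 12))
        assert mask.sum() == 100

    def test_triangle_matches_bruteforce_point_in_polygon(self):
        tri = np.array([[2.0, 2.0], [2.0, 17.0], [14.0, 9.0]])
        mask = contour_to_mask(Contour(tri), (20, 20))

        def ray_cast(py, px):
            """Even-odd crossing count, with an on-edge check."""
            n = len(tri)
            inside = False
            for i in range(n):
                (y1, x1), (y2, x2) = tri[i], tri[(i + 1) % n]
                # on-segment test
                cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
                if abs(cross) < 1e-9 and min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9 \
                        and min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9:
                    return True
                if (y1 > py) != (y2 > py):
                    x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < x_at:
                        inside = not inside
            return inside

        oracle = np.array(
            [[ray_cast(float(r), float(c)) for c in range(20)] for r in range(20)]
        )
        assert np.array_equal(mask, oracle)

    def test_orientation_invariance(self):
        tri = np.array([[2.0, 2.0], [2.0, 17.0], [14.0, 9.0]])
        forward = contour_to_mask(Contour(tri), (20, 20))
        backward = contour_to_mask(Contour(tri[::-1]), (20, 20))
        assert np.array_equal(forward, backward)

    def test_self_intersecting_polygon_still_filled(self, caplog):
        bowtie = Contour(
            np.array([[0.0, 0.0], [10.0, 10.0], [0.0, 10.0], [10.0, 0.0]])
        )
        with caplog.at_level("WARNING", logger="canopyield.segmentation"):
            mask = contour_to_mask(bowtie, (12, 12))
        assert mask.any()
        assert any("self-intersecting" in r.message for r in caplog.records)


class TestSegmentCanopy:
    def test_stress_free_scene_high_jaccard(self, mid_scene, mid_scene_segmented):
        assert jaccard(mid_scene_segmented.mask, mid_scene.truth_mask) >= 0.90

    def test_pixel_count_consistent_with_mask(self, mid_scene_segmented):
        assert mid_scene_segmented.pixel_count == int(mid_scene_segmented.mask.sum())

    def test_mask_at_native_resolution(self, mid_scene, mid_scene_segmented):
        assert mid_scene_segmented.mask.shape == mid_scene.image.shape[:2]

    def test_deterministic(self, mid_scene, mid_scene_segmented):
        again = segment_canopy(mid_scene.image)
        assert np.array_equal(again.mask, mid_scene_segmented.mask)
        assert again.pixel_count == mid_scene_segmented.pixel_count

    def test_all_board_raises_no_plant_found(self):
        rng = np.random.default_rng(1)
        image = np.clip(rng.normal(235, 5, (96, 96, 3)), 0, 255).astype(np.uint8)
        with pytest.raises(NoPlantFoundError):
            segment_canopy(image)

    def test_small_scene_without_downscaling(self):
        scene = generate_canopy_scene(PRESETS["tiny256"], "seedling", seed=2)
        result = segment_canopy(scene.image)
        assert jaccard(result.mask, scene.truth_mask) >= 0.75
        assert 0.8 <= result.pixel_count / scene.truth_pixel_count <= 1.25

    def test_boundary_contour_traces_largest_region(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        contour = boundary_contour(mask)
        v = contour.vertices
        assert v[:, 0].min() >= 9 and v[:, 0].max() <= 30
        assert len(contour) >= 3
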