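"""Disc ellipse and quadrant partition geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octavd import (DiscAnnotation, EnFaceImage, build_region_set,
                    ellipse_from_bbox, ellipse_mask, quadrant_masks)


def _enface(scan_type, segment, laterality="OD", shape=(120, 120)):
    return EnFaceImage(pixels=np.zeros(shape), scan_type=scan_type,
                       segment_label=segment, laterality=laterality,
                       subject_id="S1", scan_index=1)


class TestEllipse:
    def test_bbox_midpoint_and_semi_axes(self):
        geom = ellipse_from_bbox(DiscAnnotation(bbox=(10, 20, 50, 60)))
        assert geom.center == (30, 40)
        assert geom.semi_axes == (20, 20)

    def test_square_bbox_gives_circle(self):
        geom = ellipse_from_bbox(DiscAnnotation(bbox=(5, 9, 45, 49)))
        assert geom.semi_axes[0] == geom.semi_axes[1]

    def test_degenerate_bbox_rejected(self):
        with pytest.raises(ValueError):
            DiscAnnotation(bbox=(10, 10, 10, 40))

    def test_raster_area_matches_analytic(self):
        geom = ellipse_from_bbox(DiscAnnotation(bbox=(70, 70, 130, 130)))
        count = ellipse_mask(geom, (200, 200)).sum()
        assert abs(count - np.pi * 30 * 30) / (np.pi * 30 * 30) < 0.02

    def test_raster_error_shrinks_with_radius(self):
        errors = []
        for r in (10, 30, 60):
            geom = ellipse_from_bbox(
                DiscAnnotation(bbox=(100 - r, 100 - r, 100 + r, 100 + r)))
            count = ellipse_mask(geom, (200, 200)).sum()
            errors.append(abs(count - np.pi * r * r) / (np.pi * r * r))
        assert errors[2] < errors[0]


class TestQuadrantMasks:
    def test_half_integer_center_splits_evenly(self):
        # oracle: brute-force per-pixel sector classification with the tie
        # rule applied ray by ray (pixels on both full diagonals of the grid
        # lie exactly on the dividing lines for this center)
        masks = quadrant_masks((100, 100), (49.5, 49.5), "OD")
        oracle = {"superior": 0, "inferior": 0, "left": 0, "right": 0}
        for y in range(100):
            for x in range(100):
                dx, dy = x - 49.5, y - 49.5
                if abs(dy) > abs(dx):
                    oracle["superior" if dy < 0 else "inferior"] += 1
                elif abs(dx) > abs(dy):
                    oracle["left" if dx < 0 else "right"] += 1
                elif dy == -dx:  # anti-diagonal: vertical sector of the ray
                    oracle["superior" if dy < 0 else "inferior"] += 1
                else:            # diagonal: horizontal sector of the ray
                    oracle["left" if dx < 0 else "right"] += 1
        assert oracle == {"superior": 2500, "inferior": 2500,
                          "left": 2500, "right": 2500}
        assert masks["superior"].sum() == oracle["superior"]
        assert masks["inferior"].sum() == oracle["inferior"]
        assert all(m.sum() == 2500 for m in masks.values())

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(h=st.integers(8, 60), w=st.integers(8, 60),
           cx=st.floats(0.5, 0.9), cy=st.floats(0.5, 0.9),
           lat=st.sampled_from(["OD", "OS"]))
    def test_masks_partition_the_grid(self, h, w, cx, cy, lat):
        center = (cx * (w - 1), cy * (h - 1))
        masks = quadrant_masks((h, w), center, lat)
        total = np.zeros((h, w), dtype=int)
        for m in masks.values():
            total += m.astype(int)
        assert np.all(total == 1)  # pairwise disjoint and covering

    def test_laterality_swaps_nasal_temporal(self):
        od = quadrant_masks((64, 64), (31.5, 31.5), "OD")
        os_ = quadrant_masks((64, 64), (31.5, 31.5), "OS")
        np.testing.assert_array_equal(od["superior"], os_["superior"])
        np.testing.assert_array_equal(od["inferior"], os_["inferior"])
        np.testing.assert_array_equal(od["nasal"], os_["temporal"])
        np.testing.assert_array_equal(od["temporal"], os_["nasal"])

    def test_tie_pixels_follow_stated_rule(self):
        # integer center: anti-diagonal rays to superior/inferior, diagonal
        # rays to the horizontal sectors, center pixel to superior
        masks = quadrant_masks((9, 9), (4, 4), "OD", od_nasal_side="right")
        assert masks["superior"][4, 4]   # center pixel
        assert masks["superior"][2, 6]   # anti-diagonal, above center
        assert masks["inferior"][6, 2]   # anti-diagonal, below center
        assert masks["nasal"][6, 6]      # diagonal, right of center (OD)
        assert masks["temporal"][2, 2]   # diagonal, left of center (OD)
        total = sum(int(m.sum()) for m in masks.values())
        assert total == 81

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            quadrant_masks((10, 10), (12.0, 3.0), "OD")


class TestBuildRegionSet:
    def test_macula_defaults(self):
        rset = build_region_set(_enface("macula", "deep_retina", shape=(304, 304)))
        assert rset.center_used == (151.5, 151.5)
        assert rset.segment_mask.all()
        assert rset.ellipse is None

    def test_disc_quadrant_apex_at_ellipse_center(self):
        rset = build_region_set(
            _enface("disc", "rpc", shape=(304, 304)),
            DiscAnnotation(bbox=(100, 100, 200, 200)))
        assert rset.center_used == (150, 150)
        assert rset.ellipse.semi_axes == (50, 50)

    def test_macula_with_annotation_rejected(self):
        with pytest.raises(ValueError, match="macula"):
            build_region_set(_enface("macula", "deep_retina"),
                             DiscAnnotation(bbox=(10, 10, 50, 50)))

    def test_disc_without_annotation_rejected(self):
        with pytest.raises(ValueError, match="disc"):
            build_region_set(_enface("disc", "rpc"))

    @pytest.mark.parametrize("interior", ["include", "exclude_inside_ellipse",
                                          "only_inside_ellipse"])
    def test_random_annotations_tile_exactly(self, interior):
        rng = np.random.default_rng(17)
        for _ in range(50):
            x0, y0 = rng.integers(5, 50, size=2)
            x1 = x0 + rng.integers(10, 60)
            y1 = y0 + rng.integers(10, 60)
            rset = build_region_set(
                _enface("disc", "rpc"),
                DiscAnnotation(bbox=(float(x0), float(y0), float(x1), float(y1))),
                disc_interior=interior)
            counts = rset.pixel_counts()
            quads = sum(counts[q] for q in ("superior", "inferior",
                                            "nasal", "temporal"))
            assert quads == counts["segment"]

    def test_disc_interior_modes_partition_frame(self):
        ann = DiscAnnotation(bbox=(30, 30, 80, 90))
        img = _enface("disc", "rpc")
        inside = build_region_set(img, ann, disc_interior="only_inside_ellipse")
        outside = build_region_set(img, ann, disc_interior="exclude_inside_ellipse")
        assert (inside.segment_mask.sum() + outside.segment_mask.sum()
                == img.pixels.size)
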