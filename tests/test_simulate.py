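from __future__ import annotations

import math

import numpy as np
import pytest

from pcpa import (
    GroundTruthCell,
    RunConfig,
    analyze_image,
    find_chunks,
    make_disk_cell,
    make_doublet,
    make_tissue,
    make_u_cell,
    raw_angle,
)
from pcpa.simulate import _disk_pixels

from _oracles import circular_error


def centroid(pixels):
    xs = [p[0] for p in pixels]
    ys = [p[1] for p in pixels]
    return sum(xs) / len(xs), sum(ys) / len(ys)


class TestMakeDiskCell:
    def test_north_bearing_puts_hole_above_center(self):
        truth = GroundTruthCell((30, 30), 10, 5, 90, 2)
        chunk, cave = make_disk_cell(truth)
        cx, cy = centroid(cave)
        assert cy == pytest.approx(25, abs=0.5)
        assert cx == pytest.approx(30, abs=0.5)

    def test_east_bearing_puts_hole_right_of_center(self):
        truth = GroundTruthCell((30, 30), 10, 5, 0, 2)
        _, cave = make_disk_cell(truth)
        cx, cy = centroid(cave)
        assert cx == pytest.approx(35, abs=0.5)
        assert cy == pytest.approx(30, abs=0.5)

    def test_concentric_hole_yields_coincident_centroids(self):
        truth = GroundTruthCell((30, 30), 10, 0, 0, 3)
        chunk, cave = make_disk_cell(truth)
        assert centroid(chunk) == pytest.approx(centroid(cave))
        with pytest.raises(ValueError):
            raw_angle(centroid(chunk), centroid(cave))

    def test_hole_containment_enforced(self):
        with pytest.raises(ValueError):
            make_disk_cell(GroundTruthCell((30, 30), 10, 8, 0, 3))

    def test_rasterization_rule_pixel_center_in_disk(self):
        pixels = _disk_pixels(5.0, 5.0, 2.0)
        expected = {
            (x, y)
            for x in range(0, 11)
            for y in range(0, 11)
            if (x - 5.0) ** 2 + (y - 5.0) ** 2 <= 4.0
        }
        assert pixels == expected


class TestMakeUCell:
    @pytest.mark.parametrize("bearing,expected", [(90.0, 90.0), (0.0, 0.0)])
    def test_mouth_bearing_recovered_with_wrap(self, bearing, expected):
        truth = GroundTruthCell((30, 30), 14, 0, bearing, 7)
        pixels = make_u_cell(truth)
        arr = np.zeros((64, 64), np.uint8)
        for x, y in pixels:
            arr[y, x] = 1
        from pcpa import BinaryImage

        cfg = RunConfig(min_chunk_px=None, border_margin_px=0, min_cave_px=None)
        result = analyze_image(BinaryImage(arr), cfg)
        assert len(result.measurements) == 1
        assert circular_error(result.measurements[0].angle, expected) < 5.0

    def test_without_wrap_unmeasurable(self):
        truth = GroundTruthCell((30, 30), 14, 0, 90, 7)
        pixels = make_u_cell(truth)
        arr = np.zeros((64, 64), np.uint8)
        for x, y in pixels:
            arr[y, x] = 1
        from pcpa import BinaryImage

        cfg = RunConfig(
            min_chunk_px=None, border_margin_px=0, min_cave_px=None, plastic_wrap=False
        )
        result = analyze_image(BinaryImage(arr), cfg)
        assert result.measurements == []
        assert result.summary.bad_count == 1


class TestMakeDoublet:
    def test_horizontal_fusion_is_one_wide_chunk(self):
        a = GroundTruthCell((40, 40), 10, 5, 90, 3)
        b = GroundTruthCell((0, 0), 10, 5, 0, 3)
        pixels, ta, tb = make_doublet(a, b, "horizontal")
        arr = np.zeros((90, 110), np.uint8)
        for x, y in pixels:
            arr[y, x] = 1
        from pcpa import BinaryImage

        chunks = find_chunks(BinaryImage(arr))
        assert len(chunks) == 1
        x0, y0, x1, y1 = chunks[0].bbox
        assert (x1 - x0 + 1) / (y1 - y0 + 1) >= 2.0

    def test_split_recovers_both_bearings(self):
        a = GroundTruthCell((40, 40), 12, 6, 90, 3)
        b = GroundTruthCell((0, 0), 12, 6, 30, 3)
        pixels, ta, tb = make_doublet(a, b, "horizontal")
        arr = np.zeros((90, 130), np.uint8)
        for x, y in pixels:
            arr[y, x] = 1
        from pcpa import BinaryImage

        cfg = RunConfig(min_chunk_px=None, border_margin_px=0, min_cave_px=None)
        result = analyze_image(BinaryImage(arr), cfg)
        assert len(result.measurements) == 2
        measured = sorted(m.angle for m in result.measurements)
        for truth in (ta, tb):
            assert min(circular_error(truth.bearing_deg, m) for m in measured) < 3.0

    def test_splitting_disabled_keeps_one_chunk(self):
        a = GroundTruthCell((40, 40), 10, 5, 90, 3)
        b = GroundTruthCell((0, 0), 10, 5, 0, 3)
        pixels, *_ = make_doublet(a, b, "horizontal")
        arr = np.zeros((90, 110), np.uint8)
        for x, y in pixels:
            arr[y, x] = 1
        from pcpa import BinaryImage

        cfg = RunConfig(
            min_chunk_px=None, border_margin_px=0, min_cave_px=None, doublet_enabled=False
        )
        result = analyze_image(BinaryImage(arr), cfg)
        assert result.summary.total_count == 1

    def test_diagonal_fusion_splits_into_two(self):
        a = GroundTruthCell((40, 40), 10, 5, 90, 3)
        b = GroundTruthCell((0, 0), 10, 5, 0, 3)
        pixels, *_ = make_doublet(a, b, "diagonal")
        arr = np.zeros((100, 120), np.uint8)
        for x, y in pixels:
            arr[y, x] = 1
        from pcpa import BinaryImage

        cfg = RunConfig(
            min_chunk_px=None,
            border_margin_px=0,
            min_cave_px=None,
            doublet_ratio=1.25,
        )
        result = analyze_image(BinaryImage(arr), cfg)
        # Count only; split quality is degraded off-axis by design.
        assert result.summary.total_count == 2


class TestMakeTissue:
    def test_truth_count_matches_components(self):
        image, truth = make_tissue(12, seed=5, image_size=(512, 512))
        assert len(truth) == 12
        assert len(find_chunks(image)) == 12

    def test_empty_tissue(self):
        image, truth = make_tissue(0, seed=1, image_size=(128, 128))
        assert image.pixels.sum() == 0
        assert truth.empty

    def test_seed_determinism(self):
        img_a, truth_a = make_tissue(8, seed=9, image_size=(400, 400))
        img_b, truth_b = make_tissue(8, seed=9, image_size=(400, 400))
        assert (img_a.pixels == img_b.pixels).all()
        assert truth_a.equals(truth_b)

    def test_overcrowding_raises(self):
        with pytest.raises(ValueError, match="dimensions"):
            make_tissue(50, seed=0, image_size=(150, 150))

    def test_speckles_add_small_components(self):
        image, truth = make_tissue(
            4, seed=2, image_size=(400, 400), n_speckles=3, speckle_size=16
        )
        chunks = find_chunks(image)
        small = [c for c in chunks if c.size <= 16]
        assert len(chunks) == 4 + len(small)
        assert len(small) == 3

    def test_fixed_bearing_recovery(self):
        image, truth = make_tissue(20, bearing=45.0, seed=3, image_size=(512, 512))
        result = analyze_image(image, RunConfig())
        assert len(result.measurements) == 20
        for m in result.measurements:
            assert circular_error(m.angle, 45.0) < 2.0

    def test_vonmises_concentration_increases_measured_rml(self):
        rmls = []
        for kappa in (0.5, 2.0, 8.0):
            values = []
            for seed in (0, 1, 2):
                image, _ = make_tissue(
                    40,
                    bearing="vonmises",
                    vonmises_kappa=kappa,
                    seed=seed,
                    image_size=(900, 900),
                )
                result = analyze_image(image, RunConfig())
                values.append(result.summary.rml)
            rmls.append(np.mean(values))
        assert rmls[0] < rmls[1] < rmls[2]

    def test_angle_recovery_random_cells(self):
        image, truth = make_tissue(60, bearing="uniform", seed=21, image_size=(768, 768))
        result = analyze_image(image, RunConfig())
        assert len(result.measurements) == 60
        errs = []
        for m in result.measurements:
            cx, cy = m.chunk_centroid
            d2 = (truth.x - cx) ** 2 + (truth.y - cy) ** 2
            row = truth.loc[d2.idxmin()]
            errs.append(circular_error(m.angle, row.bearing_deg))
        assert max(errs) < 2.0
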