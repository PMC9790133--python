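import numpy as np
import pytest

from oracles import fast_corners, fast_score
from spvsim.enhance import (
    CannyParams,
    ClipArtRegistry,
    CornerSet,
    Detection,
    DetectorError,
    FastParams,
    detect_corners,
    detect_edges,
    emphasize_corners,
    register_ground_truth,
    resize_nearest,
    sharpen_edges,
    stub_detector,
    substitute_clipart,
)
from spvsim.imaging import BoundingBox


def make_step(width=64):
    img = np.zeros((width, width), dtype=np.uint8)
    img[:, width // 2:] = 255
    return img


class TestCanny:
    def test_constant_image_has_no_edges(self):
        assert detect_edges(np.full((16, 16), 77, np.uint8)).sum() == 0

    def test_step_edge_is_thin_and_localized(self):
        edges = detect_edges(make_step())
        rows, cols = np.nonzero(edges)
        assert len(rows) > 0
        # edge confined to the step boundary, at most 2 px per row
        assert set(cols) <= {30, 31, 32, 33}
        per_row = np.bincount(rows, minlength=64)
        assert per_row.max() <= 2

    def test_edge_count_invariant_under_inversion(self):
        step = make_step()
        assert detect_edges(step).sum() == detect_edges(255 - step).sum()

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            CannyParams(low_threshold=0.2, high_threshold=0.1)
        with pytest.raises(ValueError):
            detect_edges(np.zeros((2, 5), np.uint8))


class TestSharpenEdges:
    def test_empty_map_is_identity(self, rng):
        img = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        np.testing.assert_array_equal(
            sharpen_edges(img, np.zeros_like(img)), img
        )

    def test_full_map_saturates(self, rng):
        img = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        assert (sharpen_edges(img, np.ones_like(img)) == 255).all()

    def test_matches_saturating_add_on_step(self):
        step = make_step()
        edges = detect_edges(step)
        out = sharpen_edges(step, edges)
        expected = np.clip(step.astype(int) + 255 * edges.astype(int), 0, 255)
        np.testing.assert_array_equal(out, expected.astype(np.uint8))

    def test_never_darkens(self, rng):
        img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        edges = (rng.random((12, 12)) < 0.2).astype(np.uint8)
        assert (sharpen_edges(img, edges) >= img).all()


class TestFast:
    def test_constant_image_has_no_corners(self):
        assert len(detect_corners(np.full((16, 16), 100, np.uint8))) == 0

    def test_square_corners_match_oracle(self):
        img = np.zeros((32, 32), np.uint8)
        img[11:21, 11:21] = 255
        # a 90-degree corner subtends 11 of the 16 circle pixels: at the
        # default 12-contiguous test neither detector nor oracle fires,
        # at 11 both find exactly the four square corners
        for n in (11, 12):
            params = FastParams(n_contiguous=n)
            got = sorted(detect_corners(img, params).points)
            expected = fast_corners(img, params.t, n, params.min_quality)
            assert got == expected
        pts = sorted(detect_corners(img, FastParams(n_contiguous=11)).points)
        assert pts == [(11, 11), (11, 20), (20, 11), (20, 20)]
        assert len(detect_corners(img, FastParams(n_contiguous=12))) == 0

    def test_subthreshold_contrast_yields_nothing(self):
        img = np.zeros((32, 32), np.uint8)
        img[11:21, 11:21] = 30  # below t*255 = 51
        for n in (9, 11, 12):
            assert len(detect_corners(img, FastParams(n_contiguous=n))) == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_bruteforce_on_random_patterns(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        params = FastParams()
        got = sorted(detect_corners(img, params).points)
        expected = fast_corners(
            img, params.t, params.n_contiguous, params.min_quality
        )
        assert got == expected

    def test_scores_match_oracle_pointwise(self):
        rng = np.random.default_rng(99)
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        from spvsim.enhance import _segment_scores

        scores = _segment_scores(img, 12)
        for r in range(3, 13):
            for c in range(3, 13):
                assert scores[r, c] == fast_score(img, r, c, 12)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            detect_corners(np.zeros((6, 10), np.uint8))


class TestEmphasizeCorners:
    def test_empty_set_is_identity(self, rng):
        img = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        np.testing.assert_array_equal(
            emphasize_corners(img, CornerSet(points=())), img
        )

    def test_single_corner_paints_nine_pixels(self):
        img = np.zeros((12, 12), np.uint8)
        out = emphasize_corners(img, CornerSet(points=((5, 5),)))
        assert (out == 255).sum() == 9
        assert (out[4:7, 4:7] == 255).all()

    def test_overlapping_neighborhoods_take_union(self):
        img = np.zeros((12, 12), np.uint8)
        out = emphasize_corners(img, CornerSet(points=((5, 5), (5, 6))))
        assert (out == 255).sum() == 12  # 3x4 union, fewer than 18

    def test_never_darkens(self, rng):
        img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        out = emphasize_corners(img, CornerSet(points=((4, 4), (8, 8))))
        assert (out >= img).all()


class TestClipArt:
    def test_direct_paste_when_sizes_match(self, rng):
        scene = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        art = rng.integers(0, 256, (6, 5), dtype=np.uint8)
        reg = ClipArtRegistry()
        reg.add("cup", art)
        det = Detection("cup", BoundingBox(3, 4, 6, 5))
        out = substitute_clipart(scene, det, reg)
        np.testing.assert_array_equal(out[3:9, 4:9], art)

    def test_pixel_count_after_substitution(self):
        scene = np.zeros((20, 20), np.uint8)
        reg = ClipArtRegistry()
        reg.add("cup", np.full((4, 4), 255, np.uint8))
        det = Detection("cup", BoundingBox(5, 5, 10, 10))
        out = substitute_clipart(scene, det, reg)
        assert (out == 255).sum() == 100

    def test_complement_of_bbox_untouched(self, rng):
        scene = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        reg = ClipArtRegistry()
        reg.add("cup", rng.integers(0, 256, (3, 3), dtype=np.uint8))
        det = Detection("cup", BoundingBox(2, 2, 8, 8))
        out = substitute_clipart(scene, det, reg)
        mask = np.ones((20, 20), bool)
        mask[2:10, 2:10] = False
        np.testing.assert_array_equal(out[mask], scene[mask])

    def test_checkerboard_upsamples_to_blocks(self):
        cb = (np.indices((4, 4)).sum(0) % 2 * 255).astype(np.uint8)
        out = resize_nearest(cb, 8, 8)
        for i in range(4):
            for j in range(4):
                assert (out[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] == cb[i, j]).all()

    def test_unknown_label_names_the_label(self):
        reg = ClipArtRegistry()
        with pytest.raises(KeyError, match="xyz"):
            substitute_clipart(
                np.zeros((10, 10), np.uint8),
                Detection("xyz", BoundingBox(0, 0, 2, 2)),
                reg,
            )


class TestStubDetector:
    def test_echoes_registered_ground_truth(self, bottle_scene):
        img, dets = bottle_scene
        assert stub_detector(img) == dets

    def test_pair_returned_left_to_right(self, pair_scene):
        img, dets = pair_scene
        out = stub_detector(img)
        assert [d.label for d in out] == ["bottle", "cup"]
        assert out[0].bbox.col0 < out[1].bbox.col0

    def test_empty_scene_yields_empty_list(self):
        img = np.full((32, 32), 230, np.uint8)
        register_ground_truth(img, [])
        assert stub_detector(img) == []

    def test_unregistered_image_raises(self):
        with pytest.raises(DetectorError):
            stub_detector(np.arange(64, dtype=np.uint8).reshape(8, 8))
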