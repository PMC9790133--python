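import logging

import numpy as np
import pytest

from oracles import placement_by_enumeration
from spvsim.dropout import (
    DropoutMap,
    apply_translation,
    best_placement,
    generate_dropout_map,
    load_dropout_map,
    save_dropout_map,
)
from spvsim.imaging import BoundingBox


class TestGenerate:
    def test_zero_rate_gives_all_working(self):
        assert generate_dropout_map(8, 8, 0.0, seed=1).n_dropped == 0

    def test_default_grid_has_102_dropouts(self):
        dmap = generate_dropout_map(32, 32, 0.10, seed=7)
        assert dmap.n_dropped == 102  # round(0.10 * 1024)

    def test_seed_reproducibility_and_variation(self):
        a = generate_dropout_map(16, 16, 0.2, seed=5)
        b = generate_dropout_map(16, 16, 0.2, seed=5)
        c = generate_dropout_map(16, 16, 0.2, seed=6)
        np.testing.assert_array_equal(a.grid, b.grid)
        assert not np.array_equal(a.grid, c.grid)

    @pytest.mark.parametrize("rate", [-0.1, 1.0, 1.5])
    def test_bad_rate_rejected(self, rate):
        with pytest.raises(ValueError):
            generate_dropout_map(8, 8, rate, seed=0)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_count_across_rates_and_seeds(self, seed):
        for rate in (0.05, 0.1, 0.25):
            dmap = generate_dropout_map(12, 12, rate, seed=seed)
            assert dmap.n_dropped == round(rate * 144)


class TestBestPlacement:
    def test_all_working_map_gives_zero_translation(self):
        dmap = DropoutMap(np.zeros((8, 8), bool), rate=0.0, seed=0)
        support = np.ones((3, 3), bool)
        p = best_placement(dmap, support, orig_topleft=(2, 3))
        assert p.translation == (0, 0)
        assert p.score == 9

    def test_avoids_the_dropout_half(self):
        grid = np.zeros((8, 8), bool)
        grid[:, :4] = True  # left half all dropped
        dmap = DropoutMap(grid, rate=0.5, seed=0)
        p = best_placement(dmap, np.ones((3, 3), bool), orig_topleft=(0, 0))
        assert p.score == 9
        assert p.center_col >= 4 + 1  # fully in the right half

    def test_single_pixel_support_prefers_nearest_working_site(self):
        grid = np.zeros((5, 5), bool)
        grid[2, 2] = True  # original site dropped
        dmap = DropoutMap(grid, rate=0.04, seed=0)
        p = best_placement(dmap, np.ones((1, 1), bool), orig_topleft=(2, 2))
        assert p.score == 1
        dist = np.hypot(p.center_row - 2, p.center_col - 2)
        assert dist == 1.0  # one of the 4-neighbors

    def test_support_larger_than_grid_rejected(self):
        dmap = DropoutMap(np.zeros((4, 4), bool), rate=0, seed=0)
        with pytest.raises(ValueError):
            best_placement(dmap, np.ones((5, 2), bool))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        rows = int(rng.integers(4, 13))
        cols = int(rng.integers(4, 13))
        rate = float(rng.uniform(0.05, 0.5))
        dmap = generate_dropout_map(rows, cols, rate, seed=seed)
        sh = int(rng.integers(1, rows))
        sw = int(rng.integers(1, cols))
        support = rng.random((sh, sw)) < 0.7
        support.flat[0] = True  # non-empty
        orig = (
            int(rng.integers(0, rows - sh + 1)),
            int(rng.integers(0, cols - sw + 1)),
        )
        p = best_placement(dmap, support, orig_topleft=orig)
        (er0, ec0), escore = placement_by_enumeration(dmap.grid, support, orig)
        assert p.score == escore
        assert p.translation == (er0 - orig[0], ec0 - orig[1])

    @pytest.mark.parametrize("seed", range(10))
    def test_overlap_count_is_minimal(self, seed):
        dmap = generate_dropout_map(10, 10, 0.3, seed=seed)
        support = np.ones((4, 3), bool)
        p = best_placement(dmap, support, orig_topleft=(3, 3))
        r0 = p.center_row - (support.shape[0] - 1) // 2
        c0 = p.center_col - (support.shape[1] - 1) // 2
        chosen_overlap = dmap.grid[r0 : r0 + 4, c0 : c0 + 3].sum()
        for rr in range(7):
            for cc in range(8):
                other = dmap.grid[rr : rr + 4, cc : cc + 3].sum()
                assert chosen_overlap <= other


class TestApplyTranslation:
    def _placement(self, dr, dc, grid_shape=(8, 8)):
        from spvsim.dropout import Placement

        return Placement(0, 0, (dr, dc), 0, grid_shape)

    def test_zero_translation_is_identity(self, rng):
        img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        bbox = BoundingBox(4, 4, 8, 8)
        out, new = apply_translation(img, bbox, self._placement(0, 0))
        np.testing.assert_array_equal(out, img)
        assert new == bbox

    def test_pure_shift_moves_patch(self):
        img = np.zeros((32, 32), np.uint8)
        img[4:6, 10:12] = 255
        bbox = BoundingBox(4, 10, 2, 2)
        # grid 8x8 over 32px -> 4 px per cell; 3 cells down = 12 px
        out, new = apply_translation(img, bbox, self._placement(3, 0))
        assert new == BoundingBox(16, 10, 2, 2)
        assert (out[16:18, 10:12] == 255).all()
        assert out.sum() == 4 * 255

    def test_vacated_region_filled(self):
        img = np.full((16, 16), 200, np.uint8)
        bbox = BoundingBox(2, 2, 4, 4)
        out, _ = apply_translation(
            img, bbox, self._placement(2, 0, grid_shape=(16, 16)), fill=7
        )
        assert (out[2:4, 2:6] == 7).all()  # non-overlapping part of source

    def test_offframe_shift_clamps_to_border(self, caplog):
        img = np.zeros((32, 32), np.uint8)
        img[28:30, 28:30] = 9
        bbox = BoundingBox(28, 28, 2, 2)
        with caplog.at_level(logging.WARNING, logger="spvsim.dropout"):
            out, new = apply_translation(img, bbox, self._placement(4, 4))
        assert new == BoundingBox(30, 30, 2, 2)  # flush against the border
        assert (out[30:32, 30:32] == 9).all()
        assert any("clamped" in r.message for r in caplog.records)


def test_dropout_map_csv_round_trip(tmp_path):
    dmap = generate_dropout_map(12, 10, 0.2, seed=3)
    path = tmp_path / "dropout.csv"
    save_dropout_map(dmap, path)
    back = load_dropout_map(path, rate=0.2, seed=3)
    np.testing.assert_array_equal(back.grid, dmap.grid)
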