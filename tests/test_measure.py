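import numpy as np
import pytest

from colonyquant import (
    GridSpec,
    PipelineConfig,
    SynthSpec,
    generate_plate,
    measure_tile,
    measures_to_frame,
    quantify_plate,
    refine_tile,
    run_image,
    uniform_colonies,
)
from colonyquant.raster import TileBox, init_tiles, tile_slices


def tile(x, y, w=20, h=20, row=0, col=0):
    return TileBox(row=row, col=col, x=x, y=y, width=w, height=h)


class TestRefineTile:
    def make_mask(self, offset=(0, 0), size=20):
        """Plate-like lattice of colonies with 1-px tile clearance, translated.

        Every 20-px cell holds an 18x18 colony, as on a fully grown plate:
        only the true offset scores zero perimeter culture pixels (escaping
        to empty space is blocked by the neighbouring colonies), so recovery
        must be exact.
        """
        cell = np.zeros((size, size), dtype=bool)
        cell[1:-1, 1:-1] = True
        mask = np.tile(cell, (6, 6))
        dy, dx = offset
        return np.roll(mask, (dy, dx), axis=(0, 1))

    @pytest.mark.parametrize("offset", [(0, 0), (5, -3), (-9, 9), (9, -9), (-7, -7)])
    def test_exact_recovery_of_translation(self, offset):
        mask = self.make_mask(offset=offset)
        t = tile(40, 40)
        refined = refine_tile(t, mask, search=10)
        assert (refined.y - t.y, refined.x - t.x) == offset
        assert (refined.width, refined.height) == (t.width, t.height)

    def test_interior_colony_keeps_origin_by_tiebreak(self):
        # small colony well inside: many offsets score zero; (0,0) wins
        mask = np.zeros((120, 120), dtype=bool)
        mask[48:52, 48:52] = True
        refined = refine_tile(tile(40, 40), mask, search=3)
        assert (refined.x, refined.y) == (40, 40)

    def test_all_background_degenerate_tie(self):
        refined = refine_tile(tile(40, 40), np.zeros((120, 120), dtype=bool))
        assert (refined.x, refined.y) == (40, 40)

    def test_matches_naive_exhaustive_search(self, rng):
        # the prefix-sum implementation must agree with a literal recount
        mask = rng.uniform(size=(100, 100)) < 0.3
        t = tile(35, 42, w=18, h=16)
        refined = refine_tile(t, mask, search=6)

        def perim(x, y):
            ys, xs = slice(max(y, 0), y + 16), slice(max(x, 0), x + 18)
            sub = mask[ys, xs]
            if sub.size == 0:
                return 0
            edge = np.zeros_like(sub)
            edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
            return int((sub & edge).sum())

        best = min(
            ((perim(t.x + dx, t.y + dy), dx * dx + dy * dy, (dy, dx))
             for dy in range(-6, 6) for dx in range(-6, 6)),
        )
        assert (refined.y - t.y, refined.x - t.x) == best[2]


class TestMeasureTile:
    def test_block_arithmetic(self):
        # 10x10 culture block at corrected intensity 200 over i_med=100
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:20, 10:20] = True
        corrected = np.full((40, 40), 100.0)
        corrected[10:20, 10:20] = 200.0
        original = np.stack([corrected] * 3, axis=-1)
        grad = np.zeros((40, 40), dtype=bool)
        m = measure_tile(tile(5, 5, 30, 30), mask, corrected, original, grad, i_med=100.0)
        assert m.area == 100
        assert m.iod == pytest.approx(10_000.0)

    def test_empty_tile(self):
        z = np.zeros((40, 40))
        m = measure_tile(tile(0, 0), np.zeros((40, 40), dtype=bool),
                         z, np.zeros((40, 40, 3)), np.zeros((40, 40), dtype=bool), 100.0)
        assert m.area == 0
        assert m.iod == 0.0
        assert m.culture_rgb is None

    def test_uniform_culture_colour(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:10, 5:10] = True
        original = np.zeros((30, 30, 3))
        original[mask] = (30, 200, 40)
        m = measure_tile(tile(0, 0, 30, 30), mask, np.full((30, 30), 150.0),
                         original, np.zeros((30, 30), dtype=bool), 100.0)
        assert m.culture_rgb == pytest.approx((30, 200, 40))
        assert m.agar_rgb == pytest.approx((0, 0, 0))

    def test_iod_clamps_negative_excess_per_pixel(self):
        mask = np.ones((10, 10), dtype=bool)
        corrected = np.full((10, 10), 90.0)  # below the background median
        m = measure_tile(tile(0, 0, 10, 10), mask, corrected,
                         np.zeros((10, 10, 3)), np.zeros((10, 10), dtype=bool), 100.0)
        assert m.iod == 0.0
        assert m.tile_iod == 0.0

    def test_granularity_counts_gradient_pixels(self):
        grad = np.zeros((20, 20), dtype=bool)
        grad[3:6, 3:6] = True
        m = measure_tile(tile(0, 0), np.zeros((20, 20), dtype=bool),
                         np.zeros((20, 20)), np.zeros((20, 20, 3)), grad, 0.0)
        assert m.granularity == 9


class TestQuantifyPlate:
    def test_record_order_and_edge_flags(self, small_grid):
        shape = (220, 300)
        tiles = init_tiles(small_grid)
        mask = np.zeros(shape, dtype=bool)
        out = quantify_plate(tiles, mask, np.zeros(shape), np.zeros(shape + (3,)),
                             np.zeros(shape, dtype=bool), 0.0, small_grid)
        assert [(m.row, m.col) for m in out] == [(r, c) for r in range(4) for c in range(6)]
        assert out[0].edge and out[-1].edge
        inner = [m for m in out if 0 < m.row < 3 and 0 < m.col < 5]
        assert not any(m.edge for m in inner)

    def test_area_equals_mask_count_in_refined_tile(self, faint_gradient_plate):
        spec, img, truth = faint_gradient_plate
        frame, diag = run_image(img, spec.grid, PipelineConfig(seed=1))
        mask = diag["mask"]
        for _, rec in frame.iloc[::7].iterrows():
            t = tile(int(rec.x), int(rec.y), int(rec.width), int(rec.height))
            ys, xs = tile_slices(t, mask.shape)
            assert rec.area == int(mask[ys, xs].sum())

    def test_total_area_tracks_ground_truth(self, small_grid):
        # hard-bounded (pinned-style) colonies: segmented and true footprints
        # agree closely; soft spotted boundaries are covered by the IOD tests
        spec = SynthSpec(
            grid=small_grid,
            colonies=uniform_colonies(small_grid, density=0.8, radius=10, edge_width=0.5),
            noise_sigma=2.0, seed=9,
        )
        img, truth = generate_plate(spec)
        frame, _ = run_image(img, small_grid, PipelineConfig(seed=1))
        assert frame["area"].sum() == pytest.approx(truth.true_area.sum(), rel=0.10)

    def test_pinned_disc_areas_within_five_percent(self, small_grid):
        spec = SynthSpec(
            grid=small_grid,
            colonies=uniform_colonies(small_grid, density=1.0, radius=10, edge_width=0.35),
            noise_sigma=2.0, seed=9,
        )
        img, truth = generate_plate(spec)
        frame, _ = run_image(img, small_grid, PipelineConfig(seed=1))
        areas = frame.sort_values(["row", "col"])["area"].to_numpy()
        rel = np.abs(areas - truth.true_area) / truth.true_area
        assert rel.max() < 0.05

    def test_iod_strictly_increases_with_density(self, small_grid):
        # 24 positions spanning 8 density levels, 3 replicates per level
        from dataclasses import replace

        levels = np.repeat(np.linspace(0.1, 0.9, 8), 3)
        colonies = tuple(
            replace(c, density=float(d))
            for c, d in zip(uniform_colonies(small_grid, radius=10), levels)
        )
        spec = SynthSpec(grid=small_grid, colonies=colonies, noise_sigma=1.5, seed=13)
        img, _ = generate_plate(spec)
        frame, _ = run_image(img, small_grid, PipelineConfig(seed=1))
        mean_iod = frame["iod"].groupby(np.arange(24) // 3).mean().to_numpy()
        assert (np.diff(mean_iod) > 0).all()


class TestOutputTable:
    def test_frame_layout_and_na(self):
        from colonyquant.measure import COLUMNS, CultureMeasures

        m = CultureMeasures(row=0, col=0, x=1, y=2, width=3, height=4, area=0,
                            iod=0.0, tile_iod=0.0, granularity=0,
                            culture_rgb=None, agar_rgb=(1.0, 2.0, 3.0), edge=True)
        frame = measures_to_frame([m], "img1")
        assert list(frame.columns) == COLUMNS
        assert np.isnan(frame.loc[0, "r_culture"])
        assert frame.loc[0, "edge_flag"] == 1
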