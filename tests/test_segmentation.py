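"""Region growing against a BFS oracle, the majority fill rule, pipeline."""

from collections import deque

import numpy as np
import pytest

from ctaseg import (
    GrowConfig,
    GrowthOverflowError,
    SeedingError,
    SeedPoint,
    Volume,
    fill_cavities_2d,
    region_grow,
    segment_pipeline,
)
from ctaseg.phantoms import get_case, render
from ctaseg.volume_io import BinaryMask


def bfs_flood_fill(binary: np.ndarray, seed: tuple, connectivity: int) -> np.ndarray:
    """Literal breadth-first flood fill; the independent oracle."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                order = abs(dz) + abs(dy) + abs(dx)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    out = np.zeros_like(binary, dtype=np.uint8)
    if not binary[seed]:
        return out
    shape = binary.shape
    out[seed] = 1
    queue = deque([seed])
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2] \
                    and binary[nz, ny, nx] and not out[nz, ny, nx]:
                out[nz, ny, nx] = 1
                queue.append((nz, ny, nx))
    return out


def synchronous_fill_oracle(slice_2d: np.ndarray) -> np.ndarray:
    """Literal per-pixel synchronous iteration of the >= 4-of-8 rule."""
    current = slice_2d.astype(np.uint8).copy()
    h, w = current.shape
    while True:
        nxt = current.copy()
        for i in range(h):
            for j in range(w):
                if current[i, j]:
                    continue
                count = 0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == 0 and dj == 0:
                            continue
                        ni, nj = i + di, j + dj
                        if 0 <= ni < h and 0 <= nj < w and current[ni, nj]:
                            count += 1
                if count >= 4:
                    nxt[i, j] = 1
        if np.array_equal(nxt, current):
            return current
        current = nxt


class TestRegionGrow:
    def test_straight_tube_recovered_exactly(self):
        v = np.zeros((10, 12, 12))
        v[:, 5, 5] = 1.0
        mask = region_grow(v, (0, 5, 5), GrowConfig(threshold=0.5))
        expected = (v >= 0.5).astype(np.uint8)
        assert np.array_equal(mask.data, expected)

    def test_only_seeded_component_grows(self):
        v = np.zeros((10, 12, 12))
        v[:, 3, 3] = 1.0
        v[:, 9, 9] = 1.0
        mask = region_grow(v, (0, 3, 3), GrowConfig(threshold=0.5))
        assert mask.data[:, 3, 3].all()
        assert not mask.data[:, 9, 9].any()

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_bfs_oracle_on_random_fields(self, connectivity):
        rng = np.random.default_rng(connectivity)
        for _ in range(10):
            binary = (rng.random((20, 20, 20)) < 0.3)
            foreground = np.argwhere(binary)
            seed = tuple(foreground[rng.integers(len(foreground))])
            grown = region_grow(binary.astype(float), seed,
                                GrowConfig(threshold=0.5, connectivity=connectivity,
                                           max_voxels=20 ** 3))
            oracle = bfs_flood_fill(binary, seed, connectivity)
            assert np.array_equal(grown.data, oracle)

    def test_seed_below_threshold_raises_without_forcing(self):
        v = np.zeros((5, 5, 5))
        with pytest.raises(SeedingError):
            region_grow(v, (2, 2, 2), GrowConfig(threshold=0.5, force_seed=False))

    def test_growth_cap_raises_overflow(self):
        v = np.ones((10, 10, 10))
        with pytest.raises(GrowthOverflowError):
            region_grow(v, (5, 5, 5), GrowConfig(threshold=0.5, max_voxels=10))

    def test_out_of_bounds_seed_rejected(self):
        with pytest.raises(ValueError):
            region_grow(np.zeros((4, 4, 4)), (5, 0, 0))

    def test_result_is_single_component_subset_of_threshold_set(self):
        from scipy import ndimage

        rng = np.random.default_rng(77)
        v = rng.random((16, 16, 16))
        seeds = np.argwhere(v >= 0.6)
        seed = tuple(seeds[0])
        mask = region_grow(v, seed, GrowConfig(threshold=0.6, max_voxels=16 ** 3))
        assert mask.data[seed] == 1
        above = v >= 0.6
        assert not mask.data[~above].any()
        structure = ndimage.generate_binary_structure(3, 3)
        _, n = ndimage.label(mask.data, structure=structure)
        assert n == 1


class TestCavityFill:
    def make_mask(self, slice_2d):
        return BinaryMask(np.asarray(slice_2d, dtype=np.uint8)[np.newaxis])

    def test_pixel_with_four_neighbours_fills_in_one_pass(self):
        sl = np.zeros((5, 5), dtype=np.uint8)
        sl[1, 1] = sl[1, 3] = sl[3, 1] = sl[3, 3] = 1  # 4 diagonal neighbours of (2,2)
        filled = fill_cavities_2d(self.make_mask(sl))
        assert filled.data[0, 2, 2] == 1

    def test_pixel_with_three_neighbours_stays_background(self):
        sl = np.zeros((5, 5), dtype=np.uint8)
        sl[1, 1] = sl[1, 3] = sl[3, 1] = 1
        filled = fill_cavities_2d(self.make_mask(sl))
        assert filled.data[0, 2, 2] == 0

    def test_square_with_central_hole_fills_completely(self):
        sl = np.ones((9, 9), dtype=np.uint8)
        sl[3:6, 3:6] = 0
        filled = fill_cavities_2d(self.make_mask(sl))
        assert filled.data.all()

    def test_all_background_slice_unchanged(self):
        filled = fill_cavities_2d(self.make_mask(np.zeros((8, 8))))
        assert not filled.data.any()

    def test_fill_is_monotone_and_idempotent(self):
        rng = np.random.default_rng(12)
        mask = BinaryMask((rng.random((4, 32, 32)) < 0.45).astype(np.uint8))
        once = fill_cavities_2d(mask)
        assert (once.data >= mask.data).all()
        twice = fill_cavities_2d(once)
        assert np.array_equal(twice.data, once.data)

    def test_matches_synchronous_per_pixel_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            sl = (rng.random((32, 32)) < 0.45)
            filled = fill_cavities_2d(self.make_mask(sl))
            oracle = synchronous_fill_oracle(sl)
            assert np.array_equal(filled.data[0], oracle)

    def test_slices_are_filled_independently(self):
        # a cavity enclosed in-slice fills; the same pattern spread across
        # slices (so no slice encloses it) does not
        enclosed = np.ones((1, 7, 7), dtype=np.uint8)
        enclosed[0, 3, 3] = 0
        assert fill_cavities_2d(BinaryMask(enclosed)).data.all()
        stacked = np.zeros((3, 7, 7), dtype=np.uint8)
        stacked[0] = stacked[2] = 1
        stacked[1, 3, :] = 1
        stacked[1, 3, 3] = 0
        filled = fill_cavities_2d(BinaryMask(stacked))
        assert filled.data[1, 3, 3] == 0


class TestPipeline:
    def test_hollow_tube_cavities_repaired(self, hollow_run):
        truth = hollow_run["truth"]
        result = hollow_run["result"]
        spec = hollow_run["case"].spec
        hole = spec.holes[0]
        zz, yy, xx = np.mgrid[0:spec.shape[0], 0:spec.shape[1], 0:spec.shape[2]]
        lumen = (((yy - hole.center[1]) ** 2 + (xx - hole.center[2]) ** 2)
                 <= hole.radius ** 2) & (zz >= hole.z_range[0]) & (zz <= hole.z_range[1])
        # interior ring of the lumen is truth but invisible pre-fill
        assert result.mask.data[lumen].all()
        assert not result.prefill_mask.data[lumen].any()
        assert truth.data[lumen].all()

    def test_discrimination_phantom_segments_tube_not_distractors(
            self, discrimination_vesselness):
        case = discrimination_vesselness["case"]
        truth = discrimination_vesselness["truth"]
        vmap = discrimination_vesselness["vmap"]
        mask = region_grow(vmap, case.seed, case.grow)
        final = fill_cavities_2d(mask)
        tube_voxels = truth.data == 1
        assert final.data[tube_voxels].mean() >= 0.9
        spec = case.spec
        blob, plate = spec.primitives[1], spec.primitives[2]
        zz, yy, xx = np.mgrid[0:spec.shape[0], 0:spec.shape[1], 0:spec.shape[2]]
        blob_vox = (((zz - blob.center[0]) / blob.radii[0]) ** 2
                    + ((yy - blob.center[1]) / blob.radii[1]) ** 2
                    + ((xx - blob.center[2]) / blob.radii[2]) ** 2) <= 1
        assert final.data[blob_vox].mean() <= 0.1

    def test_constant_volume_cannot_be_seeded(self):
        vol = Volume(np.zeros((8, 32, 32)))
        with pytest.raises(SeedingError):
            segment_pipeline(vol)

    def test_manual_seed_bypasses_detection(self):
        case = get_case("single_tube_snrinf")
        volume, truth = render(case.spec)
        result = segment_pipeline(volume, params=case.params, grow=case.grow,
                                  seed=(20, 32, 32))
        assert result.seed == SeedPoint(voxel=(20, 32, 32), label="aorta")
        assert result.mask.data[20, 32, 32] == 1
        # the tube is recovered generously but not the empty background corner
        assert result.mask.data[:, 32, 32].all()
        assert not result.mask.data[:, :8, :8].any()
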