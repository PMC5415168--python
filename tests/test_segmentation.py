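"""Segmentation stages against brute-force oracles and hand-derived values."""

import numpy as np
import pytest

from rootone import (
    BinaryVolume,
    DegenerateDistributionError,
    SeedError,
    SegmentationParams,
    Volume,
    bilevel_threshold,
    bin_max,
    erode3d,
    extract_connected,
    isodata_threshold,
    median3d,
    pve_mask,
    sobel_edges2d,
    upsample2x,
)
from rootone.segmentation import PveMask

from .conftest import make_binary


def params_with(lo, hi, seed=(0, 0, 0), **kw):
    return SegmentationParams(root_grey_lo=lo, root_grey_hi=hi, seed_voxel=seed, **kw)


# ---------------------------------------------------------------- oracles
def majority_vote_oracle(data):
    """27-neighbourhood majority with edge replication, one voxel at a time."""
    padded = np.pad(data.astype(np.int8), 1, mode="edge")
    out = np.zeros_like(data, dtype=bool)
    for z in range(data.shape[0]):
        for y in range(data.shape[1]):
            for x in range(data.shape[2]):
                out[z, y, x] = padded[z:z + 3, y:y + 3, x:x + 3].sum() >= 14
    return out


def erosion_oracle(data, structure_offsets):
    """Erosion keeping voxels whose in-bounds structure neighbours are all fg."""
    out = np.zeros_like(data, dtype=bool)
    dims = data.shape
    for z, y, x in np.argwhere(data):
        keep = True
        for dz, dy, dx in structure_offsets:
            n = (z + dz, y + dy, x + dx)
            if all(0 <= c < d for c, d in zip(n, dims)) and not data[n]:
                keep = False
                break
        out[z, y, x] = keep
    return out


def flood_fill_oracle(data, seed):
    """26-connected BFS flood fill."""
    from collections import deque

    out = np.zeros_like(data, dtype=bool)
    out[seed] = True
    queue = deque([seed])
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            n = (z + dz, y + dy, x + dx)
            if all(0 <= c < d for c, d in zip(n, data.shape)):
                if data[n] and not out[n]:
                    out[n] = True
                    queue.append(n)
    return out


# ---------------------------------------------------------------- upsample
class TestUpsample2x:
    def test_dimensions_double_voxel_count_times_eight(self, rng):
        vol = Volume(rng.integers(0, 100, (10, 20, 30), dtype=np.uint16), 65.0)
        up = upsample2x(vol)
        assert up.shape == (20, 40, 60)
        assert np.prod(up.shape) == 8 * np.prod(vol.shape)
        assert up.voxel_size_um == pytest.approx(32.5)

    def test_constant_stays_constant(self):
        up = upsample2x(Volume(np.full((3, 3, 3), 42, dtype=np.uint16), 1.0))
        assert np.all(up.data == 42.0)

    def test_ramp_midpoints_present(self):
        ramp = Volume(np.arange(0, 8, 2, dtype=np.float32).reshape(1, 1, 4), 1.0)
        up = upsample2x(ramp)
        row = up.data[0, 0]
        for v in (1.0, 3.0, 5.0):
            assert v in row


# ---------------------------------------------------------------- sobel
class TestSobel2d:
    def test_constant_slice_has_zero_gradient(self):
        g = sobel_edges2d(Volume(np.full((2, 6, 6), 9, dtype=np.uint16), 1.0))
        assert np.all(g.data == 0)

    def test_step_edge_magnitude_is_4h(self):
        h = 7.0
        sl = np.zeros((1, 8, 8), dtype=np.float32)
        sl[:, :, 4:] = h
        g = sobel_edges2d(Volume(sl, 1.0))
        assert g.data[0, 4, 3] == pytest.approx(4 * h)
        assert g.data[0, 4, 4] == pytest.approx(4 * h)

    def test_ramp_magnitude_is_8s(self):
        s = 3.0
        sl = np.tile(np.arange(8, dtype=np.float32) * s, (8, 1))[None]
        g = sobel_edges2d(Volume(sl, 1.0))
        assert g.data[0, 4, 4] == pytest.approx(8 * s)

    def test_slices_are_independent(self, rng):
        """2-D filter: a slice's gradient ignores neighbouring slices."""
        a = rng.normal(size=(1, 8, 8)).astype(np.float32)
        stacked = np.concatenate([a, 100 * rng.normal(size=(1, 8, 8)).astype(np.float32)])
        g1 = sobel_edges2d(Volume(a, 1.0)).data[0]
        g2 = sobel_edges2d(Volume(stacked, 1.0)).data[0]
        assert np.allclose(g1, g2)


# ---------------------------------------------------------------- isodata
class TestIsodata:
    def test_two_cluster_fixed_point(self):
        values = np.array([0.0] * 900 + [100.0] * 100)
        assert isodata_threshold(values) == pytest.approx(50.0)

    def test_symmetric_two_point_distribution(self):
        values = np.array([10.0, 30.0] * 50)
        assert isodata_threshold(values) == pytest.approx(20.0)

    def test_constant_input_errors(self):
        with pytest.raises(DegenerateDistributionError):
            isodata_threshold(np.full(10, 5.0))

    def test_fixed_point_property_vs_brute_force(self, rng):
        """The returned T satisfies the intermeans equation at least as well
        as any candidate from a dense scan."""
        values = np.concatenate(
            [rng.normal(20, 4, 500), rng.normal(60, 8, 300)]
        )
        t = isodata_threshold(values)
        residual = abs(t - 0.5 * (values[values <= t].mean() + values[values > t].mean()))
        assert residual < 0.5
        candidates = np.linspace(values.min() + 1e-6, values.max() - 1e-6, 2000)
        best = min(
            abs(c - 0.5 * (values[values <= c].mean() + values[values > c].mean()))
            for c in candidates
        )
        assert residual <= best + 0.5


# ---------------------------------------------------------------- pve mask
class TestPveMask:
    def test_zero_gradient_gives_empty_mask(self):
        mask = pve_mask(Volume(np.zeros((2, 4, 4), dtype=np.float32), 1.0))
        assert not mask.data.any()

    def test_mask_count_matches_brute_force(self, rng):
        g = Volume(np.abs(rng.normal(0, 10, (4, 8, 8))).astype(np.float32), 1.0)
        mask = pve_mask(g)
        assert mask.data.sum() == (g.data > mask.threshold_used).sum()

    def test_sharp_edges_masked_subtle_edges_kept(self):
        """Air:soil contrast is masked; the subtler root:soil contrast is not."""
        sl = np.full((1, 9, 30), 30000.0, dtype=np.float32)
        sl[:, :, 0:6] = 5000.0    # air pocket: sharp boundary at x=6
        sl[:, :, 20:24] = 22000.0  # root: subtle boundary
        g = sobel_edges2d(Volume(sl, 1.0))
        mask = pve_mask(g)
        assert mask.data[0, 4, 6]        # air:soil boundary masked
        assert not mask.data[0, 4, 20]   # root:soil boundary kept


# ---------------------------------------------------------------- bilevel
class TestBilevelThreshold:
    def test_bounds_inclusive_and_mask_wins(self):
        vol = Volume(
            np.array([[[10, 20, 30, 20]]], dtype=np.uint16), 1.0
        )
        mask = PveMask(np.array([[[False, False, False, True]]]), 0.0)
        out = bilevel_threshold(vol, params_with(20, 30), mask)
        assert list(out.data.ravel()) == [False, True, True, False]

    def test_foreground_count_matches_brute_force(self, rng):
        vol = Volume(rng.integers(0, 100, (6, 8, 8), dtype=np.uint16), 1.0)
        mask = PveMask(rng.random((6, 8, 8)) < 0.2, 0.0)
        out = bilevel_threshold(vol, params_with(30, 60), mask)
        expected = sum(
            30 <= v <= 60 and not m
            for v, m in zip(vol.data.ravel(), mask.data.ravel())
        )
        assert out.foreground_count() == expected


# ---------------------------------------------------------------- median
class TestMedian3d:
    def test_isolated_voxel_removed(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        assert not median3d(make_binary(data)).data.any()

    def test_solid_cube_interior_preserved(self):
        data = np.zeros((7, 7, 7), dtype=bool)
        data[1:6, 1:6, 1:6] = True
        out = median3d(make_binary(data))
        assert out.data[2:5, 2:5, 2:5].all()

    def test_matches_majority_oracle_on_random_volumes(self, rng):
        for density in (0.2, 0.5, 0.8):
            data = rng.random((12, 12, 12)) < density
            out = median3d(make_binary(data))
            assert np.array_equal(out.data, majority_vote_oracle(data))


# ---------------------------------------------------------------- erosion
CROSS_OFFSETS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


class TestErode3d:
    def test_zero_iterations_is_identity(self, rng):
        data = rng.random((6, 6, 6)) < 0.5
        out = erode3d(make_binary(data), iterations=0)
        assert np.array_equal(out.data, data)

    def test_thin_filament_removed_in_one_iteration(self):
        data = np.zeros((10, 5, 5), dtype=bool)
        data[:, 2, 2] = True
        assert not erode3d(make_binary(data), 1).data.any()

    def test_ball_erosion_matches_oracle(self, rng):
        zz, yy, xx = np.mgrid[0:15, 0:15, 0:15]
        ball = (zz - 7) ** 2 + (yy - 7) ** 2 + (xx - 7) ** 2 <= 25
        out = erode3d(make_binary(ball), 1)
        assert np.array_equal(out.data, erosion_oracle(ball, CROSS_OFFSETS))

    def test_random_volumes_match_oracle(self, rng):
        for _ in range(3):
            data = rng.random((10, 10, 10)) < 0.6
            out = erode3d(make_binary(data), 1)
            assert np.array_equal(out.data, erosion_oracle(data, CROSS_OFFSETS))


# ---------------------------------------------------------------- extraction
class TestExtractConnected:
    def test_keeps_only_seeded_blob(self):
        data = np.zeros((6, 6, 6), dtype=bool)
        data[0:2, 0:2, 0:2] = True
        data[4:6, 4:6, 4:6] = True
        out = extract_connected(make_binary(data), (0, 0, 0))
        assert out.data[:2, :2, :2].all() and not out.data[4:, 4:, 4:].any()

    def test_background_seed_errors_with_suggestion(self):
        data = np.zeros((4, 4, 4), dtype=bool)
        data[3, 3, 3] = True
        with pytest.raises(SeedError) as exc:
            extract_connected(make_binary(data), (0, 0, 0))
        assert exc.value.nearest_foreground == (3, 3, 3)

    def test_corner_touching_voxels_retained(self):
        data = np.zeros((4, 4, 4), dtype=bool)
        data[0, 0, 0] = data[1, 1, 1] = data[2, 2, 2] = True
        out = extract_connected(make_binary(data), (0, 0, 0))
        assert out.data.sum() == 3

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(3):
            data = rng.random((10, 10, 10)) < 0.3
            seeds = np.argwhere(data)
            seed = tuple(seeds[0])
            out = extract_connected(make_binary(data), seed)
            assert np.array_equal(out.data, flood_fill_oracle(data, seed))

    def test_output_is_single_component_subset(self, rng):
        from scipy import ndimage

        data = rng.random((10, 10, 10)) < 0.3
        seed = tuple(np.argwhere(data)[0])
        out = extract_connected(make_binary(data), seed)
        assert not (out.data & ~data).any()
        _, n = ndimage.label(out.data, structure=np.ones((3, 3, 3)))
        assert n == 1


# ---------------------------------------------------------------- bin_max
class TestBinMax:
    def test_single_foreground_voxel_survives(self):
        data = np.zeros((4, 4, 4), dtype=bool)
        data[1, 0, 3] = True
        out = bin_max(make_binary(data, voxel_size_um=13.5))
        assert out.shape == (2, 2, 2)
        assert out.data[0, 0, 1] and out.data.sum() == 1
        assert out.voxel_size_um == pytest.approx(27.0)

    def test_all_background_block_stays_background(self):
        out = bin_max(make_binary(np.zeros((4, 4, 4), dtype=bool)))
        assert not out.data.any()

    def test_upsample_then_bin_is_superset(self, rng):
        """Doubling then max re-binning can only grow binary foreground."""
        data = rng.random((6, 6, 6)) < 0.3
        vol = Volume(data.astype(np.float32), 1.0)
        up = upsample2x(vol)
        binary_up = BinaryVolume(up.data >= 0.999, up.voxel_size_um)
        back = bin_max(binary_up)
        assert np.all(back.data[data])


# ---------------------------------------------------------------- invariants
class TestStageInvariants:
    def test_empty_foreground_stays_empty(self):
        empty = make_binary(np.zeros((6, 6, 6), dtype=bool))
        assert not median3d(empty).data.any()
        assert not erode3d(empty, 2).data.any()
        assert not bin_max(empty).data.any()

    def test_filters_never_create_foreground_in_empty_neighbourhoods(self, rng):
        data = rng.random((10, 10, 10)) < 0.4
        padded = np.pad(data, 1, mode="edge")
        windows = np.zeros_like(data)
        for z in range(10):
            for y in range(10):
                for x in range(10):
                    windows[z, y, x] = padded[z:z + 3, y:y + 3, x:x + 3].any()
        med = median3d(make_binary(data)).data
        ero = erode3d(make_binary(data), 1).data
        assert not (med & ~windows).any()
        assert not (ero & ~windows).any()
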