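"""DVC engine: grid layout, correlation, multipass, region masking."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import dvcstrain as ds
from dvcstrain.dvc import zncc_map, zncc_map_direct


def brute_force_zncc(search: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Spatial-domain ZNCC oracle, written independently of the FFT path."""
    out_shape = tuple(s - t + 1 for s, t in zip(search.shape, template.shape))
    out = np.zeros(out_shape)
    t = template - template.mean()
    t_norm = np.sqrt(np.sum(t * t))
    for i in range(out_shape[0]):
        for j in range(out_shape[1]):
            for k in range(out_shape[2]):
                w = search[
                    i : i + template.shape[0],
                    j : j + template.shape[1],
                    k : k + template.shape[2],
                ]
                w = w - w.mean()
                w_norm = np.sqrt(np.sum(w * w))
                denom = t_norm * w_norm
                out[i, j, k] = np.sum(w * t) / denom if denom > 0 else 0.0
    return out


class TestBuildGrid:
    def test_integer_tiling_without_overlap(self):
        grid = ds.build_grid((96, 96, 96), 48, 0.0)
        assert grid.n_nodes == (2, 2, 2)

    def test_half_overlap_tiling(self):
        # spacing 24, nodes per axis = (96 - 48) // 24 + 1 = 3
        grid = ds.build_grid((96, 96, 96), 48, 0.5)
        assert grid.n_nodes == (3, 3, 3)
        assert grid.spacing == 24

    def test_size_equal_to_image_gives_single_central_node(self):
        grid = ds.build_grid((64, 64, 64), 64, 0.0)
        assert grid.n_nodes == (1, 1, 1)
        np.testing.assert_allclose(grid.node_centers()[0], [31.5, 31.5, 31.5])

    def test_oversized_subvolume_rejected(self):
        with pytest.raises(ValueError):
            ds.build_grid((32, 32, 32), 64, 0.0)

    @given(
        dim=st.integers(min_value=32, max_value=200),
        size=st.integers(min_value=8, max_value=32),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    def test_every_subvolume_fits_and_layout_is_centered(self, dim, size, overlap):
        grid = ds.build_grid((dim, dim, dim), size, overlap)
        for ax in range(3):
            starts = grid.starts[ax]
            assert starts[0] >= 0
            assert starts[-1] + size <= dim
            # symmetric about the image center: margins agree within rounding
            assert abs(starts[0] - (dim - (starts[-1] + size))) <= 1
            if len(starts) > 1:
                assert np.all(np.diff(starts) == grid.spacing)


class TestCorrelatePass:
    def test_identical_volumes_give_zero_field_and_unit_cc(self, speckle):
        vol, _ = speckle
        grid = ds.build_grid(vol.shape, 32, 0.0)
        f = ds.correlate_pass(vol, vol, grid, search_radius=5)
        assert f.n_valid == np.prod(f.grid.n_nodes)
        assert np.all(f.u[f.valid] == 0.0)
        np.testing.assert_allclose(f.cc[f.valid], 1.0, atol=1e-9)

    def test_integer_circular_shift_recovered_exactly(self, speckle):
        vol, _ = speckle
        shift = (3, -2, 5)
        dfm = ds.Volume(np.roll(vol.data, shift, axis=(0, 1, 2)), vol.voxel_size)
        grid = ds.build_grid(vol.shape, 32, 0.0)
        f = ds.correlate_pass(vol, dfm, grid, search_radius=8)
        # interior nodes (away from the wrap-around seam)
        inner = f.u[1:-1, 1:-1, 1:-1][f.valid[1:-1, 1:-1, 1:-1]]
        assert inner.size > 0
        np.testing.assert_array_equal(inner, np.broadcast_to(shift, inner.shape))

    def test_subvoxel_lanczos_shift_recovered_within_005(self, speckle):
        vol, _ = speckle
        dfm = ds.translate(vol, (0.0, 0.0, 0.3))
        # crop a central VOI so windows stay clear of the resampling boundary
        ref_c = ds.crop_voi(vol, 80)
        dfm_c = ds.crop_voi(dfm, 80)
        grid = ds.build_grid(ref_c.shape, 32, 0.0)
        f = ds.correlate_pass(ref_c, dfm_c, grid, search_radius=5)
        uz = f.u[f.valid][:, 2]
        assert f.n_valid > 0
        assert abs(uz.mean() - 0.3) < 0.05

    def test_translation_invariance_under_added_integer_shift(self, speckle):
        vol, _ = speckle
        base = ds.translate(vol, (0.0, 0.0, 0.3))
        shifted = ds.Volume(np.roll(base.data, (1, 2, 3), axis=(0, 1, 2)),
                            vol.voxel_size, np.roll(base.invalid, (1, 2, 3), axis=(0, 1, 2)))
        grid = ds.build_grid(vol.shape, 32, 0.0)
        f0 = ds.correlate_pass(vol, base, grid, search_radius=6)
        f1 = ds.correlate_pass(vol, shifted, grid, search_radius=6)
        both = f0.valid[1:-1, 1:-1, 1:-1] & f1.valid[1:-1, 1:-1, 1:-1]
        d = (f1.u - f0.u)[1:-1, 1:-1, 1:-1][both]
        np.testing.assert_allclose(d, np.broadcast_to((1, 2, 3), d.shape), atol=0.02)

    def test_flat_template_flagged_invalid_not_raised(self):
        vol = ds.Volume(np.zeros((48, 48, 48)))
        grid = ds.build_grid(vol.shape, 16, 0.0)
        f = ds.correlate_pass(vol, vol, grid, search_radius=4)
        assert f.n_valid == 0
        assert np.all(np.isnan(f.u))

    def test_fft_and_direct_match_brute_force_oracle(self, rng):
        search = rng.normal(size=(20, 18, 22))
        template = rng.normal(size=(8, 8, 8))
        slow = brute_force_zncc(search, template)
        for fast in (zncc_map(search, template), zncc_map_direct(search, template)):
            assert np.unravel_index(np.argmax(fast), fast.shape) == np.unravel_index(
                np.argmax(slow), slow.shape
            )
            np.testing.assert_allclose(fast, slow, atol=1e-10)


class TestMultipass:
    def test_single_size_on_identical_volumes_is_zero(self, speckle):
        vol, _ = speckle
        f = ds.run_multipass(vol, vol, [48])
        assert f.n_valid > 0
        assert np.all(f.u[f.valid] == 0.0)

    def test_descending_order_enforced(self, speckle):
        vol, _ = speckle
        with pytest.raises(ValueError):
            ds.run_multipass(vol, vol, [48, 56])
        with pytest.raises(ValueError):
            ds.run_multipass(vol, vol, [])

    def test_multipass_keeps_at_least_single_pass_valid_count(self, speckle):
        vol, _ = speckle
        noisy1 = ds.add_noise(vol, 6.0, seed=11)
        noisy2 = ds.add_noise(ds.translate(vol, (0, 0, 2.0)), 6.0, seed=12)
        multi = ds.run_multipass(noisy1, noisy2, [64, 48], final_overlap=0.5)
        grid = ds.build_grid(vol.shape, 48, 0.5)
        single = ds.correlate_pass(noisy1, noisy2, grid, search_radius=4)
        inner_m = multi.valid[1:-1, 1:-1, 1:-1].sum()
        inner_s = single.valid[1:-1, 1:-1, 1:-1].sum()
        assert inner_m >= inner_s


class TestMaskByRegion:
    def test_uniform_label_map_keeps_field(self, speckle):
        vol, _ = speckle
        labels = ds.RegionLabelMap(
            np.full(vol.shape, ds.CARTILAGE, dtype=np.uint8), vol.voxel_size
        )
        grid = ds.build_grid(vol.shape, 32, 0.0)
        f = ds.correlate_pass(vol, vol, grid, search_radius=4)
        masked = ds.mask_by_region(f, labels, ds.CARTILAGE)
        assert masked.n_valid == f.n_valid

    def test_interface_straddling_nodes_excluded_from_both_regions(self, flat_slab):
        vol, labels = flat_slab  # 64^3, interface at z = 32
        grid = ds.build_grid(vol.shape, 32, 0.0)  # windows z: [0,32) and [32,64)
        f = ds.DisplacementField(
            grid,
            np.zeros(grid.n_nodes + (3,)),
            np.ones(grid.n_nodes),
            np.ones(grid.n_nodes, dtype=bool),
        )
        cart = ds.mask_by_region(f, labels, ds.CARTILAGE)
        mino = ds.mask_by_region(f, labels, ds.MINERALIZED)
        # z-layer 0 lies fully in cartilage, layer 1 fully in mineralized
        assert cart.valid[:, :, 0].all() and not cart.valid[:, :, 1].any()
        assert mino.valid[:, :, 1].all() and not mino.valid[:, :, 0].any()
        # a grid offset so windows straddle the interface excludes everywhere
        grid2 = ds.build_grid(vol.shape, 48, 0.0)  # single window z [8, 56)
        f2 = ds.DisplacementField(
            grid2,
            np.zeros(grid2.n_nodes + (3,)),
            np.ones(grid2.n_nodes),
            np.ones(grid2.n_nodes, dtype=bool),
        )
        assert ds.mask_by_region(f2, labels, ds.CARTILAGE).n_valid == 0
        assert ds.mask_by_region(f2, labels, ds.MINERALIZED).n_valid == 0

    def test_half_slab_valid_counts_match_geometry_oracle(self, flat_slab):
        vol, labels = flat_slab
        grid = ds.build_grid(vol.shape, 16, 0.0)  # 4 windows per axis, interface z=32
        nn = grid.n_nodes
        f = ds.DisplacementField(
            grid, np.zeros(nn + (3,)), np.ones(nn), np.ones(nn, dtype=bool)
        )
        cart = ds.mask_by_region(f, labels, ds.CARTILAGE)
        # windows with z-extent below 32: z-layers 0 and 1 -> 4*4*2 nodes
        assert cart.n_valid == 4 * 4 * 2

    def test_unknown_label_rejected(self, flat_slab):
        vol, labels = flat_slab
        grid = ds.build_grid(vol.shape, 32, 0.0)
        nn = grid.n_nodes
        f = ds.DisplacementField(
            grid, np.zeros(nn + (3,)), np.ones(nn), np.ones(nn, dtype=bool)
        )
        with pytest.raises(ValueError, match="unknown region"):
            ds.mask_by_region(f, labels, 7)
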