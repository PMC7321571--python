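"""Zero-strain and synthetic-deformation error protocols (MAER/SDER)."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import dvcstrain as ds


@pytest.fixture(scope="module")
def textured_pair():
    """Noiseless 96^3 phantom plus label map for protocol tests."""
    spec = ds.PhantomSpec(
        shape=(96, 96, 96),
        lacunae_density_per_region=(25_000.0, 40_000.0),
        noise_sd=0.0,
        seed=13,
    )
    return ds.generate_phantom(spec)


class TestZeroStrainTest:
    def test_identical_noiseless_volumes_have_exactly_zero_error(self, textured_pair):
        vol, labels = textured_pair
        report = ds.zero_strain_test(vol, vol, labels, sizes=(16, 32), overlap=0.0)
        assert report.entries  # at least one (region, size) reported
        for e in report.entries.values():
            assert e["maer"] == 0.0
            assert e["sder"] == 0.0

    def test_report_covers_every_requested_region_size_combination(self, textured_pair):
        vol, labels = textured_pair
        sizes = (16, 32)
        report = ds.zero_strain_test(vol, vol, labels, sizes=sizes, overlap=0.0)
        seen = set(report.entries) | set(report.absent)
        assert seen == {(r, s) for r in (1, 2) for s in sizes}

    def test_region_with_no_interior_subvolume_flagged_absent(self, textured_pair):
        vol, labels = textured_pair
        # size 64 windows cannot fit inside either 48-voxel-thick region of 96^3
        report = ds.zero_strain_test(vol, vol, labels, sizes=(64,), overlap=0.5)
        assert (1, 64) in report.absent and (2, 64) in report.absent

    def test_permuting_region_labels_swaps_entries(self, textured_pair):
        vol, labels = textured_pair
        swapped = ds.RegionLabelMap(
            np.where(labels.labels == 1, 2, 1).astype(np.uint8), labels.voxel_size
        )
        r1 = ds.zero_strain_test(vol, vol, labels, sizes=(16,), overlap=0.0)
        r2 = ds.zero_strain_test(vol, vol, swapped, sizes=(16,), overlap=0.0)
        for region in (1, 2):
            a = r1.entries[(region, 16)]
            b = r2.entries[(3 - region, 16)]
            assert a["maer"] == b["maer"]
            assert a["n_valid_nodes"] == b["n_valid_nodes"]

    def test_noisy_pair_error_shrinks_with_subvolume_size(self, textured_pair):
        vol, labels = textured_pair
        v1 = ds.add_noise(vol, 5.0, seed=31)
        v2 = ds.add_noise(vol, 5.0, seed=32)
        report = ds.zero_strain_test(v1, v2, labels, sizes=(16, 32), overlap=0.0)
        for region in (1, 2):
            assert report.maer(region, 32) < report.maer(region, 16)


class TestMakeSyntheticPair:
    def test_one_percent_compression_matrix_and_center(self, textured_pair):
        vol, _ = textured_pair
        _, deformed, truth = ds.make_synthetic_pair(vol, 0.01)
        np.testing.assert_allclose(truth.matrix, np.diag([1.0, 1.0, 0.99]))
        np.testing.assert_allclose(truth.center, vol.center)
        assert deformed.shape == vol.shape

    def test_analytic_truth_is_uniform_minus_10000_ue(self, textured_pair):
        vol, _ = textured_pair
        _, _, truth = ds.make_synthetic_pair(vol, 0.01)
        t = truth.strain_tensor() * 1e6
        np.testing.assert_allclose(np.diag(t), [0.0, 0.0, -10_000.0], atol=1e-9)

    def test_out_of_range_strain_level_rejected(self, textured_pair):
        vol, _ = textured_pair
        for bad in (0.0, 0.06, -0.01):
            with pytest.raises(ValueError):
                ds.make_synthetic_pair(vol, bad)

    def test_roundtrip_through_inverse_preserves_speckle(self, textured_pair):
        vol, _ = textured_pair
        _, deformed, truth = ds.make_synthetic_pair(vol, 0.01)
        back = ds.apply_affine_deformation(deformed, truth.inverse())
        interior = (slice(8, -8),) * 3
        err = back.data[interior] - np.asarray(vol.data, float)[interior]
        assert np.sqrt(np.mean(err**2)) < 0.05 * np.asarray(vol.data)[interior].std()


class TestSyntheticDeformationTest:
    def test_identity_truth_reduces_to_zero_strain_protocol(self, textured_pair):
        vol, labels = textured_pair
        v2 = ds.add_noise(vol, 4.0, seed=51)
        ident = ds.AffineDeformation(np.eye(3), vol.center)
        zs = ds.zero_strain_test(vol, v2, labels, sizes=(24,), overlap=0.0)
        sy = ds.synthetic_deformation_test(vol, v2, ident, labels, sizes=(24,), overlap=0.0)
        for key, e in zs.entries.items():
            assert sy.entries[key]["maer"] == e["maer"]
            assert sy.entries[key]["sder"] == e["sder"]

    def test_small_scale_compression_recovery(self):
        # flat interface + cropped VOI: windows either lie inside one
        # region or straddle a plane the region mask excludes, so the
        # per-region strain is free of interface-edge anchoring.
        # Sub-voxel interpolation-phase bias (~0.03 voxel) divided by the
        # small 16-voxel node spacing bounds accuracy to ~15% here; the
        # protocol-scale configuration with 48-voxel spacing is what the
        # 5% recovery requirement is asserted on (see tests/test_acceptance.py)
        spec = ds.PhantomSpec(
            shape=(128, 128, 128), interface_roughness_amp=0.0, noise_sd=0.0, seed=13
        )
        vol, labels = ds.generate_phantom(spec)
        _, deformed, truth = ds.make_synthetic_pair(vol, 0.01)
        ref = ds.crop_voi(vol, 120)
        dfm = ds.crop_voi(deformed, 120)
        lab = ds.RegionLabelMap(labels.labels[4:124, 4:124, 4:124], labels.voxel_size)
        field = ds.run_multipass(ref, dfm, (48, 32), final_overlap=0.5)
        for region in (ds.CARTILAGE, ds.MINERALIZED):
            masked = ds.mask_by_region(field, lab, region)
            strain = ds.compute_strain(masked)
            ezz = strain.component("ezz")[strain.valid]
            assert ezz.size > 0
            assert abs(np.mean(np.abs(ezz)) - 10_000.0) / 10_000.0 < 0.20

    def test_synthetic_error_at_least_zero_strain_error(self):
        # the virtual deformation adds interpolation error on top of the
        # correlation noise of the equivalent zero-strain comparison
        spec = ds.PhantomSpec(
            shape=(128, 128, 128), interface_roughness_amp=0.0, noise_sd=0.0, seed=19
        )
        vol, labels = ds.generate_phantom(spec)
        v1 = ds.add_noise(vol, 3.0, seed=61)
        v2 = ds.add_noise(vol, 3.0, seed=62)
        _, deformed, truth = ds.make_synthetic_pair(v2, 0.01)
        crop = lambda v: ds.crop_voi(v, 120)
        lab = ds.RegionLabelMap(labels.labels[4:124, 4:124, 4:124], labels.voxel_size)
        truth_c = ds.AffineDeformation(truth.matrix, truth.center - 4.0)
        zs = ds.zero_strain_test(crop(v1), crop(v2), lab, sizes=(24,), overlap=0.0)
        sy = ds.synthetic_deformation_test(
            crop(v1), crop(deformed), truth_c, lab, sizes=(24,), overlap=0.0
        )
        for region in (1, 2):
            assert sy.maer(region, 24) >= zs.maer(region, 24)


class TestStrainHistogram:
    def test_constant_values_occupy_single_bin(self):
        centers, freq, peak = ds.strain_histogram([640.0] * 20, bin_width=100.0)
        assert freq.max() == 1.0
        assert centers[np.argmax(freq)] == peak
        assert 600.0 <= peak <= 700.0

    @given(
        values=st.lists(
            st.floats(min_value=0.0, max_value=2e4), min_size=1, max_size=200
        ),
        bin_width=st.sampled_from([50.0, 100.0, 250.0]),
    )
    def test_frequencies_always_sum_to_one(self, values, bin_width):
        _, freq, _ = ds.strain_histogram(values, bin_width=bin_width)
        assert freq.sum() == pytest.approx(1.0)

    def test_gaussian_sample_peak_near_mean(self, rng):
        values = rng.normal(3000.0, 500.0, size=100_000)
        _, _, peak = ds.strain_histogram(values, bin_width=100.0)
        assert abs(peak - 3000.0) <= 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ds.strain_histogram([], bin_width=100.0)
        with pytest.raises(ValueError):
            ds.strain_histogram([1.0], bin_width=0.0)
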