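"""Flat-punch indentation and unconfined-compression metrics."""

import numpy as np
import pytest

import dvcstrain as ds


class TestSegmentPhases:
    def test_triangle_wave_splits_at_apex_with_empty_hold(self):
        t, p, h = ds.synthesize_indentation_curve(n_load=30, n_hold=0, n_unload=30)
        curve = ds.segment_phases(t, p, h)
        assert curve.samples("hold").size == 0
        assert curve.samples("loading").size == 30
        assert curve.samples("unloading").size == 30

    def test_trapezoid_has_three_contiguous_phases(self):
        t, p, h = ds.synthesize_indentation_curve(n_load=30, n_hold=15, n_unload=30)
        curve = ds.segment_phases(t, p, h)
        assert curve.samples("hold").size == 15
        assert curve.samples("loading").size == 30
        assert curve.samples("unloading").size == 30
        order = [curve.phase[i] for i in range(len(curve.phase))]
        assert order == sorted(order, key=["loading", "hold", "unloading"].index)

    def test_phase_counts_track_generator_bookkeeping(self):
        for n_load, n_hold, n_unload in [(40, 10, 25), (10, 2, 10), (25, 0, 40)]:
            t, p, h = ds.synthesize_indentation_curve(
                n_load=n_load, n_hold=n_hold, n_unload=n_unload
            )
            curve = ds.segment_phases(t, p, h, hold_tolerance=0.01)
            assert curve.samples("loading").size == n_load
            assert curve.samples("hold").size == n_hold
            assert curve.samples("unloading").size == n_unload

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError, match="time"):
            ds.segment_phases([0, 2, 1], [0, 1, 0], [0, 1, 0])


class TestContactStiffness:
    def test_linear_unloading_slope_recovered_exactly(self):
        # P = 2 h + 1 on the unloading branch -> S = 2 mN/µm
        h = np.linspace(10.0, 0.0, 50)
        p = 2.0 * h + 1.0
        curve = ds.IndentationCurve(
            time=np.arange(50, dtype=float), load=p, depth=h,
            phase=np.array(["unloading"] * 50),
        )
        assert ds.contact_stiffness(curve) == pytest.approx(2.0, abs=1e-12)

    def test_power_law_unloading_tends_to_analytic_derivative(self):
        # P = c h^2: dP/dh at h_max = 2 c h_max
        c, h_max = 0.05, 30.0
        h = np.linspace(h_max, 0.0, 20_000)
        p = c * h**2
        curve = ds.IndentationCurve(
            time=np.arange(h.size, dtype=float), load=p, depth=h,
            phase=np.array(["unloading"] * h.size),
        )
        s = ds.contact_stiffness(curve, fit_fraction=0.01)
        assert abs(s - 2 * c * h_max) / (2 * c * h_max) < 0.02

    def test_deterministic_on_duplicate_curve(self):
        t, p, h = ds.synthesize_indentation_curve(noise_sd=0.3, seed=4)
        c1 = ds.segment_phases(t, p, h)
        c2 = ds.segment_phases(t.copy(), p.copy(), h.copy())
        assert ds.contact_stiffness(c1) == ds.contact_stiffness(c2)

    def test_invariant_under_time_axis_rescaling(self):
        t, p, h = ds.synthesize_indentation_curve()
        a = ds.contact_stiffness(ds.segment_phases(t, p, h))
        b = ds.contact_stiffness(ds.segment_phases(t * 7.5, p, h))
        assert a == b

    def test_too_few_unloading_samples_rejected(self):
        curve = ds.IndentationCurve(
            time=np.arange(3.0), load=np.array([1.0, 2.0, 1.0]),
            depth=np.array([0.5, 1.0, 0.5]),
            phase=np.array(["loading", "loading", "unloading"]),
        )
        with pytest.raises(ValueError):
            ds.contact_stiffness(curve)


class TestHardness:
    def test_unit_arithmetic(self):
        t, p, h = ds.synthesize_indentation_curve(p_max=1.0)
        curve = ds.segment_phases(t, p, h)
        assert ds.hardness(curve, tip_area=1000.0) == pytest.approx(1.0)

    def test_nominal_flat_punch_at_45mn(self):
        t, p, h = ds.synthesize_indentation_curve(p_max=45.0)
        curve = ds.segment_phases(t, p, h)
        assert ds.hardness(curve, tip_area=2500.0) == pytest.approx(18.0)

    def test_doubling_area_halves_hardness(self):
        t, p, h = ds.synthesize_indentation_curve()
        curve = ds.segment_phases(t, p, h)
        assert ds.hardness(curve, 2000.0) == pytest.approx(2 * ds.hardness(curve, 4000.0))

    def test_nonpositive_area_rejected(self):
        t, p, h = ds.synthesize_indentation_curve()
        curve = ds.segment_phases(t, p, h)
        with pytest.raises(ValueError):
            ds.hardness(curve, 0.0)


class TestSummarizeLocations:
    def test_identical_replicates_have_zero_sd(self):
        metrics = [
            ds.IndentationMetrics(2.0, 1.5, location_id=loc, replicate_id=rep)
            for loc in range(3)
            for rep in range(3)
        ]
        out = ds.summarize_locations(metrics)
        assert out.loc["stiffness", "sd"] == 0.0
        assert out.loc["stiffness", "mean"] == 2.0

    def test_replicates_1_2_3_average_to_2(self):
        metrics = [
            ds.IndentationMetrics(s, s, location_id=0, replicate_id=i)
            for i, s in enumerate([1.0, 2.0, 3.0])
        ]
        out = ds.summarize_locations(metrics)
        assert out.loc["stiffness", "mean"] == pytest.approx(2.0)
        assert out.loc["stiffness", "n_locations"] == 1

    def test_nine_locations_three_replicates_recover_generator_mean(self):
        mu, sigma = 2.5, 0.3
        rng = np.random.default_rng(8)
        metrics = []
        for loc in range(9):
            for rep in range(3):
                t, p, h = ds.synthesize_indentation_curve(
                    stiffness=rng.normal(mu, sigma), seed=100 * loc + rep
                )
                curve = ds.segment_phases(t, p, h)
                metrics.append(
                    ds.IndentationMetrics(
                        ds.contact_stiffness(curve), ds.hardness(curve),
                        location_id=loc, replicate_id=rep,
                    )
                )
        out = ds.summarize_locations(metrics)
        tol = 2 * sigma / np.sqrt(9)
        assert abs(out.loc["stiffness", "mean"] - mu) < tol

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ds.summarize_locations([])


class TestCompressionStressStrain:
    def make_record(self, force, disp, d=4.0, thick=2.0):
        n = len(force)
        return ds.CompressionTestRecord(
            time=np.arange(n, dtype=float),
            force=np.asarray(force, dtype=float),
            displacement=np.asarray(disp, dtype=float),
            specimen_diameter=d,
            cartilage_thickness=thick,
        )

    def test_stress_arithmetic_for_known_geometry(self):
        rec = self.make_record([0.2], [0.1], d=4.0)
        out = ds.compression_stress_strain(rec)
        assert out["stress"][0] == pytest.approx(0.2 / (np.pi * 4.0**2 / 4), rel=1e-12)
        assert out["stress"][0] == pytest.approx(0.0159, abs=2e-4)

    def test_ten_percent_strain_from_02mm_on_2mm_cartilage(self):
        rec = self.make_record([0.1, 0.2], [0.0, 0.2], thick=2.0)
        out = ds.compression_stress_strain(rec)
        assert out["strain"][-1] == pytest.approx(0.10)

    def test_zero_force_zero_stress_and_linearity(self):
        rec = self.make_record([0.0, 0.1, 0.2], [0.0, 0.1, 0.2])
        out = ds.compression_stress_strain(rec)
        assert out["stress"][0] == 0.0
        np.testing.assert_allclose(out["stress"], 2 * out["stress"] / 2)
        rec2 = self.make_record([0.0, 0.2, 0.4], [0.0, 0.1, 0.2])
        out2 = ds.compression_stress_strain(rec2)
        np.testing.assert_allclose(out2["stress"], 2 * out["stress"])

    def test_relaxation_drop_measured_over_displacement_hold(self):
        # ramp to 0.2 mm, then hold while force decays 0.25 N
        disp = np.concatenate([np.linspace(0, 0.2, 10), np.full(20, 0.2)])
        force = np.concatenate([np.linspace(0, 1.5, 10), np.linspace(1.5, 1.25, 20)])
        rec = self.make_record(force, disp)
        out = ds.compression_stress_strain(rec)
        area = np.pi * 4.0**2 / 4
        assert out["relaxation"] == pytest.approx(0.25 / area)
        assert out["max_stress"] == pytest.approx(1.5 / area)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            self.make_record([0.1], [0.1], d=0.0)
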