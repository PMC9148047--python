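"""Virtual thermometry: probe sampling, IR imaging, property draws, power
metering — noise-free fidelity, seeded reproducibility, calibrated spread."""

import numpy as np
import pytest

from coaxtherm import NoiseModel, PowerSchedule, ProbeLayout, ir_snapshot, power_trace, run_transient, sample_phantom_properties, sample_probes, scale_loss
from coaxtherm.em import LossField
from coaxtherm.geometry import ApplicatorGeometry, GridSpec, build_material_map
from coaxtherm.thermal import cooling_phase

NOISELESS = NoiseModel(fiber_sd=0.0, ir_sd=0.0, power_rel_sd=0.0, seed=0)


@pytest.fixture(scope="module")
def small_series():
    """Cheap transient on the real applicator map with all probe points."""
    geom = ApplicatorGeometry.prototype(domain_padding=4.0)
    mmap = build_material_map(geom, GridSpec(fine_mm=2.0, device_mm=4.0, coarse_mm=15.0, min_layer_cells=1))
    p = np.zeros(mmap.shape)
    agar = mmap.cell_material == mmap.materials.index("agar gel")
    zc = np.broadcast_to(mmap.z_centers[None, :], mmap.shape)
    rc = np.broadcast_to(mmap.r_centers[:, None], mmap.shape)
    p[agar] = np.exp(-(rc[agar] ** 2 + zc[agar] ** 2) / (2 * 0.008**2))
    loss = LossField(p_loss=p, sar=p / 1000, total_absorbed=float((p * mmap.cell_volumes).sum()), map=mmap)
    loss = scale_loss(loss, 5.0)
    s = run_transient(mmap, loss, PowerSchedule.constant(5.0, 120.0),
                      probe_points=ProbeLayout().as_dict())
    return cooling_phase(s, 240.0)


class TestProbeLayout:
    def test_fourteen_points_with_pinned_positions(self):
        layout = ProbeLayout()
        pts = layout.as_dict()
        assert len(pts) == 14
        assert pts[3] == (0.0, 0.0)
        assert pts[2] == (0.0, 2.0)
        assert pts[4] == (0.0, -2.0)
        assert pts[9] == (0.5, 0.0)
        assert pts[12] == (1.0, 0.0)

    def test_all_points_inside_the_phantom(self):
        geom = ApplicatorGeometry.prototype()
        ProbeLayout().validate_inside(geom.phantom_radius, geom.phantom_z_range)

    def test_two_centimeter_pitch_along_each_fiber(self):
        layout = ProbeLayout()
        by_fiber = {}
        for pid, r, z in layout.points:
            by_fiber.setdefault(r, []).append(z)
        for zs in by_fiber.values():
            assert np.allclose(np.diff(sorted(zs)), 2.0)

    def test_outside_point_rejected(self, small_series):
        bad = ProbeLayout(points=((1, 2.5, 0.0),))
        with pytest.raises(ValueError):
            sample_probes(small_series, bad, NOISELESS)


class TestSampleProbes:
    def test_noise_free_matches_solver_traces(self, small_series):
        frame = sample_probes(small_series, ProbeLayout(), NOISELESS)
        for pid, trace in small_series.probe_traces.items():
            got = frame[frame.point_id == pid].temperature_C.to_numpy()
            assert np.array_equal(got, trace)

    def test_seeded_runs_are_bit_identical(self, small_series):
        a = sample_probes(small_series, noise=NoiseModel(seed=42))
        b = sample_probes(small_series, noise=NoiseModel(seed=42))
        assert a.equals(b)
        c = sample_probes(small_series, noise=NoiseModel(seed=43))
        assert not a.temperature_C.equals(c.temperature_C)

    def test_noise_spread_matches_fiber_accuracy(self, small_series):
        """sd 0.05 degC over ~1000 samples: the sample sd lands in the
        chi-square 99% interval [0.045, 0.055] around the nominal value."""
        frame = sample_probes(small_series, noise=NoiseModel(fiber_sd=0.05, seed=11))
        clean = sample_probes(small_series, noise=NOISELESS)
        resid = (frame.temperature_C - clean.temperature_C).to_numpy()
        resid = resid[:1000]
        assert 0.045 <= resid.std() <= 0.055


class TestIRSnapshot:
    def test_zero_delay_noise_free_equals_power_off_field(self, small_series):
        from scipy.interpolate import RegularGridInterpolator

        img = ir_snapshot(small_series, delay=0.0, noise=NOISELESS)
        field = small_series.temperature_at(small_series.t_power_off)
        oracle = RegularGridInterpolator(
            (small_series.map.r_centers, small_series.map.z_centers), field,
            bounds_error=False, fill_value=None,
        )
        X, Z = np.meshgrid(np.abs(img.x_cm) * 1e-2, img.z_cm * 1e-2, indexing="ij")
        expected = oracle(np.column_stack([X.ravel(), Z.ravel()])).reshape(X.shape)
        assert np.array_equal(img.temperature_C, expected)

    def test_mirror_symmetry_at_zero_noise(self, small_series):
        img = ir_snapshot(small_series, delay=60.0, noise=NOISELESS)
        assert np.allclose(img.temperature_C, img.temperature_C[::-1, :])

    def test_maximum_at_the_voi_center(self, small_series):
        img = ir_snapshot(small_series, delay=60.0, noise=NOISELESS)
        i, j = np.unravel_index(np.argmax(img.temperature_C), img.temperature_C.shape)
        assert abs(img.x_cm[i]) < 0.3
        assert abs(img.z_cm[j]) < 0.3

    def test_insufficient_cooling_rejected(self, small_series):
        with pytest.raises(ValueError):
            ir_snapshot(small_series, delay=1e4)


class TestPhantomProperties:
    def test_zero_spread_returns_table_values(self):
        agar = sample_phantom_properties(NoiseModel(seed=0), relative_sd=0.0)
        assert agar.sigma == 0.755
        assert agar.eps_r == 74.0

    def test_draws_positive_and_centered(self):
        draws = [
            sample_phantom_properties(NoiseModel(seed=s), relative_sd=0.02).sigma
            for s in range(1000)
        ]
        draws = np.array(draws)
        assert np.all(draws > 0)
        assert abs(draws.mean() - 0.755) / 0.755 < 0.005


class TestPowerTrace:
    def test_noise_free_samples_equal_schedule(self):
        sched = PowerSchedule.constant(3.6, 100.0)
        frame = power_trace(sched, NOISELESS)
        assert np.all(frame.power_W == 3.6)
        assert len(frame) == 100

    def test_mean_within_half_percent_over_long_hold(self):
        sched = PowerSchedule.constant(3.6, 600.0)
        frame = power_trace(sched, NoiseModel(seed=5))
        assert abs(frame.power_W.mean() - 3.6) / 3.6 < 0.005

    def test_seeded_reproducibility(self):
        sched = PowerSchedule.constant(2.5, 50.0)
        a = power_trace(sched, NoiseModel(seed=9))
        b = power_trace(sched, NoiseModel(seed=9))
        assert a.equals(b)
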