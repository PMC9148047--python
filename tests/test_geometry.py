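"""Geometry, materials and rasterization."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coaxtherm import (
    ApplicatorGeometry,
    GridSpec,
    MaterialProperties,
    MaterialTable,
    build_material_map,
    coax_impedance,
    default_materials,
    solve_outer_diameter,
)
from coaxtherm.geometry import GeometryError


class TestCoaxSizing:
    def test_prototype_impedance_matches_closed_form(self):
        # 138 log10(11.7/3.5)/sqrt(2.1), evaluated by hand
        assert coax_impedance(11.7, 3.5, 2.1) == pytest.approx(49.91, abs=0.005)

    def test_equal_diameters_give_zero_impedance(self):
        assert coax_impedance(4.0, 4.0, 2.1) == 0.0

    def test_fifty_ohm_outer_diameter_rounds_to_prototype(self):
        assert round(solve_outer_diameter(50.0, 3.5, 2.1), 1) == 11.7

    def test_zero_impedance_returns_inner_diameter(self):
        assert solve_outer_diameter(0.0, 3.5, 2.1) == pytest.approx(3.5)

    @pytest.mark.parametrize(
        "d, expected", [(2.2, 7.37), (3.5, 11.73), (4.3, 14.41)]
    )
    def test_sweep_diameters(self, d, expected):
        assert solve_outer_diameter(50.0, d, 2.1) == pytest.approx(expected, abs=0.005)

    def test_fifty_ohm_ratio_is_constant_across_sweep_diameters(self):
        ratios = [solve_outer_diameter(50.0, d, 2.1) / d for d in (2.2, 3.5, 4.3)]
        assert np.ptp(ratios) < 1e-12
        assert ratios[0] == pytest.approx(3.35, abs=0.005)

    @given(
        d=st.floats(0.5, 20.0),
        Z=st.floats(0.0, 120.0),
        eps=st.floats(1.0, 80.0),
    )
    def test_sizing_round_trip(self, d, Z, eps):
        D = solve_outer_diameter(Z, d, eps)
        assert coax_impedance(D, d, eps) == pytest.approx(Z, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("D, d", [(-1.0, 1.0), (1.0, -1.0), (2.0, 3.0), (0.0, 0.0)])
    def test_invalid_diameters_rejected(self, D, d):
        with pytest.raises(GeometryError):
            coax_impedance(D, d, 2.1)


class TestMaterials:
    def test_table_values(self):
        mats = default_materials()
        assert mats.lookup("agar gel").sigma == pytest.approx(0.755)
        assert mats.lookup("agar gel").eps_r == pytest.approx(74)
        assert mats.lookup("HDPE").eps_r == pytest.approx(2.1)
        assert mats.lookup("HDPE").rho == pytest.approx(950)
        assert mats.lookup("PVC").k == pytest.approx(0.2)
        assert mats.lookup("brass").is_pec

    def test_csv_round_trip_preserves_table(self):
        mats = default_materials()
        buf = io.StringIO()
        mats.to_csv(buf)
        buf.seek(0)
        back = MaterialTable.from_csv(buf)
        for a, b in zip(mats, back):
            assert a == b

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rho=-1, sigma=0, eps_r=1, cp=1, k=1),
            dict(rho=1, sigma=-1, eps_r=1, cp=1, k=1),
            dict(rho=1, sigma=0, eps_r=0.5, cp=1, k=1),
            dict(rho=1, sigma=0, eps_r=1, cp=0, k=1),
        ],
    )
    def test_invalid_properties_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MaterialProperties("bad", **kwargs)


class TestGeometryInvariants:
    def test_aperture_must_be_narrower_than_conductor(self):
        with pytest.raises(GeometryError):
            ApplicatorGeometry(w=8.0, h=8.0)

    def test_tube_must_fit_inside_inner_conductor(self):
        with pytest.raises(GeometryError):
            ApplicatorGeometry(tube_outer_diameter=3.6)

    def test_sweep_geometry_resizes_tube_and_phantom(self):
        g = ApplicatorGeometry.for_sweep(2.2, 1.2)
        assert g.D == pytest.approx(7.37, abs=0.005)
        assert g.tube_outer_diameter < g.d
        assert g.phantom_diameter == pytest.approx(g.tube_outer_diameter - 2 * g.tube_wall)


class TestMaterialMap:
    def test_grid_structure(self, fast_map):
        assert fast_map.r_edges[0] == 0.0
        assert np.all(np.diff(fast_map.r_edges) > 0)
        assert np.all(np.diff(fast_map.z_edges) > 0)

    def test_rasterized_volumes_converge_to_analytic(self, fast_geometry):
        geom = fast_geometry
        analytic = {
            "agar gel": math.pi * (geom.phantom_radius * 1e-2) ** 2 * geom.phantom_height * 1e-2,
            "PVC": math.pi
            * ((geom.tube_outer_diameter / 2 * 1e-2) ** 2 - (geom.phantom_radius * 1e-2) ** 2)
            * geom.phantom_height * 1e-2,
        }
        errs = {}
        for fine in (2.0, 1.0):
            m = build_material_map(geom, GridSpec(fine_mm=fine, device_mm=3.0, coarse_mm=12.0))
            for name, v in analytic.items():
                errs[(name, fine)] = abs(m.material_volume(name) - v) / v
        for name in analytic:
            assert errs[(name, 1.0)] < 0.02

    def test_pec_outline_broken_only_at_aperture_and_feed(self, fast_geometry, fast_map):
        """Scanning the inner-conductor radius, conductor cells are missing
        exactly along the aperture band; the feed gap interrupts the plate."""
        m = fast_map
        geom = fast_geometry
        a = geom.d / 2 * 1e-2
        i_wall = np.searchsorted(m.r_edges, a - 1e-6) - 1  # cell inside the wall
        zc = m.z_centers
        in_conductor_span = (zc > -geom.h / 2 * 1e-2) & (zc < geom.h / 2 * 1e-2)
        gap = np.abs(zc) < geom.w / 2 * 1e-2
        pec_col = m.pec_cells[i_wall, :]
        assert np.all(pec_col[in_conductor_span & ~gap])
        assert not np.any(pec_col[gap])
        assert m.source_index is not None

    def test_phantom_cells_have_agar_properties(self, fast_map):
        sigma = fast_map.cell_property("sigma")
        agar = fast_map.cell_material == fast_map.materials.index("agar gel")
        assert np.all(sigma[agar] == pytest.approx(0.755))

    def test_thin_layers_resolved_by_at_least_two_cells(self, fast_geometry):
        m = build_material_map(fast_geometry, GridSpec(fine_mm=1.0, device_mm=2.0, coarse_mm=12.0))
        geom = fast_geometry
        for lo, hi in [
            (geom.phantom_radius, geom.tube_outer_diameter / 2),
            (geom.d / 2 - geom.conductor_wall, geom.d / 2),
            (geom.D / 2, geom.D / 2 + geom.conductor_wall),
        ]:
            n = np.sum((m.r_edges > lo * 1e-2 + 1e-9) & (m.r_edges < hi * 1e-2 - 1e-9)) + 1
            assert n >= 2

    def test_metal_transparent_mode_replaces_brass(self, fast_map):
        mat = fast_map.thermal_material("transparent")
        assert not np.any(mat == fast_map.materials.index("brass"))
        with pytest.raises(ValueError):
            fast_map.thermal_material("bogus")
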