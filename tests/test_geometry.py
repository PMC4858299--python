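"""Closed-form geometry derivation and structured Q8 meshing."""

import math

import numpy as np
import pytest

from capstress.geometry import (
    CrystalSpec,
    GeometryError,
    MeshValidationError,
    MorphologyParams,
    QuadMesh,
    build_half_model,
    derive_geometry,
    validate_mesh,
)


class TestDeriveGeometry:
    def test_lumen_radius_closed_form(self):
        g = derive_geometry(MorphologyParams())
        assert g.lumen_radius == pytest.approx(math.sqrt(5.77 / math.pi), rel=1e-12)
        assert math.pi * g.lumen_radius**2 == pytest.approx(5.77, rel=1e-12)

    def test_unit_circle_lumen(self):
        # shrink the core so the printed stenosis still accommodates it
        g = derive_geometry(MorphologyParams(lumen_area=math.pi, core_area=0.3))
        assert g.lumen_radius == pytest.approx(1.0, rel=1e-12)

    def test_core_outer_radius_inverts_sector_area(self):
        p = MorphologyParams()
        g = derive_geometry(p)
        sector = (p.core_arc / 360.0) * math.pi * (g.core_outer_radius**2 - g.core_inner_radius**2)
        assert sector == pytest.approx(p.core_area, rel=1e-12)

    def test_stenosis_pins_vessel_radius(self):
        p = MorphologyParams()
        g = derive_geometry(p)
        assert 1.0 - p.lumen_area / g.reference_area == pytest.approx(p.stenosis_severity, rel=1e-12)

    def test_radius_ordering(self):
        g = derive_geometry(MorphologyParams())
        assert (
            g.lumen_radius < g.core_inner_radius < g.core_outer_radius < g.vessel_outer_radius
        )

    def test_unachievable_core_raises(self):
        # an oversized wall squeezes the plaque bed below the core annulus
        with pytest.raises(GeometryError):
            derive_geometry(MorphologyParams(wall_thickness=1.5))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cap_thickness": -0.01},
            {"lumen_area": 0.0},
            {"core_arc": 400.0},
            {"stenosis_severity": 1.2},
        ],
    )
    def test_invalid_morphology_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MorphologyParams(**kwargs)


class TestBuildHalfModel:
    def test_element_count_matches_reference_model(self, default_mesh):
        assert abs(default_mesh.n_elements - 1224) <= 0.10 * 1224

    def test_no_crystals_means_no_crystal_elements(self, default_mesh):
        assert not (default_mesh.region == "crystal").any()
        assert default_mesh.crystal_elements == {}

    def test_shoulder_crystal_centroid_at_core_arc_end(self):
        mesh = build_half_model(crystals=[CrystalSpec("shoulder")])
        elems = mesh.crystal_elements["shoulder"]
        xy = mesh.nodes[mesh.elements[elems]].mean(axis=(0, 1))
        theta = math.degrees(math.atan2(xy[1], xy[0]))
        one_element = math.degrees(mesh.d_theta)
        assert abs(theta - 84.65 / 2.0) <= one_element

    def test_crystal_band_radial_placement(self):
        mesh = build_half_model(crystals=[CrystalSpec("halfway")])
        elems = mesh.crystal_elements["halfway"]
        r = np.hypot(*mesh.nodes[np.unique(mesh.elements[elems])].T)
        g = mesh.geometry
        assert r.max() == pytest.approx(g.core_inner_radius, abs=1e-12)
        assert r.min() == pytest.approx(g.core_inner_radius - 0.0030, abs=1e-12)

    def test_overlapping_crystals_raise(self):
        long = 1.5  # mm, spans well past the neighboring station
        with pytest.raises(GeometryError, match="overlap"):
            build_half_model(
                crystals=[CrystalSpec("shoulder", length=long), CrystalSpec("halfway", length=long)]
            )

    def test_duplicate_locations_raise(self):
        with pytest.raises(GeometryError, match="distinct"):
            build_half_model(crystals=[CrystalSpec("center"), CrystalSpec("center")])

    def test_crystal_thicker_than_cap_raises(self):
        with pytest.raises(GeometryError, match="cap"):
            build_half_model(
                MorphologyParams(cap_thickness=0.025),
                crystals=[CrystalSpec("shoulder", thickness=0.030, length=0.26)],
            )

    def test_refinement_grows_and_keeps_area_accuracy(self):
        prev_count, prev_err = 0, None
        for k in (1, 2):
            mesh = build_half_model(refinement=k)
            diag = validate_mesh(mesh)
            assert mesh.n_elements > prev_count
            if prev_err is not None:
                assert abs(diag.region_area_errors["core"]) <= prev_err + 1e-12
            prev_count = mesh.n_elements
            prev_err = abs(diag.region_area_errors["core"])


class TestValidateMesh:
    def test_default_mesh_passes_with_tight_areas(self, default_mesh):
        diag = validate_mesh(default_mesh)
        assert diag.min_jacobian > 0
        assert abs(diag.region_area_errors["core"]) < 0.02
        assert not diag.nonconforming_edges

    def test_half_model_area_conservation(self, default_mesh):
        diag = validate_mesh(default_mesh)
        g = default_mesh.geometry
        target = math.pi * (g.vessel_outer_radius**2 - g.lumen_radius**2) / 2.0
        assert abs(diag.total_area - target) / target < 0.005

    def test_symmetry_nodes_on_axis(self, default_mesh):
        sym = np.unique(default_mesh.edge_groups["symmetry_line"].nodes)
        assert np.abs(default_mesh.nodes[sym, 1]).max() <= 1e-12

    def test_clockwise_element_fails_with_jacobian_diagnostic(self, default_mesh):
        broken = QuadMesh(
            nodes=default_mesh.nodes.copy(),
            elements=default_mesh.elements.copy(),
            region=default_mesh.region.copy(),
            edge_groups=default_mesh.edge_groups,
            geometry=default_mesh.geometry,
            params=default_mesh.params,
            d_theta=default_mesh.d_theta,
        )
        broken.elements[0, :4] = broken.elements[0, :4][::-1]
        with pytest.raises(MeshValidationError, match="Jacobian"):
            validate_mesh(broken)
        diag = validate_mesh(broken, raise_on_fail=False)
        assert 0 in diag.negative_jacobian_elements

    def test_empty_mesh_errors(self):
        empty = QuadMesh(
            nodes=np.zeros((0, 2)),
            elements=np.zeros((0, 8), dtype=int),
            region=np.array([], dtype="<U8"),
            edge_groups={},
        )
        with pytest.raises(MeshValidationError, match="empty"):
            validate_mesh(empty)
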