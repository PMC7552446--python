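import numpy as np
import pytest

from ablaheat import build_geometry, generate_mesh, sampling_line
from ablaheat.mesh import MeshingError


class TestGeometryPresets:
    def test_study1_control_layers(self):
        g = build_geometry(1, protected=False)
        L = g.layers
        assert (L.myocardium_thickness, L.fat_thickness, L.esophagus_thickness) == (2.00, 1.00, 2.50)
        assert "device_wall" not in g.subdomains()

    def test_study2_protected_device_span(self):
        g = build_geometry(2, protected=True)
        L = g.layers
        assert (L.myocardium_thickness, L.fat_thickness, L.esophagus_thickness) == (1.50, 0.50, 2.50)
        assert {"device_wall", "device_water"} <= set(g.subdomains())
        device_total = 2 * L.device_wall_thickness + L.water_layer_thickness
        assert device_total == pytest.approx(12.0, abs=0.5)

    def test_unknown_study_rejected(self):
        with pytest.raises(ValueError, match="study"):
            build_geometry(3, protected=False)

    def test_nonpositive_override_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_geometry(1, False, layer_overrides={"fat_thickness": 0.0})

    def test_insertion_depth_is_tip_height_over_25(self):
        g = build_geometry(1, False)
        assert g.catheter.insertion_depth == pytest.approx(g.catheter.tip_height / 25)
        assert g.catheter.insertion_depth == pytest.approx(0.160)


@pytest.fixture(scope="module")
def mesh_s1():
    return generate_mesh(build_geometry(1, False), target_elements=5748)


@pytest.fixture(scope="module")
def mesh_s2p():
    return generate_mesh(build_geometry(2, True), target_elements=6234)


class TestMeshInvariants:
    def test_element_count_near_target(self, mesh_s1, mesh_s2p):
        assert 0.7 * 5748 <= mesh_s1.n_elements <= 1.3 * 5748
        assert 0.7 * 6234 <= mesh_s2p.n_elements <= 1.3 * 6234

    def test_positive_areas_and_radii(self, mesh_s1):
        assert np.all(mesh_s1.element_areas > 0)
        assert np.all(mesh_s1.nodes[:, 0] >= 0)

    def test_every_subdomain_populated(self, mesh_s1, mesh_s2p):
        for mesh in (mesh_s1, mesh_s2p):
            for label in mesh.geometry.subdomains():
                assert len(mesh.subdomain_elements(label)) >= 1
        assert len(np.unique(mesh_s2p.element_subdomain)) == 10

    def test_boundary_edges_single_tag(self, mesh_s1):
        # exterior edges carry exactly one tag from the tag vocabulary
        tags = set(mesh_s1.boundary_tags.values())
        assert tags <= {
            "external",
            "symmetry_axis",
            "tip_surface",
            "blood_tissue_interface",
            "blood_catheter_interface",
            "water_inlet",
        }
        assert len(mesh_s1.edges_by_tag("external")) > 0
        assert len(mesh_s1.edges_by_tag("tip_surface")) > 0

    def test_tip_overlap_depth_is_insertion_depth(self, mesh_s1):
        # tip elements below the endocardial surface span exactly the insertion
        geom = mesh_s1.geometry
        ins = geom.z_interfaces["myocardium_top"]
        tip = mesh_s1.subdomain_elements("catheter_tip")
        zmin = mesh_s1.nodes[mesh_s1.triangles[tip]][:, :, 1].min()
        assert zmin == pytest.approx(0.0, abs=1e-12)
        myo = mesh_s1.subdomain_elements("myocardium")
        zmax_myo = mesh_s1.nodes[mesh_s1.triangles[myo]][:, :, 1].max()
        assert zmax_myo == pytest.approx(ins, abs=1e-12)

    def test_tip_refinement_vs_far_field(self, mesh_s1):
        p = mesh_s1.nodes[mesh_s1.triangles]
        edge = np.stack(
            [
                np.hypot(*(p[:, 1] - p[:, 0]).T),
                np.hypot(*(p[:, 2] - p[:, 1]).T),
                np.hypot(*(p[:, 0] - p[:, 2]).T),
            ]
        ).max(axis=0)
        c = p.mean(axis=1)
        near = np.hypot(c[:, 0], np.abs(c[:, 1])) < 2e-3
        assert edge[near].max() <= 0.25 * edge.max()

    def test_area_conservation_under_refinement(self):
        geom = build_geometry(1, False)
        m1 = generate_mesh(geom, 4000)
        m2 = generate_mesh(geom, 8000)
        for label in geom.subdomains():
            a1, a2 = m1.subdomain_area(label), m2.subdomain_area(label)
            assert abs(a2 - a1) / a1 < 1e-3

    def test_coarse_floor_still_valid(self):
        mesh = generate_mesh(build_geometry(1, False), target_elements=500)
        assert np.all(mesh.element_areas > 0)
        mesh.validate()

    def test_target_below_floor_rejected(self):
        with pytest.raises(ValueError, match=">= 500"):
            generate_mesh(build_geometry(1, False), target_elements=100)

    def test_degenerate_geometry_raises(self):
        geom = build_geometry(1, False, layer_overrides={"myocardium_thickness": 1e-9})
        with pytest.raises(MeshingError):
            generate_mesh(geom, 4000)


class TestSamplingLine:
    def test_tissue_span_matches_layer_sum(self, mesh_s1, mesh_s2p):
        line1 = sampling_line(mesh_s1)
        tissue1 = line1.arc_mm[np.isin(line1.labels, ["myocardium", "fat", "esophagus"])]
        assert line1.interfaces["eso_end"] == pytest.approx(5.50, abs=1e-12)
        assert tissue1.max() - 0.0 == pytest.approx(5.50, abs=1e-9)
        line2 = sampling_line(mesh_s2p)
        assert line2.interfaces["eso_end"] == pytest.approx(4.50, abs=1e-12)

    def test_strictly_increasing_and_dense(self, mesh_s1):
        line = sampling_line(mesh_s1)
        d = np.diff(line.arc_mm)
        assert np.all(d > 0)
        assert d.max() <= 0.05 + 1e-12

    def test_interfaces_are_sample_points(self, mesh_s2p):
        line = sampling_line(mesh_s2p)
        for pos in line.interfaces.values():
            assert np.min(np.abs(line.arc_mm - pos)) < 1e-12
        # the fat-esophagus interface point carries the deeper (esophagus) label
        i = int(np.argmin(np.abs(line.arc_mm - line.interfaces["fat_eso"])))
        assert line.labels[i] == "esophagus"

    def test_protected_line_continues_through_device_wall(self, mesh_s2p):
        line = sampling_line(mesh_s2p)
        assert line.labels[-1] == "device_wall"
        assert line.arc_mm[-1] == pytest.approx(4.5 + mesh_s2p.geometry.layers.device_wall_thickness)
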