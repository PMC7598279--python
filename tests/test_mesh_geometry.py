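"""Surface geometry: STL I/O, areas, volumes, reference cylinders."""

import numpy as np
import pytest
import trimesh
from hypothesis import given
from hypothesis import strategies as st

import graftgauge as gg
from graftgauge import mesh_geometry as mg

SINGLE_TRIANGLE_ASCII = """\
solid one
  facet normal 0 0 1
    outer loop
      vertex 0 0 0
      vertex 1 0 0
      vertex 0 1 0
    endloop
  endfacet
endsolid one
"""


def _near_duplicate_ascii():
    """Two triangles sharing an edge, one shared vertex offset by 1e-9 mm."""
    eps = 1e-9
    return f"""\
solid pair
  facet normal 0 0 1
    outer loop
      vertex 0 0 0
      vertex 1 0 0
      vertex 0 1 0
    endloop
  endfacet
  facet normal 0 0 1
    outer loop
      vertex 1 {eps} 0
      vertex 1 1 0
      vertex 0 1 0
    endloop
  endfacet
endsolid pair
"""


class TestSTLIO:
    def test_reads_minimal_ascii_triangle(self, tmp_path):
        path = tmp_path / "tri.stl"
        path.write_text(SINGLE_TRIANGLE_ASCII)
        mesh = mg.read_stl(path)
        assert mesh.n_vertices == 3
        assert mesh.n_faces == 1
        assert mg.side_surface_area(mesh) == pytest.approx(0.5)

    def test_merges_vertices_within_tolerance(self, tmp_path):
        path = tmp_path / "pair.stl"
        path.write_text(_near_duplicate_ascii())
        mesh = mg.read_stl(path)
        # 6 listed vertices, 2 shared pairs (one offset by 1e-9) -> 4 unique
        assert mesh.n_vertices == 4
        assert mesh.n_faces == 2

    def test_binary_roundtrip_preserves_counts_and_area(self, tmp_path, unit_cylinder_20k):
        path = tmp_path / "cyl.stl"
        mg.write_stl(unit_cylinder_20k, path)
        assert path.stat().st_size == 84 + 50 * unit_cylinder_20k.n_faces
        back = mg.read_stl(path)
        assert back.n_vertices == unit_cylinder_20k.n_vertices
        assert back.n_faces == unit_cylinder_20k.n_faces
        assert mg.side_surface_area(back) == pytest.approx(
            mg.side_surface_area(unit_cylinder_20k), rel=1e-6
        )

    def test_write_is_byte_deterministic(self, tmp_path, unit_cylinder_20k):
        a, b = tmp_path / "a.stl", tmp_path / "b.stl"
        mg.write_stl(unit_cylinder_20k, a)
        mg.write_stl(unit_cylinder_20k, b)
        assert a.read_bytes() == b.read_bytes()

    def test_empty_mesh_write_rejected(self, tmp_path):
        empty = mg.TriSurfaceMesh(
            vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int)
        )
        with pytest.raises(mg.MeshGeometryError):
            mg.write_stl(empty, tmp_path / "x.stl")

    def test_corrupt_file_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.stl"
        path.write_bytes(b"solid broken\nfacet gibberish\x00\x01\x02")
        with pytest.raises(mg.MeshFormatError):
            mg.read_stl(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(mg.MeshFormatError):
            mg.read_stl(tmp_path / "nope.stl")


class TestScalarGeometry:
    def test_axial_height_of_unit_cylinder(self, unit_cylinder_20k):
        assert mg.axial_height(unit_cylinder_20k) == pytest.approx(1.0)

    def test_axial_height_is_sign_invariant(self, unit_cylinder_20k):
        flipped = mg.TriSurfaceMesh(
            vertices=unit_cylinder_20k.vertices,
            faces=unit_cylinder_20k.faces,
            axis=np.array([0.0, 0.0, -1.0]),
        )
        assert mg.axial_height(flipped) == pytest.approx(1.0)

    def test_aaa_height_matches_construction(self, anatomy):
        mesh = gg.make_aaa_mesh(anatomy)
        assert mg.axial_height(mesh) == pytest.approx(anatomy.height, abs=1e-6)

    def test_single_triangle_area(self):
        mesh = mg.TriSurfaceMesh(
            vertices=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float),
            faces=np.array([[0, 1, 2]]),
        )
        assert mg.side_surface_area(mesh) == pytest.approx(0.5)

    def test_open_cylinder_lateral_area(self, unit_cylinder_20k):
        assert mg.side_surface_area(unit_cylinder_20k) == pytest.approx(
            2 * np.pi, rel=1e-3
        )

    def test_sphere_area_and_volume(self):
        ico = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
        mesh = mg.TriSurfaceMesh(vertices=ico.vertices, faces=ico.faces)
        assert mesh.n_faces >= 20000
        assert mg.side_surface_area(mesh) == pytest.approx(4 * np.pi, rel=2e-3)
        assert mg.enclosed_volume(mesh) == pytest.approx(4 * np.pi / 3, rel=3e-3)

    def test_capped_cylinder_volume(self, unit_cylinder_20k):
        assert mg.enclosed_volume(unit_cylinder_20k) == pytest.approx(
            np.pi, rel=2e-3
        )

    def test_unit_cube_volume_exact(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        mesh = mg.TriSurfaceMesh(vertices=box.vertices, faces=box.faces)
        assert mesh.n_faces == 12
        assert mg.enclosed_volume(mesh) == pytest.approx(1.0, rel=1e-12)


class TestStripCaps:
    def test_capped_cylinder_recovers_lateral_area(self):
        capped = trimesh.creation.cylinder(radius=1.0, height=1.0, sections=256)
        mesh = mg.TriSurfaceMesh(vertices=capped.vertices, faces=capped.faces)
        stripped = mg.strip_caps(mesh, tol_deg=15.0)
        assert mg.side_surface_area(stripped) == pytest.approx(2 * np.pi, rel=2e-3)

    def test_open_cylinder_unchanged(self, unit_cylinder_20k):
        stripped = mg.strip_caps(unit_cylinder_20k, tol_deg=15.0)
        assert stripped.n_faces == unit_cylinder_20k.n_faces

    def test_flat_disc_is_all_caps(self):
        ring = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        vertices = np.concatenate(
            [[[0.0, 0.0, 0.0]], np.stack([np.cos(ring), np.sin(ring), 0 * ring], axis=1)]
        )
        faces = [[0, 1 + i, 1 + (i + 1) % 32] for i in range(32)]
        disc = mg.TriSurfaceMesh(vertices=vertices, faces=np.array(faces))
        with pytest.raises(mg.MeshGeometryError, match="all caps"):
            mg.strip_caps(disc)

    def test_tolerance_domain(self, unit_cylinder_20k):
        with pytest.raises(mg.MeshGeometryError):
            mg.strip_caps(unit_cylinder_20k, tol_deg=0.0)


class TestReferenceCylinder:
    def test_diameter_from_area_and_height(self):
        ref = mg.ReferenceCylinder.from_height_and_side_surface(1.0, 2 * np.pi)
        assert ref.diameter == pytest.approx(2.0)

    def test_self_consistency_on_open_cylinder(self):
        mesh = gg.make_cylinder_mesh(10.0, 100.0, segments=(160, 64))
        ref = mg.build_reference_cylinder(mesh)
        assert ref.diameter == pytest.approx(20.0, rel=2e-3)
        assert ref.height == pytest.approx(100.0)

    def test_type_invariants_hold(self, small_cohort):
        for patient in small_cohort:
            for mesh in patient.meshes().values():
                ref = mg.build_reference_cylinder(mesh)
                area = mg.side_surface_area(mesh)
                assert np.pi * ref.diameter * ref.height == pytest.approx(
                    area, rel=1e-9
                )
                assert ref.volume == pytest.approx(
                    np.pi * ref.diameter**2 / 4 * ref.height, rel=1e-9
                )

    def test_bulged_aaa_has_larger_reference_diameter(self, anatomy):
        ref = mg.build_reference_cylinder(gg.make_aaa_mesh(anatomy))
        assert ref.diameter > 2 * anatomy.neck_radius


class TestShapeFactors:
    def test_cylinder_is_its_own_reference(self, unit_cylinder_20k):
        assert mg.shape_factor_vs_cylinder(unit_cylinder_20k) == pytest.approx(
            1.0, abs=0.01
        )

    def test_refinement_converges_to_unity(self, unit_cylinder_20k):
        coarse = abs(mg.shape_factor_vs_cylinder(unit_cylinder_20k) - 1.0)
        fine_mesh = gg.make_cylinder_mesh(1.0, 1.0, segments=(640, 64))
        fine = abs(mg.shape_factor_vs_cylinder(fine_mesh) - 1.0)
        assert fine < coarse

    def test_pair_identity(self, unit_cylinder_20k):
        report = mg.shape_factor_pair(unit_cylinder_20k, unit_cylinder_20k)
        assert report.phi_AS == pytest.approx(1.0)

    def test_pair_lateral_areas_scale_with_radius(self):
        big = gg.make_cylinder_mesh(20.0, 100.0, segments=(160, 32))
        small = gg.make_cylinder_mesh(10.0, 100.0, segments=(160, 32))
        report = mg.shape_factor_pair(big, small, "aneurysm_over_graft")
        assert report.phi_AS == pytest.approx(2.0, rel=5e-3)
        flipped = mg.shape_factor_pair(big, small, "graft_over_aneurysm")
        assert flipped.phi_AS == pytest.approx(0.5, rel=5e-3)

    def test_reciprocity_exact(self, small_cohort):
        p = small_cohort[0]
        ab = mg.shape_factor_pair(p.aaa, p.graft_long, "aneurysm_over_graft")
        ba = mg.shape_factor_pair(p.aaa, p.graft_long, "graft_over_aneurysm")
        assert ab.phi_AS * ba.phi_AS == pytest.approx(1.0, rel=1e-12)

    @given(scale=st.floats(min_value=0.05, max_value=50.0))
    def test_scale_invariance(self, scale):
        mesh = gg.make_cylinder_mesh(1.0, 2.0, segments=(32, 16))
        base = mg.shape_factor_vs_cylinder(mesh)
        scaled = mg.shape_factor_vs_cylinder(mesh.scaled(scale))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_scale_invariance_of_pair_ratio(self, small_cohort):
        p = small_cohort[0]
        base = mg.shape_factor_pair(p.aaa, p.graft_long).phi_AS
        scaled = mg.shape_factor_pair(
            p.aaa.scaled(3.7), p.graft_long.scaled(3.7)
        ).phi_AS
        assert scaled == pytest.approx(base, rel=1e-9)


def _brute_force_area(mesh):
    total = 0.0
    for i, j, k in mesh.faces:
        a, b, c = mesh.vertices[i], mesh.vertices[j], mesh.vertices[k]
        cx = np.cross(b - a, c - a)
        total += 0.5 * float(np.sqrt(cx @ cx))
    return total


def _brute_force_volume(mesh):
    total = 0.0
    for i, j, k in mesh.faces:
        a, b, c = mesh.vertices[i], mesh.vertices[j], mesh.vertices[k]
        total += float(a @ np.cross(b, c)) / 6.0
    return abs(total)


class TestBruteForceOracles:
    def test_area_matches_per_face_summation(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(1, 12)
            vertices = rng.normal(size=(3 * n, 3))
            faces = np.arange(3 * n).reshape(n, 3)
            mesh = mg.TriSurfaceMesh(vertices=vertices, faces=faces)
            assert mg.side_surface_area(mesh) == pytest.approx(
                _brute_force_area(mesh), rel=1e-9
            )

    def test_volume_matches_tetrahedron_summation(self):
        ico = trimesh.creation.icosphere(subdivisions=1, radius=1.0)
        rng = np.random.default_rng(7)
        for _ in range(100):
            stretch = np.diag(rng.uniform(0.5, 2.0, size=3))
            shift = rng.normal(scale=0.5, size=3)
            vertices = ico.vertices @ stretch + shift
            mesh = mg.TriSurfaceMesh(vertices=vertices, faces=ico.faces)
            assert mg.enclosed_volume(mesh) == pytest.approx(
                _brute_force_volume(mesh), rel=1e-9
            )

    def test_volume_matches_convex_hull_oracle(self):
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(11)
        points = rng.normal(size=(30, 3))
        hull = ConvexHull(points)
        mesh = mg.TriSurfaceMesh(
            vertices=points, faces=hull.simplices
        )
        assert mg.enclosed_volume(mesh) == pytest.approx(hull.volume, rel=1e-9)
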