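"""Strain measures: areal, Green-Lagrange, composition, summaries."""
import numpy as np
import pytest

from valvetrack.mesh import TriangleSurfaceMesh
from valvetrack.phantom import DeformationSpec, apply_analytic_deformation
from valvetrack.strain import (StrainField, areal_strain, build_strain_field,
                               compose_total_strain, element_triads,
                               fe_green_lagrange, inplane_green_lagrange,
                               multiplicative_areal_diagnostic,
                               per_leaflet_summary, scalar_measures,
                               total_areal_strain)


def _two_triangles():
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
    faces = np.array([[0, 1, 2], [1, 3, 2]])
    return TriangleSurfaceMesh(verts, faces,
                               leaflet_label=np.array([1, 2]))


class TestAreal:
    def test_identical_meshes_zero(self, trileaflet):
        assert np.abs(areal_strain(trileaflet, trileaflet)).max() == 0.0

    def test_uniform_scale_gives_s2_minus_1(self, trileaflet):
        out = apply_analytic_deformation(
            trileaflet, DeformationSpec(kind="uniform_scale", scale=1.1))
        ea = areal_strain(trileaflet, out)
        assert np.abs(ea - (1.1 ** 2 - 1.0)).max() < 1e-12

    def test_degenerate_reference_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0.0]])
        mesh = TriangleSurfaceMesh(verts, np.array([[0, 1, 2], [0, 1, 3]]))
        with pytest.raises(ValueError, match="element"):
            areal_strain(mesh, mesh)

    def test_topology_mismatch_rejected(self, trileaflet):
        other = TriangleSurfaceMesh(trileaflet.vertices,
                                    trileaflet.faces[:-1],
                                    trileaflet.leaflet_label[:-1])
        with pytest.raises(ValueError):
            areal_strain(trileaflet, other)


class TestTotalAreal:
    def test_zero_second_step_is_identity(self):
        e1 = np.array([0.1, -0.05, 0.2])
        assert np.array_equal(total_areal_strain(e1, np.zeros(3)), e1)

    def test_component_sum(self):
        assert total_areal_strain(np.array([0.10]),
                                  np.array([0.05]))[0] == pytest.approx(0.15)

    def test_commutes(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert np.array_equal(total_areal_strain(a, b),
                              total_areal_strain(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_areal_strain(np.zeros(3), np.zeros(4))

    def test_multiplicative_diagnostic(self):
        d = multiplicative_areal_diagnostic(np.array([0.1]),
                                            np.array([0.05]))
        assert d[0] == pytest.approx((1.1 * 1.05 - 1.0) - 0.15)


class TestFeGreenLagrange:
    def test_homogeneous_F_matches_closed_form(self, flat_sheet):
        from valvetrack.constitutive import MaterialParams
        from valvetrack.fe import LoadCase, build_shell_model
        from valvetrack.fe import SimulationFrames, _relative_F
        model = build_shell_model(
            flat_sheet, MaterialParams(),
            LoadCase(pressure=0.0, annulus_displacement=np.zeros(
                (len(flat_sheet.annulus_nodes), 3))))
        Fh = np.array([[1.08, 0.02, 0], [0.03, 0.95, 0], [0, 0, 1.0]])
        deformed = flat_sheet.vertices @ Fh.T
        frames = SimulationFrames(
            [flat_sheet, flat_sheet, flat_sheet.with_vertices(deformed)],
            [0.0, 0.5, 1.0],
            [_relative_F(model, flat_sheet.vertices),
             _relative_F(model, flat_sheet.vertices),
             _relative_F(model, deformed)],
            [0.0, 0.0, 0.0])
        E = fe_green_lagrange(frames)
        # flat sheet in the xy plane: expected in-plane block of
        # 1/2 (F^T F - I) with zero out-of-plane components
        E2_expected = 0.5 * (Fh.T @ Fh - np.eye(3))[:2, :2]
        # triads may rotate the in-plane axes; compare the full sorted
        # spectrum (in-plane eigenvalues plus the zero normal mode)
        exp3 = np.sort(np.append(np.linalg.eigvalsh(E2_expected), 0.0))
        got = np.linalg.eigvalsh(E)
        assert np.abs(got - exp3).max() < 1e-10

    def test_identical_frames_zero(self, flat_sheet):
        from valvetrack.constitutive import MaterialParams
        from valvetrack.fe import (LoadCase, SimulationFrames,
                                   _relative_F, build_shell_model)
        model = build_shell_model(
            flat_sheet, MaterialParams(),
            LoadCase(pressure=0.0, annulus_displacement=np.zeros(
                (len(flat_sheet.annulus_nodes), 3))))
        F0 = _relative_F(model, flat_sheet.vertices)
        frames = SimulationFrames([flat_sheet] * 3, [0, 0.5, 1.0],
                                  [F0, F0, F0], [0.0] * 3)
        E = fe_green_lagrange(frames)
        assert np.abs(E).max() < 1e-12
        assert np.abs(E - np.transpose(E, (0, 2, 1))).max() < 1e-12


class TestInplane:
    def test_rigid_motion_gives_zero(self, trileaflet):
        spec = DeformationSpec(kind="rigid", rotvec=np.array([0.3, 0.2, 0.1]),
                               translation=np.array([1.0, 2.0, 3.0]))
        out = apply_analytic_deformation(trileaflet, spec)
        E = inplane_green_lagrange(trileaflet, out)
        assert np.abs(E).max() < 1e-10

    def test_uniform_stretch_eigenvalues(self, trileaflet):
        out = apply_analytic_deformation(
            trileaflet, DeformationSpec(kind="uniform_scale", scale=1.2))
        E = inplane_green_lagrange(trileaflet, out)
        eigs = np.linalg.eigvalsh(E)
        expected = (1.2 ** 2 - 1.0) / 2.0
        assert np.abs(eigs[:, 1:] - expected).max() < 1e-10
        assert np.abs(eigs[:, 0]).max() < 1e-10

    def test_random_linear_maps_match_closed_form(self):
        # 50 random per-triangle linear maps against 1/2(F^T F - I)
        # restricted to the tangent plane
        rng = np.random.default_rng(12)
        verts = np.array([[0.0, 0, 0], [1.3, 0.1, 0.2], [0.2, 1.1, -0.1]])
        faces = np.array([[0, 1, 2]])
        base = TriangleSurfaceMesh(verts, faces)
        B = element_triads(base)[0]
        T = B[:2, :].T  # (3, 2) tangent basis columns
        for _ in range(50):
            A = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
            out = base.with_vertices(verts @ A.T)
            E = inplane_green_lagrange(base, out)[0]
            FT = A @ T
            E2 = 0.5 * (FT.T @ FT - np.eye(2))
            E_expected = np.zeros((3, 3))
            E_expected[:2, :2] = E2
            E_expected = B.T @ E_expected @ B
            assert np.abs(E - E_expected).max() < 1e-9

    def test_degenerate_triangle_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0.0]])
        mesh = TriangleSurfaceMesh(verts, np.array([[0, 1, 2], [0, 1, 3]]))
        with pytest.raises(ValueError):
            inplane_green_lagrange(mesh, mesh)


class TestCompose:
    def test_zero_second_step(self, trileaflet):
        rng = np.random.default_rng(2)
        E = rng.normal(size=(len(trileaflet.faces), 3, 3))
        E = (E + np.transpose(E, (0, 2, 1))) / 2
        out = compose_total_strain(E, np.zeros_like(E), "as_given")
        assert np.array_equal(out, E)

    def test_diagonal_addition_in_shared_frame(self):
        E1 = np.array([np.diag([0.1, 0.05, 0.0])])
        E2 = np.array([np.diag([0.02, -0.01, 0.0])])
        out = compose_total_strain(E1, E2, "as_given")
        assert np.allclose(out[0], np.diag([0.12, 0.04, 0.0]))

    def test_frame_policies_differ_by_rotation_bound(self, trileaflet):
        # rotate the deformed configuration: the policy difference is
        # bounded by 2 |E_2d| * rotation angle
        angle = 0.3
        spec = DeformationSpec(kind="rigid",
                               rotvec=np.array([0.0, 0.0, angle]))
        rotated = apply_analytic_deformation(trileaflet, spec)
        rng = np.random.default_rng(5)
        m = len(trileaflet.faces)
        E_fe = rng.normal(0, 0.02, size=(m, 3, 3))
        E_fe = (E_fe + np.transpose(E_fe, (0, 2, 1))) / 2
        E_2d = rng.normal(0, 0.02, size=(m, 3, 3))
        E_2d = (E_2d + np.transpose(E_2d, (0, 2, 1))) / 2
        a = compose_total_strain(E_fe, E_2d, "synthetic_closed_local",
                                 ref_mesh=trileaflet, closed_mesh=rotated)
        b = compose_total_strain(E_fe, E_2d, "reference_local",
                                 ref_mesh=trileaflet, closed_mesh=rotated)
        diff = np.linalg.norm(a - b, axis=(1, 2))
        bound = 2.0 * (np.linalg.norm(E_fe, axis=(1, 2))
                       + np.linalg.norm(E_2d, axis=(1, 2))) * angle
        assert np.all(diff <= bound + 1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compose_total_strain(np.zeros((3, 3, 3)), np.zeros((4, 3, 3)))


class TestScalars:
    def test_zero_tensor(self):
        eeff, egl = scalar_measures(np.zeros((1, 3, 3)))
        assert eeff[0] == 0.0 and egl[0] == 0.0

    def test_hydrostatic(self):
        a = 0.07
        eeff, egl = scalar_measures(np.array([a * np.eye(3)]))
        assert eeff[0] == pytest.approx(0.0, abs=1e-12)
        assert egl[0] == pytest.approx(abs(a) * np.sqrt(3), rel=1e-12)

    def test_traceless_equality(self):
        E = np.array([[[0.1, 0.02, 0], [0.02, -0.06, 0], [0, 0, -0.04]]])
        eeff, egl = scalar_measures(E)
        assert eeff[0] == pytest.approx(egl[0], rel=1e-12)

    def test_deviatoric_never_exceeds_magnitude(self):
        rng = np.random.default_rng(8)
        E = rng.normal(size=(500, 3, 3))
        E = (E + np.transpose(E, (0, 2, 1))) / 2
        eeff, egl = scalar_measures(E)
        assert np.all(eeff <= egl + 1e-12)

    def test_asymmetric_input_rejected(self):
        E = np.zeros((1, 3, 3))
        E[0, 0, 1] = 1.0
        with pytest.raises(ValueError):
            scalar_measures(E)


class TestSummary:
    def test_uniform_field(self):
        mesh = _two_triangles()
        E = np.zeros((2, 3, 3))
        field = build_strain_field(E, np.full(2, 0.25), mesh.leaflet_label)
        table = per_leaflet_summary(field, mesh.areas)
        areal = table[table.measure == "areal"]
        assert np.allclose(areal["mean"], 0.25)
        assert np.allclose(areal["min"], 0.25)
        assert np.allclose(areal["max"], 0.25)

    def test_two_leaflet_means(self):
        mesh = _two_triangles()
        field = build_strain_field(np.zeros((2, 3, 3)),
                                   np.array([0.1, 0.3]),
                                   mesh.leaflet_label)
        table = per_leaflet_summary(field, mesh.areas)
        areal = table[table.measure == "areal"].set_index("leaflet")
        assert areal.loc[1, "mean"] == pytest.approx(0.1)
        assert areal.loc[2, "mean"] == pytest.approx(0.3)

    def test_area_weighting(self):
        # both elements in one leaflet; doubling one element's area
        # shifts the mean by the analytic weighted average
        mesh = _two_triangles()
        labels = np.array([1, 1])
        field = build_strain_field(np.zeros((2, 3, 3)),
                                   np.array([0.1, 0.3]), labels)
        w = np.array([1.0, 1.0])
        t1 = per_leaflet_summary(field, w)
        assert t1[t1.measure == "areal"]["mean"].iloc[0] == \
            pytest.approx(0.2)
        w2 = np.array([1.0, 2.0])
        t2 = per_leaflet_summary(field, w2)
        assert t2[t2.measure == "areal"]["mean"].iloc[0] == \
            pytest.approx((0.1 + 2 * 0.3) / 3.0)

    def test_additive_total_below_minus_one_warns(self):
        with pytest.warns(UserWarning, match="areal"):
            build_strain_field(np.zeros((1, 3, 3)), np.array([-1.2]),
                               np.array([1]))
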