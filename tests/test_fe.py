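"""Membrane shell solver: assembly, loads, stepping, convergence."""
import numpy as np
import pytest

from valvetrack.constitutive import MaterialParams
from valvetrack.fe import (MMHG_TO_KPA, LoadCase, SimulationError,
                           build_shell_model, internal_forces,
                           mesh_convergence_study, pressure_forces,
                           simulate_closure)
from valvetrack.mesh import TriangleSurfaceMesh


def _zero_load(mesh, pressure=0.0):
    return LoadCase(pressure=pressure,
                    annulus_displacement=np.zeros(
                        (len(mesh.annulus_nodes), 3)))


def _disc_mesh(radius=10.0, edge=0.8, thickness=1.2):
    """Flat clamped disc built from concentric rings."""
    n_r = int(round(radius / edge))
    verts = [np.zeros(3)]
    rings = []
    for i in range(1, n_r + 1):
        r = radius * i / n_r
        n_t = max(6, int(round(2 * np.pi * r / edge)))
        ring = []
        for j in range(n_t):
            a = 2 * np.pi * j / n_t
            ring.append(len(verts))
            verts.append(np.array([r * np.cos(a), r * np.sin(a), 0.0]))
        rings.append(ring)
    verts = np.array(verts)
    faces = []
    for j in range(len(rings[0])):
        nxt = rings[0][(j + 1) % len(rings[0])]
        faces.append((0, rings[0][j], nxt))
    for i in range(len(rings) - 1):
        a, b = rings[i], rings[i + 1]
        # zipper between rings of different sizes
        ia = ib = 0
        pa = [verts[k] for k in a] + [verts[a[0]]]
        pb = [verts[k] for k in b] + [verts[b[0]]]
        ka = a + [a[0]]
        kb = b + [b[0]]
        while ia < len(a) or ib < len(b):
            adv_a = ia < len(a)
            adv_b = ib < len(b)
            if adv_a and adv_b:
                if np.linalg.norm(pa[ia + 1] - pb[ib]) <= \
                        np.linalg.norm(pb[ib + 1] - pa[ia]):
                    adv_b = False
                else:
                    adv_a = False
            if adv_a:
                faces.append((ka[ia], kb[ib], ka[ia + 1]))
                ia += 1
            else:
                faces.append((kb[ib], kb[ib + 1], ka[ia]))
                ib += 1
    rim = np.array(rings[-1])
    return TriangleSurfaceMesh(verts, np.array(faces), annulus_nodes=rim,
                               thickness=thickness)


class TestBuild:
    def test_pressure_preset_conversion(self):
        lc = LoadCase.from_mmhg(75.0)
        assert lc.pressure == pytest.approx(75.0 * 0.133322)
        assert lc.pressure == pytest.approx(9.99915, abs=1e-5)

    def test_total_lumped_mass(self, flat_sheet):
        model = build_shell_model(flat_sheet, MaterialParams(),
                                  _zero_load(flat_sheet))
        # density g/mm^3 -> kg; area 100 mm^2, t = 1.2 mm
        expected = 1.1e-3 * 1e-3 * 100.0 * 1.2
        assert model.total_mass == pytest.approx(expected, rel=1e-10)

    def test_missing_annulus_displacement_rejected(self, flat_sheet):
        with pytest.raises(ValueError, match="annulus"):
            lc = LoadCase(pressure=0.0,
                          annulus_displacement=np.zeros((3, 3)))
            build_shell_model(flat_sheet, MaterialParams(), lc)


class TestInternalForces:
    def test_zero_at_reference(self, flat_sheet):
        model = build_shell_model(flat_sheet, MaterialParams(),
                                  _zero_load(flat_sheet))
        f = internal_forces(model, flat_sheet.vertices)
        assert np.abs(f).max() < 1e-10

    def test_rigid_translation_invariance(self, flat_sheet):
        model = build_shell_model(flat_sheet, MaterialParams(),
                                  _zero_load(flat_sheet))
        f = internal_forces(model, flat_sheet.vertices + [3.0, -1.0, 2.0])
        assert np.abs(f).max() < 1e-9

    def test_patch_test_interior_forces_vanish(self, flat_sheet):
        # homogeneous membrane stretch: constant-strain triangles must
        # be in exact interior equilibrium
        model = build_shell_model(flat_sheet, MaterialParams(),
                                  _zero_load(flat_sheet))
        F = np.array([[1.10, 0.03, 0.0], [0.02, 1.05, 0.0], [0, 0, 1.0]])
        f = internal_forces(model, flat_sheet.vertices @ F.T)
        rim = flat_sheet.annulus_nodes
        interior = np.setdiff1d(np.arange(len(flat_sheet.vertices)), rim)
        assert np.abs(f[interior]).max() < 1e-8 * np.abs(f[rim]).max()

    def test_inverted_element_identified(self, flat_sheet):
        model = build_shell_model(flat_sheet, MaterialParams(),
                                  _zero_load(flat_sheet))
        bad = flat_sheet.vertices.copy()
        # collapse one interior vertex onto a neighbour -> degenerate
        interior = np.setdiff1d(np.arange(len(bad)),
                                flat_sheet.annulus_nodes)
        bad[interior[0]] = bad[interior[1]]
        with pytest.raises(ValueError, match="element"):
            internal_forces(model, bad)


class TestPressureForces:
    def test_zero_pressure(self, flat_sheet):
        model = build_shell_model(flat_sheet, MaterialParams(),
                                  _zero_load(flat_sheet))
        f = pressure_forces(flat_sheet.vertices, 0.0, model=model)
        assert np.abs(f).max() == 0.0

    def test_negative_pressure_rejected(self, flat_sheet):
        model = build_shell_model(flat_sheet, MaterialParams(),
                                  _zero_load(flat_sheet))
        with pytest.raises(ValueError):
            pressure_forces(flat_sheet.vertices, -1.0, model=model)

    def test_flat_disc_total_force(self, flat_sheet):
        model = build_shell_model(flat_sheet, MaterialParams(),
                                  _zero_load(flat_sheet))
        p = 2.0
        f = pressure_forces(flat_sheet.vertices, p, model=model)
        total = f.sum(axis=0)
        assert np.linalg.norm(total) == pytest.approx(p * 100.0, rel=1e-10)
        # directed along -normal (away from the aortic side)
        assert abs(abs(total[2]) - p * 100.0) < 1e-8

    def test_follower_property_under_rotation(self, flat_sheet):
        from scipy.spatial.transform import Rotation
        model = build_shell_model(flat_sheet, MaterialParams(),
                                  _zero_load(flat_sheet))
        R = Rotation.from_rotvec([0.4, -0.2, 0.7]).as_matrix()
        f0 = pressure_forces(flat_sheet.vertices, 2.0, model=model)
        f1 = pressure_forces(flat_sheet.vertices @ R.T, 2.0, model=model)
        assert np.abs(f1 - f0 @ R.T).max() < 1e-10


class TestSimulation:
    def test_zero_load_stays_put(self, flat_sheet):
        model = build_shell_model(flat_sheet, MaterialParams(),
                                  _zero_load(flat_sheet))
        frames = simulate_closure(model, n_steps=4)
        d = np.linalg.norm(frames.configurations[-1].vertices
                           - flat_sheet.vertices, axis=1)
        assert d.max() < 1e-8

    def test_default_exports_three_frames(self, trileaflet):
        from valvetrack.mesh import remesh_to_edge_length
        m = remesh_to_edge_length(trileaflet, 1.4)
        m.thickness = 1.2
        model = build_shell_model(m, MaterialParams(), _zero_load(
            m, pressure=75 * MMHG_TO_KPA), bending_stiffness=5.0)
        frames = simulate_closure(model, n_steps=8)
        assert len(frames.configurations) == 3
        assert frames.pseudo_times == [0.0, 0.5, 1.0]
        assert np.array_equal(frames.configurations[0].vertices, m.vertices)

    def test_annulus_follows_prescription_and_determinism(self, trileaflet):
        from valvetrack.mesh import remesh_to_edge_length
        m = remesh_to_edge_length(trileaflet, 1.4)
        m.thickness = 1.2
        rng = np.random.default_rng(0)
        disp = np.tile([0.3, -0.2, 0.4], (len(m.annulus_nodes), 1))
        lc = LoadCase(pressure=75 * MMHG_TO_KPA, annulus_displacement=disp)
        model = build_shell_model(m, MaterialParams(), lc,
                                  bending_stiffness=5.0)
        f1 = simulate_closure(model, n_steps=8)
        got = f1.configurations[-1].vertices[m.annulus_nodes] \
            - m.vertices[m.annulus_nodes]
        assert np.abs(got - disp).max() < 1e-12
        # mid frame carries the half-ramped prescription exactly
        mid = f1.configurations[1].vertices[m.annulus_nodes] \
            - m.vertices[m.annulus_nodes]
        assert np.abs(mid - 0.5 * disp).max() < 1e-12
        model2 = build_shell_model(m, MaterialParams(), lc,
                                   bending_stiffness=5.0)
        f2 = simulate_closure(model2, n_steps=8)
        assert f1.configurations[-1].vertices.tobytes() \
            == f2.configurations[-1].vertices.tobytes()

    def test_energy_sanity_and_quasi_statics(self, trileaflet):
        from valvetrack.mesh import remesh_to_edge_length
        m = remesh_to_edge_length(trileaflet, 1.4)
        m.thickness = 1.2
        model = build_shell_model(m, MaterialParams(), _zero_load(
            m, pressure=75 * MMHG_TO_KPA), bending_stiffness=5.0)
        frames = simulate_closure(model, n_steps=8)
        d = frames.diagnostics
        # dissipation non-negative: external work >= stored energy
        for t, w in d["external_work"].items():
            if t > 0:
                assert w + 1e-9 >= d["strain_energy_frames"][t]
        # inertial forces negligible vs pressure at the final frame
        assert d["final_inertial_norm"] < 0.01 * d["final_pressure_norm"]


class TestMembraneOracle:
    def test_clamped_circular_membrane_deflection(self):
        # independent oracle: the classical Hencky stress-function ODE
        # for a pressurized clamped circular membrane,
        #   r^2 phi'' + r phi' - phi = -E t p^2 r^5 / (8 phi^2),
        # phi = r N_r, with phi(0) = 0 and the clamped-edge condition
        # phi'(a) = nu phi(a) / a; deflection w0 = int p r^2/(2 phi) dr.
        # Linearized constants: E = 3 c0, nu = 1/2 (incompressible).
        from scipy.integrate import solve_bvp
        c0 = 67.0
        E, nu, t, a = 3 * c0, 0.5, 1.2, 10.0
        p = 0.03  # kPa, small-strain regime

        def rhs(r, y):
            phi, dphi = y
            return np.vstack([dphi,
                              (phi - r * dphi) / r ** 2
                              - E * t * p * p * r ** 3 / (8 * phi ** 2)])

        def bc(y0, y1):
            return np.array([y0[0] - 1e-3 * a * y0[1],
                             y1[1] - nu * y1[0] / a])

        r = np.linspace(1e-3 * a, a, 400)
        scale = (E * t * p * p * a * a / 64.0) ** (1 / 3)
        y_init = np.vstack([2 * scale * r / a, np.full_like(r, 2 * scale / a)])
        sol = solve_bvp(rhs, bc, r, y_init, max_nodes=40000, tol=1e-10)
        assert sol.success
        rr = np.linspace(1e-3 * a, a, 2000)
        phi = sol.sol(rr)[0]
        w0_oracle = float(np.trapezoid(p * rr ** 2 / (2 * phi), rr))

        mesh = _disc_mesh(radius=a, edge=0.8, thickness=t)
        model = build_shell_model(mesh, MaterialParams(),
                                  _zero_load(mesh, pressure=p))
        frames = simulate_closure(model, n_steps=5)
        w0_fe = float(np.abs(
            frames.configurations[-1].vertices[:, 2]).max())
        assert w0_fe == pytest.approx(w0_oracle, rel=0.05)


class TestConvergenceStudy:
    def test_requires_two_targets(self, trileaflet):
        with pytest.raises(ValueError):
            mesh_convergence_study(trileaflet, MaterialParams(),
                                   _zero_load(trileaflet), [0.8])

    def test_refinement_converges(self, trileaflet):
        lc = LoadCase(pressure=75 * MMHG_TO_KPA,
                      annulus_displacement=np.zeros(
                          (len(trileaflet.annulus_nodes), 3)))
        table = mesh_convergence_study(
            trileaflet, MaterialParams(), lc, [0.8, 0.6, 0.4],
            n_steps=10, bending_stiffness=5.0)
        assert list(table.edge_target_mm) == [0.8, 0.6, 0.4]
        assert not table.failed.any()
        assert table.rel_change.iloc[-1] < 0.02
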