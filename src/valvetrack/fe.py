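"""Quasi-static valve closure by dynamic implicit membrane FE.

Constant-strain triangles carry the Lee-Sacks membrane response
(plane stress via incompressible thickness change); diastolic pressure
is a follower load on the deformed surface; the annulus is driven by
prescribed displacements while free edges stay unconstrained. Time
integration is a numerically damped implicit Newmark scheme
(gamma = 0.9, beta = 0.49) over a pseudo-time horizon [0, 1], with
Newton iterations, Levenberg-style regularization on indefinite
tangents, and adaptive step halving. Units: mm, kPa, s; forces in mN,
mass in kg (so density given in g/mm^3 is converted by 1e-3).

An optional hinge bending penalty regularizes membrane wrinkling
modes; with zero stiffness the model is a pure membrane.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import (MaterialParams, membrane_energy_batch,
                           membrane_pk2_batch)
from .mesh import TriangleSurfaceMesh

__all__ = [
    "MMHG_TO_KPA",
    "LoadCase",
    "ShellModel",
    "SimulationFrames",
    "SimulationError",
    "build_shell_model",
    "internal_forces",
    "pressure_forces",
    "simulate_closure",
    "mesh_convergence_study",
    "resample_annulus_displacement",
]

MMHG_TO_KPA = 0.133322


class SimulationError(RuntimeError):
    """Raised when the stepper cannot advance; carries the last state."""

    def __init__(self, msg, frames=None):
        super().__init__(msg)
        self.frames = frames


def _linear_ramp(t: float) -> float:
    return float(t)


@dataclass
class LoadCase:
    """Loading for one closure simulation.

    pressure : kPa (use ``LoadCase.from_mmhg`` for clinical units)
    annulus_displacement : (n_annulus, 3) total displacements (mm),
        ordered like ``mesh.annulus_nodes``; ramped linearly.
    density : g/mm^3; damping : mass-proportional Rayleigh coeff (1/s).
    """

    pressure: float = 75.0 * MMHG_TO_KPA
    annulus_displacement: Optional[np.ndarray] = None
    pressure_ramp: Callable[[float], float] = _linear_ramp
    annulus_ramp: Callable[[float], float] = None  # defaults to linear
    density: float = 1.1e-3
    damping: float = 1.0e3

    def __post_init__(self):
        if self.pressure < 0:
            raise ValueError("pressure must be >= 0")
        if abs(self.pressure_ramp(0.0)) > 1e-12 or \
                abs(self.pressure_ramp(1.0) - 1.0) > 1e-12:
            raise ValueError("pressure_ramp must satisfy ramp(0)=0, ramp(1)=1")
        if self.annulus_ramp is None:
            self.annulus_ramp = _linear_ramp
        if abs(self.annulus_ramp(0.0)) > 1e-12 or \
                abs(self.annulus_ramp(1.0) - 1.0) > 1e-12:
            raise ValueError("annulus_ramp must satisfy ramp(0)=0, ramp(1)=1")

    @staticmethod
    def from_mmhg(pressure_mmhg: float, **kw) -> "LoadCase":
        return LoadCase(pressure=pressure_mmhg * MMHG_TO_KPA, **kw)


@dataclass
class ShellModel:
    """Assembled membrane shell model (reference data precomputed)."""

    mesh: TriangleSurfaceMesh
    material: MaterialParams
    load: LoadCase
    bending_stiffness: float = 0.0  # kPa mm^3 hinge penalty; 0 = membrane

    def __post_init__(self):
        mesh = self.mesh
        if self.load.annulus_displacement is None:
            self.load.annulus_displacement = np.zeros(
                (len(mesh.annulus_nodes), 3))
        disp = np.asarray(self.load.annulus_displacement, dtype=float)
        if disp.shape != (len(mesh.annulus_nodes), 3):
            raise ValueError(
                "annulus_displacement must provide one 3-vector per annulus "
                f"node ({len(mesh.annulus_nodes)} required, got {disp.shape})")
        self.load.annulus_displacement = disp

        self.faces = _orient_faces(mesh)
        v = mesh.vertices
        p0, p1, p2 = (v[self.faces[:, i]] for i in range(3))
        g1, g2 = p1 - p0, p2 - p0
        n = np.cross(g1, g2)
        a2 = np.linalg.norm(n, axis=1)
        if np.any(a2 < 1e-12):
            raise ValueError("degenerate reference triangle in shell model")
        self.ref_area = 0.5 * a2
        e1 = g1 / np.linalg.norm(g1, axis=1)[:, None]
        nn = n / a2[:, None]
        e2 = np.cross(nn, e1)
        # 2x2 reference edge matrix in the local frame and its inverse
        Dm = np.empty((len(self.faces), 2, 2))
        Dm[:, 0, 0] = np.einsum("ij,ij->i", g1, e1)
        Dm[:, 1, 0] = np.einsum("ij,ij->i", g1, e2)
        Dm[:, 0, 1] = np.einsum("ij,ij->i", g2, e1)
        Dm[:, 1, 1] = np.einsum("ij,ij->i", g2, e2)
        det = Dm[:, 0, 0] * Dm[:, 1, 1] - Dm[:, 0, 1] * Dm[:, 1, 0]
        self.Dm_inv = np.empty_like(Dm)
        self.Dm_inv[:, 0, 0] = Dm[:, 1, 1]
        self.Dm_inv[:, 1, 1] = Dm[:, 0, 0]
        self.Dm_inv[:, 0, 1] = -Dm[:, 0, 1]
        self.Dm_inv[:, 1, 0] = -Dm[:, 1, 0]
        self.Dm_inv /= det[:, None, None]
        self.ref_triad = np.stack([e1, e2, nn], axis=1)  # (m, 3[row], 3)

        # lumped mass (kg): density g/mm^3 -> kg/mm^3
        rho = self.load.density * 1e-3
        self.mass = np.zeros(len(v))
        np.add.at(self.mass, self.faces.ravel(),
                  np.repeat(rho * self.ref_area * mesh.thickness / 3.0, 3))

        # prescribed dof bookkeeping
        self.n_nodes = len(v)
        self.prescribed = np.zeros(self.n_nodes, dtype=bool)
        self.prescribed[mesh.annulus_nodes] = True
        self.free = ~self.prescribed

        # hinge stencils for optional bending penalty
        self._build_hinges()

    def _build_hinges(self):
        edge_map = {}
        for fi, f in enumerate(self.faces):
            for k in range(3):
                a, b = int(f[k]), int(f[(k + 1) % 3])
                key = (min(a, b), max(a, b))
                edge_map.setdefault(key, []).append((fi, f[(k + 2) % 3]))
        hinges = []
        for (a, b), inc in edge_map.items():
            if len(inc) == 2:
                hinges.append((a, b, int(inc[0][1]), int(inc[1][1])))
        self.hinges = np.array(hinges, dtype=np.int64).reshape(-1, 4)
        if len(self.hinges):
            v = self.mesh.vertices
            self.hinge_rest_angle = _dihedral_angles(v, self.hinges)
            e_len = np.linalg.norm(v[self.hinges[:, 1]] - v[self.hinges[:, 0]],
                                   axis=1)
            self.hinge_weight = e_len  # per-hinge length weight
        else:
            self.hinge_rest_angle = np.zeros(0)
            self.hinge_weight = np.zeros(0)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())


def _orient_faces(mesh: TriangleSurfaceMesh) -> np.ndarray:
    """Consistently wind faces with normals toward the aortic side.

    Winding is propagated from a seed element across shared edges, then
    the global orientation is fixed so normals point away from the
    valve axis (the aortic sinuses) or, for near-flat sheets, along the
    annulus-plane normal.
    """
    faces = mesh.faces.copy()
    edge_map: dict[tuple, list] = {}
    for fi, f in enumerate(faces):
        for k in range(3):
            a, b = int(f[k]), int(f[(k + 1) % 3])
            edge_map.setdefault((min(a, b), max(a, b)), []).append(fi)
    visited = np.zeros(len(faces), dtype=bool)
    for seed in range(len(faces)):
        if visited[seed]:
            continue
        stack = [seed]
        visited[seed] = True
        while stack:
            fi = stack.pop()
            f = faces[fi]
            dirs = {}
            for k in range(3):
                a, b = int(f[k]), int(f[(k + 1) % 3])
                dirs[(min(a, b), max(a, b))] = (a, b)
            for key, nbrs in ((key, edge_map[key]) for key in dirs):
                for nb in nbrs:
                    if nb == fi or visited[nb]:
                        continue
                    g = faces[nb]
                    same = False
                    for k in range(3):
                        if (int(g[k]), int(g[(k + 1) % 3])) == dirs[key]:
                            same = True
                    if same:  # same directed edge => inconsistent winding
                        faces[nb] = g[::-1]
                    visited[nb] = True
                    stack.append(nb)
    from ._geometry import triangle_areas, triangle_normals
    normals = triangle_normals(mesh.vertices, faces)
    areas = triangle_areas(mesh.vertices, faces)
    centroid = mesh.vertices.mean(axis=0)
    cent = mesh.vertices[faces].mean(axis=1)
    if len(mesh.annulus_nodes):
        ann = mesh.vertices[mesh.annulus_nodes]
        u, s, vt = np.linalg.svd(ann - ann.mean(axis=0))
        up = vt[2]
        if len(mesh.free_edge_nodes):
            fe_dir = (mesh.vertices[mesh.free_edge_nodes].mean(axis=0)
                      - ann.mean(axis=0))
            if np.dot(up, fe_dir) < 0:
                up = -up
    else:
        up = np.array([0.0, 0.0, 1.0])
    radial = cent - centroid
    radial -= np.outer(radial @ up, up)
    norms = np.linalg.norm(radial, axis=1)
    ok = norms > 1e-9
    score_r = float(np.sum(areas[ok] * np.einsum(
        "ij,ij->i", normals[ok], radial[ok] / norms[ok, None])))
    score_z = float(np.sum(areas * (normals @ up)))
    score = score_r if abs(score_r) > 0.2 * areas.sum() else score_z
    if score < 0:
        faces = faces[:, ::-1]
    return faces


def _dihedral_from_coords(hx: np.ndarray) -> np.ndarray:
    """Signed dihedral angles from per-hinge coordinates (nh, 4, 3)."""
    x0, x1, x2, x3 = hx[:, 0], hx[:, 1], hx[:, 2], hx[:, 3]
    e = x1 - x0
    n1 = np.cross(e, x2 - x0)
    n2 = np.cross(x3 - x0, e)
    el = np.linalg.norm(e, axis=1)
    el = np.where(el < 1e-300, 1.0, el)
    cosv = np.einsum("ij,ij->i", n1, n2)
    sinv = np.einsum("ij,ij->i", np.cross(n1, n2), e / el[:, None])
    return np.arctan2(sinv, cosv)


def _dihedral_angles(v: np.ndarray, hinges: np.ndarray) -> np.ndarray:
    x0, x1, x2, x3 = (v[hinges[:, i]] for i in range(4))
    e = x1 - x0
    n1 = np.cross(e, x2 - x0)
    n2 = np.cross(x3 - x0, e)
    el = np.linalg.norm(e, axis=1)
    el = np.where(el < 1e-300, 1.0, el)
    cosv = np.einsum("ij,ij->i", n1, n2)
    sinv = np.einsum("ij,ij->i", np.cross(n1, n2), e / el[:, None])
    return np.arctan2(sinv, cosv)


def build_shell_model(mesh: TriangleSurfaceMesh, mat: MaterialParams,
                      load: LoadCase, bending_stiffness: float = 0.0
                      ) -> ShellModel:
    """Assemble the membrane shell model (validates annulus coverage)."""
    return ShellModel(mesh, mat, load, bending_stiffness)


# --- force evaluation -------------------------------------------------


def _element_positions(model: ShellModel, vertices: np.ndarray) -> np.ndarray:
    return vertices[model.faces]  # (m, 3 nodes, 3)


def _membrane_element_forces(model: ShellModel, pos: np.ndarray,
                             check: bool = True):
    """Internal membrane nodal forces per element, (m, 3, 3)."""
    g1 = pos[:, 1] - pos[:, 0]
    g2 = pos[:, 2] - pos[:, 0]
    if check:
        a2 = np.linalg.norm(np.cross(g1, g2), axis=1)
        bad = np.where(a2 < 1e-12)[0]
        if bad.size:
            raise ValueError(f"inverted/degenerate element(s): "
                             f"{bad[:10].tolist()}")
    G = np.stack([g1, g2], axis=2)           # (m, 3, 2)
    F = G @ model.Dm_inv                     # (m, 3, 2)
    C2d = np.einsum("mki,mkj->mij", F, F)
    S = membrane_pk2_batch(C2d, model.material)
    P = F @ S                                # (m, 3, 2)
    H = (model.ref_area * model.mesh.thickness)[:, None, None] \
        * (P @ np.transpose(model.Dm_inv, (0, 2, 1)))
    f = np.empty_like(pos)
    f[:, 1] = H[:, :, 0]
    f[:, 2] = H[:, :, 1]
    f[:, 0] = -H[:, :, 0] - H[:, :, 1]
    return f


def _pressure_element_forces(model: ShellModel, pos: np.ndarray,
                             pressure: float) -> np.ndarray:
    """Follower pressure nodal forces per element, (m, 3, 3).

    Force = -p * current_area * aortic normal, lumped by thirds
    (pushes from the aortic toward the ventricular side)."""
    g1 = pos[:, 1] - pos[:, 0]
    g2 = pos[:, 2] - pos[:, 0]
    avec = 0.5 * np.cross(g1, g2)            # area-weighted aortic normal
    fe = -pressure * avec / 3.0
    return np.repeat(fe[:, None, :], 3, axis=1)


def _dihedral_grad_coords(hx: np.ndarray) -> np.ndarray:
    """Analytic gradient of the signed dihedral angle wrt the 4 hinge
    nodes, (nh, 4, 3)."""
    x0, x1, x2, x3 = hx[:, 0], hx[:, 1], hx[:, 2], hx[:, 3]
    e = x1 - x0
    el = np.linalg.norm(e, axis=1)
    el = np.where(el < 1e-300, 1.0, el)
    n1 = np.cross(e, x2 - x0)
    n2 = np.cross(x3 - x0, e)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    n1sq = np.where(n1sq < 1e-300, 1.0, n1sq)
    n2sq = np.where(n2sq < 1e-300, 1.0, n2sq)
    a1 = (el / n1sq)[:, None] * n1
    a2 = (el / n2sq)[:, None] * n2
    w02 = np.einsum("ij,ij->i", x1 - x2, e) / el ** 2
    w03 = np.einsum("ij,ij->i", x1 - x3, e) / el ** 2
    w12 = np.einsum("ij,ij->i", x2 - x0, e) / el ** 2
    w13 = np.einsum("ij,ij->i", x3 - x0, e) / el ** 2
    g = np.empty_like(hx)
    g[:, 2] = a1
    g[:, 3] = a2
    g[:, 0] = -w02[:, None] * a1 - w03[:, None] * a2
    g[:, 1] = -w12[:, None] * a1 - w13[:, None] * a2
    return -g  # sign matches the atan2 convention of _dihedral_from_coords


def _hinge_grad(model: ShellModel, hx: np.ndarray) -> np.ndarray:
    """Per-hinge analytic gradient of the hinge energy wrt its 4
    nodes, (nh, 4, 3)."""
    kb = model.bending_stiffness
    th = _dihedral_from_coords(hx)
    coef = 2.0 * kb * model.hinge_weight * (th - model.hinge_rest_angle)
    return coef[:, None, None] * _dihedral_grad_coords(hx)


def _bending_forces(model: ShellModel, vertices: np.ndarray):
    """Hinge bending penalty forces (FD gradient of the hinge energy)."""
    if model.bending_stiffness <= 0 or not len(model.hinges):
        return np.zeros_like(vertices)
    hv = model.hinges
    g = _hinge_grad(model, vertices[hv])
    forces = np.zeros_like(vertices)
    np.add.at(forces, hv.ravel(), g.reshape(-1, 3))
    return forces


def internal_forces(model: ShellModel, configuration) -> np.ndarray:
    """Assembled internal (membrane + bending) nodal forces, (n, 3) mN.

    Zero at the reference configuration and invariant to rigid
    translations of the whole mesh.
    """
    vertices = configuration.vertices if hasattr(configuration, "vertices") \
        else np.asarray(configuration, dtype=float)
    pos = _element_positions(model, vertices)
    fe = _membrane_element_forces(model, pos)
    out = np.zeros_like(vertices)
    np.add.at(out, model.faces.ravel(),
              fe.reshape(-1, 3))
    out += _bending_forces(model, vertices)
    return out


def pressure_forces(configuration, pressure: float,
                    model: ShellModel = None,
                    faces: np.ndarray = None) -> np.ndarray:
    """Assembled follower pressure nodal forces, (n, 3) mN."""
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    vertices = configuration.vertices if hasattr(configuration, "vertices") \
        else np.asarray(configuration, dtype=float)
    if model is not None:
        faces = model.faces
        pos = vertices[faces]
        fe = _pressure_element_forces(model, pos, pressure)
    else:
        if faces is None:
            raise ValueError("pass a model or an oriented face array")
        pos = vertices[faces]
        g1 = pos[:, 1] - pos[:, 0]
        g2 = pos[:, 2] - pos[:, 0]
        avec = 0.5 * np.cross(g1, g2)
        fe = np.repeat((-pressure * avec / 3.0)[:, None, :], 3, axis=1)
    out = np.zeros_like(vertices)
    np.add.at(out, faces.ravel(), fe.reshape(-1, 3))
    return out


def strain_energy_total(model: ShellModel, vertices: np.ndarray) -> float:
    pos = _element_positions(model, vertices)
    g1 = pos[:, 1] - pos[:, 0]
    g2 = pos[:, 2] - pos[:, 0]
    G = np.stack([g1, g2], axis=2)
    F = G @ model.Dm_inv
    C2d = np.einsum("mki,mkj->mij", F, F)
    w = membrane_energy_batch(C2d, model.material)
    return float(np.sum(w * model.ref_area * model.mesh.thickness))


# --- tangent (batched element-level finite differences) ---------------


def _element_residual(model: ShellModel, pos: np.ndarray,
                      pressure: float) -> np.ndarray:
    f = _membrane_element_forces(model, pos, check=False)
    if pressure > 0:
        f -= _pressure_element_forces(model, pos, pressure)
    return f


def _tangent_matrix(model: ShellModel, vertices: np.ndarray,
                    pressure: float) -> sp.csr_matrix:
    pos = _element_positions(model, vertices)
    m = len(model.faces)
    h = 1e-7 * max(1.0, float(np.abs(vertices).max()))
    K_el = np.empty((m, 9, 9))
    for d in range(9):
        node, comp = divmod(d, 3)
        pp = pos.copy()
        pp[:, node, comp] += h
        fp = _element_residual(model, pp, pressure)
        pp[:, node, comp] -= 2 * h
        fm = _element_residual(model, pp, pressure)
        K_el[:, :, d] = ((fp - fm) / (2 * h)).reshape(m, 9)
    dof = (3 * model.faces[:, :, None] + np.arange(3)[None, None, :]) \
        .reshape(m, 9)
    rows = np.repeat(dof, 9, axis=1).ravel()
    cols = np.tile(dof, (1, 9)).ravel()
    K = sp.coo_matrix((K_el.ravel(), (rows, cols)),
                      shape=(3 * model.n_nodes, 3 * model.n_nodes)).tocsr()
    if model.bending_stiffness > 0 and len(model.hinges):
        K = K + _bending_tangent(model, vertices)
    return K


def _bending_tangent(model: ShellModel, vertices: np.ndarray):
    """Gauss-Newton hinge stiffness 2 kb w grad(theta) x grad(theta).

    The (theta - theta0) * Hessian(theta) term is dropped: it is
    indefinite, small for a small regularizer, and the damped Newton
    loop tolerates the approximation."""
    hv = model.hinges
    nh = len(hv)
    g = _dihedral_grad_coords(vertices[hv]).reshape(nh, 12)
    coef = 2.0 * model.bending_stiffness * model.hinge_weight
    blocks = coef[:, None, None] * g[:, :, None] * g[:, None, :]
    dof_all = (3 * hv[:, :, None] + np.arange(3)[None, None, :]).reshape(nh, 12)
    rows = np.repeat(dof_all, 12, axis=1).ravel()
    cols = np.tile(dof_all, (1, 12)).ravel()
    return sp.coo_matrix((blocks.ravel(), (rows, cols)),
                         shape=(3 * model.n_nodes, 3 * model.n_nodes)).tocsr()


# --- time stepping ----------------------------------------------------


@dataclass
class SimulationFrames:
    """Exported configurations of one closure run.

    configurations share the input topology; F_rel holds per-element
    3x2 deformation gradients (local 2D reference frame of frame 0);
    first configuration equals the input mesh.
    """

    configurations: list
    pseudo_times: list
    F_rel: list
    residual_norms: list
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.configurations) < 3:
            raise ValueError("at least 3 frames required")
        t = np.asarray(self.pseudo_times)
        if np.any(np.diff(t) <= 0):
            raise ValueError("pseudo_times must be strictly increasing")


def _relative_F(model: ShellModel, vertices: np.ndarray) -> np.ndarray:
    pos = vertices[model.faces]
    g1 = pos[:, 1] - pos[:, 0]
    g2 = pos[:, 2] - pos[:, 0]
    G = np.stack([g1, g2], axis=2)
    return G @ model.Dm_inv  # (m, 3, 2)


def simulate_closure(model: ShellModel, n_steps: int = 20,
                     newton_tol: float = 1e-4, max_newton: int = 15,
                     export_times=(0.0, 0.5, 1.0),
                     export_all: bool = False) -> SimulationFrames:
    """Run the damped implicit Newmark closure simulation.

    Pressure and annulus displacement ramp over pseudo-time [0, 1];
    by default exactly the initial, midpoint and final configurations
    are exported (``export_all`` stores every accepted step instead).
    Steps adaptively halve on Newton failure.
    """
    mesh = model.mesh
    n = model.n_nodes
    u = np.zeros((n, 3))
    v = np.zeros((n, 3))
    a = np.zeros((n, 3))
    gamma, beta = 0.9, 0.49
    alpha = model.load.damping
    M = np.repeat(model.mass, 3)
    ann = mesh.annulus_nodes
    d_total = model.load.annulus_displacement

    export_times = sorted(set(float(t) for t in export_times))
    stored = {0.0: (mesh.vertices.copy(), _relative_F(model, mesh.vertices),
                    0.0)}
    work_ext = 0.0
    work_at = {0.0: 0.0}
    energy_at = {0.0: 0.0}
    f_pres_old = pressure_forces(mesh.vertices, 0.0, model=model)

    t = 0.0
    dt0 = 1.0 / n_steps
    dt = dt0
    dt_min = dt0 / 256.0
    frames_so_far = None
    ext_norm_last = 0.0
    checkpoints = sorted(set(export_times[1:] + [1.0]))

    while t < 1.0 - 1e-12:
        # do not step across an export checkpoint
        next_cp = min(cp for cp in checkpoints if cp > t + 1e-12)
        dt_eff = min(dt, next_cp - t)
        t_new = t + dt_eff
        ok, u_new, v_new, a_new, res, ext_norm = _newmark_step(
            model, u, v, a, t_new, dt_eff, M, alpha, gamma, beta,
            newton_tol, max_newton, ann, d_total)
        if not ok:
            dt = dt_eff / 2.0
            if dt < dt_min:
                partial = None
                if len(stored) >= 3:
                    keys = sorted(stored)
                    partial = SimulationFrames(
                        [mesh.with_vertices(stored[k][0]) for k in keys],
                        keys, [stored[k][1] for k in keys],
                        [stored[k][2] for k in keys],
                        {"non_converged": True, "reached_pseudo_time": t})
                raise SimulationError(
                    f"step size underflow at pseudo-time {t:.4f}",
                    frames=partial)
            continue
        p_new = model.load.pressure * model.load.pressure_ramp(t_new)
        f_pres_new = pressure_forces(mesh.vertices + u_new, p_new, model=model)
        work_ext += float(np.sum(0.5 * (f_pres_old + f_pres_new)
                                 * (u_new - u)))
        f_pres_old = f_pres_new
        u, v, a = u_new, v_new, a_new
        t = t_new
        ext_norm_last = ext_norm
        if dt < dt0:
            dt = min(dt * 2.0, dt0)
        want = export_all or any(abs(t - cp) < 1e-9 for cp in export_times)
        if want:
            verts = mesh.vertices + u
            stored[round(t, 12)] = (verts, _relative_F(model, verts), res)
            work_at[round(t, 12)] = work_ext
            energy_at[round(t, 12)] = strain_energy_total(model, verts)

    configs, times, Fs, resids = [], [], [], []
    wanted = sorted(stored) if export_all else export_times
    for cp in wanted:
        key = min(stored, key=lambda s: abs(s - cp))
        if abs(key - cp) > 1e-9:
            raise SimulationError(f"no frame stored at pseudo-time {cp}")
        verts, F, res = stored[key]
        configs.append(mesh.with_vertices(verts))
        times.append(cp)
        Fs.append(F)
        resids.append(res)

    # quasi-static diagnostics at the final state
    f_pres = pressure_forces(mesh.vertices + u, model.load.pressure,
                             model=model)
    inertial = np.linalg.norm((M * a.reshape(-1)))
    diag = {
        "final_inertial_norm": float(inertial),
        "final_pressure_norm": float(np.linalg.norm(f_pres)),
        "external_force_norm": float(ext_norm_last),
        "strain_energy": strain_energy_total(model, mesh.vertices + u),
        "external_work": {cp: work_at.get(min(work_at,
                                              key=lambda s: abs(s - cp)))
                          for cp in times},
        "strain_energy_frames": {cp: energy_at.get(
            min(energy_at, key=lambda s: abs(s - cp))) for cp in times},
    }
    return SimulationFrames(configs, times, Fs, resids, diag)


def _newmark_step(model, u, v, a, t_new, dt, M, alpha, gamma, beta,
                  newton_tol, max_newton, ann, d_total):
    mesh = model.mesh
    n = model.n_nodes
    free = np.repeat(model.free, 3)
    u_try = u.copy()
    # prescribed annulus dofs follow the ramp exactly
    u_try[ann] = model.load.annulus_ramp(t_new) * d_total
    p_now = model.load.pressure * model.load.pressure_ramp(t_new)

    c_a = 1.0 / (beta * dt * dt)
    c_v = gamma / (beta * dt)

    def kinematics(u_new):
        a_new = (u_new - u - dt * v).reshape(-1) * c_a \
            - (1.0 / (2 * beta) - 1.0) * a.reshape(-1)
        v_new = v.reshape(-1) + dt * ((1 - gamma) * a.reshape(-1)
                                      + gamma * a_new)
        return v_new, a_new

    def residual(u_new):
        verts = mesh.vertices + u_new
        f_int = internal_forces(model, verts)
        f_ext = pressure_forces(verts, p_now, model=model)
        v_new, a_new = kinematics(u_new)
        r = (M * a_new + alpha * M * v_new
             + f_int.reshape(-1) - f_ext.reshape(-1))
        # external-force-relative convergence (tiny floor guards the
        # zero-load case); under a pressure-free schedule the caller
        # must provide a nonzero external load for this to be reachable
        ref = max(np.linalg.norm(f_ext.reshape(-1)[free]), 1e-10)
        return r, f_ext, ref

    r, f_ext, ext_norm = residual(u_try)
    rn = np.linalg.norm(r[free])
    mu = 0.0
    for it in range(max_newton):
        if rn <= newton_tol * ext_norm or rn < 1e-12:
            v_new, a_new = kinematics(u_try)
            return (True, u_try, v_new.reshape(n, 3), a_new.reshape(n, 3),
                    float(rn), float(ext_norm))
        K = _tangent_matrix(model, mesh.vertices + u_try,
                            model.load.pressure
                            * model.load.pressure_ramp(t_new))
        A = K + sp.diags((c_a + alpha * c_v) * M)
        A_ff = A[free][:, free].tocsc()
        scale = max(float(np.abs(A_ff.diagonal()).mean()), 1e-12)
        solved = False
        while not solved:
            try:
                A_try = A_ff + mu * scale * sp.identity(A_ff.shape[0],
                                                        format="csc")
                du = spla.spsolve(A_try, -r[free])
                if not np.all(np.isfinite(du)):
                    raise RuntimeError("non-finite Newton update")
                solved = True
            except Exception:
                mu = max(mu * 10.0, 1e-6)
                if mu > 1e6:
                    return False, None, None, None, None, None
        # line search with Levenberg fallback
        step = 1.0
        improved = False
        for _ in range(8):
            u_cand = u_try.copy()
            u_cand.reshape(-1)[free] += step * du
            try:
                r_cand, f_ext, ext_norm = residual(u_cand)
            except ValueError:
                step *= 0.5
                continue
            rn_cand = np.linalg.norm(r_cand[free])
            if rn_cand < rn or rn_cand <= newton_tol * ext_norm:
                u_try, r, rn = u_cand, r_cand, rn_cand
                improved = True
                mu = mu / 4.0 if mu > 1e-8 else 0.0
                break
            step *= 0.5
        if not improved:
            mu = max(mu * 10.0, 1e-4)
            if mu > 1e6:
                return False, None, None, None, None, None
    if rn <= newton_tol * ext_norm or rn < 1e-12:
        v_new, a_new = kinematics(u_try)
        return (True, u_try, v_new.reshape(n, 3), a_new.reshape(n, 3),
                float(rn), float(ext_norm))
    return False, None, None, None, None, None


def resample_annulus_displacement(src_mesh: TriangleSurfaceMesh,
                                  load: LoadCase,
                                  dst_mesh: TriangleSurfaceMesh) -> np.ndarray:
    """Carry prescribed annulus displacements onto a remeshed annulus by
    nearest-node lookup (the annulus polyline is preserved by remeshing,
    so nearest positions are sub-edge accurate)."""
    from scipy.spatial import cKDTree
    if load.annulus_displacement is None:
        return np.zeros((len(dst_mesh.annulus_nodes), 3))
    tree = cKDTree(src_mesh.vertices[src_mesh.annulus_nodes])
    _, idx = tree.query(dst_mesh.vertices[dst_mesh.annulus_nodes])
    return np.asarray(load.annulus_displacement)[idx]


# --- convergence study ------------------------------------------------


def mesh_convergence_study(mesh: TriangleSurfaceMesh, mat: MaterialParams,
                           load: LoadCase, edge_targets,
                           n_steps: int = 10, bending_stiffness: float = 0.0,
                           **sim_kw):
    """Re-run the closure at several mesh resolutions.

    Returns a DataFrame with one row per target edge length (sorted by
    decreasing edge length): element count, max displacement magnitude,
    relative change vs the previous (coarser) row, and a failure flag.
    """
    import pandas as pd
    from .mesh import remesh_to_edge_length

    targets = sorted(set(float(t) for t in edge_targets), reverse=True)
    if len(targets) < 2:
        raise ValueError("need at least two edge targets")
    rows = []
    prev = None
    for target in targets:
        try:
            m = remesh_to_edge_length(mesh, target)
            disp = resample_annulus_displacement(mesh, load, m)
            lc = LoadCase(pressure=load.pressure,
                          annulus_displacement=disp,
                          pressure_ramp=load.pressure_ramp,
                          annulus_ramp=load.annulus_ramp,
                          density=load.density, damping=load.damping)
            model = build_shell_model(m, mat, lc, bending_stiffness)
            frames = simulate_closure(model, n_steps=n_steps, **sim_kw)
            umax = float(np.linalg.norm(
                frames.configurations[-1].vertices - m.vertices,
                axis=1).max())
            rel = abs(umax - prev) / abs(prev) if prev else np.nan
            rows.append({"edge_target_mm": target, "n_elements": len(m.faces),
                         "max_displacement_mm": umax,
                         "rel_change": rel, "failed": False})
            prev = umax
        except Exception as exc:  # partial table with failure flags
            rows.append({"edge_target_mm": target, "n_elements": np.nan,
                         "max_displacement_mm": np.nan, "rel_change": np.nan,
                         "failed": True, "error": str(exc)})
    return pd.DataFrame(rows)
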