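"""Leaflet strain measures from tracked valve configurations.

The total closure strain is assembled in two steps: a finite-element
Green-Lagrange strain from the simulated open -> synthetic-closed
deformation, plus an in-plane Green-Lagrange strain from the small
registration correction synthetic-closed -> imaged-closed, computed
directly from nodal coordinates of the shell meshes. Scalars:

    areal strain      eA   = (Ad - Ar) / Ar           (per element)
    effective strain  eeff = sqrt(E' : E'),  E' = E - tr(E)/3 I
    magnitude         eGL  = sqrt(E : E)

Both addends of E_total are rotated into the per-element local frame of
the synthetic-closed configuration before summation (tensor sums are
frame-dependent; the deformed frame is where the correction lives).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriangleSurfaceMesh

__all__ = [
    "StrainField",
    "areal_strain",
    "total_areal_strain",
    "fe_green_lagrange",
    "inplane_green_lagrange",
    "compose_total_strain",
    "scalar_measures",
    "per_leaflet_summary",
    "element_triads",
]


def element_triads(mesh: TriangleSurfaceMesh) -> np.ndarray:
    """Orthonormal per-element triads (m, 3 rows = e1, e2, n)."""
    p = mesh.vertices[mesh.faces]
    g1 = p[:, 1] - p[:, 0]
    g2 = p[:, 2] - p[:, 0]
    n = np.cross(g1, g2)
    a2 = np.linalg.norm(n, axis=1)
    if np.any(a2 < 1e-12):
        bad = np.where(a2 < 1e-12)[0]
        raise ValueError(f"degenerate triangle(s): {bad[:10].tolist()}")
    e1 = g1 / np.linalg.norm(g1, axis=1)[:, None]
    nn = n / a2[:, None]
    e2 = np.cross(nn, e1)
    return np.stack([e1, e2, nn], axis=1)


@dataclass
class StrainField:
    """Per-element total strain tensors plus the scalar measures."""

    E_total: np.ndarray          # (m, 3, 3) world-frame symmetric tensors
    areal: np.ndarray            # (m,) total areal strain
    effective: np.ndarray        # (m,) eeff
    magnitude: np.ndarray        # (m,) eGL
    leaflet_label: np.ndarray    # (m,)
    reference: str = ""
    areal_components: tuple = None   # (eA_1, eA_2) if two-step

    def __post_init__(self):
        m = len(self.E_total)
        if not (len(self.areal) == len(self.effective)
                == len(self.magnitude) == len(self.leaflet_label) == m):
            raise ValueError("inconsistent per-element array lengths")
        asym = np.abs(self.E_total - np.transpose(self.E_total, (0, 2, 1)))
        if asym.max(initial=0) > 1e-8:
            raise ValueError("strain tensors must be symmetric")
        if np.any(self.areal <= -1):
            # a single-step areal strain cannot reach -1 (areas are
            # positive); the additive two-step total can, which is an
            # acknowledged artifact of summing large compressive steps
            import warnings
            warnings.warn("additive total areal strain <= -1 in "
                          f"{int(np.sum(self.areal <= -1))} element(s); "
                          "see the multiplicative composition diagnostic")

    def reference_areas(self, mesh: TriangleSurfaceMesh) -> np.ndarray:
        return mesh.areas


def areal_strain(ref: TriangleSurfaceMesh,
                 deformed: TriangleSurfaceMesh) -> np.ndarray:
    """Per-element relative area change (Ad - Ar) / Ar."""
    if ref.faces.shape != deformed.faces.shape or \
            np.any(ref.faces != deformed.faces):
        raise ValueError("meshes must share topology")
    Ar = ref.areas
    bad = np.where(Ar <= 1e-12)[0]
    if bad.size:
        raise ValueError(f"degenerate reference element(s): "
                         f"{bad[:10].tolist()}")
    return (deformed.areas - Ar) / Ar


def total_areal_strain(e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    """Elementwise sum of the two per-step areal strain components."""
    e1 = np.asarray(e1, float)
    e2 = np.asarray(e2, float)
    if e1.shape != e2.shape:
        raise ValueError("length mismatch between strain components")
    return e1 + e2


def multiplicative_areal_diagnostic(e1, e2) -> np.ndarray:
    """Difference between the additive total and the exact composition
    (1+e_tot) = (1+e1)(1+e2); reported as a diagnostic only."""
    return (1.0 + np.asarray(e1)) * (1.0 + np.asarray(e2)) - 1.0 \
        - total_areal_strain(e1, e2)


def _embed_2d(E2, triads) -> np.ndarray:
    """Lift per-element 2x2 tangent-plane tensors to world 3x3 via the
    triads (zero out-of-plane row/column in the local frame)."""
    m = len(E2)
    E3loc = np.zeros((m, 3, 3))
    E3loc[:, :2, :2] = E2
    B = triads  # rows are the local basis vectors
    return np.einsum("mai,mab,mbj->mij", B, E3loc, B)


def fe_green_lagrange(frames) -> np.ndarray:
    """Step-1 strain: E = 1/2 (F^T F - I) per element at the final
    (synthetic closed) frame, in the world frame (m, 3, 3).

    Uses the per-element 3x2 deformation gradients the simulation
    stores relative to frame 0; the in-plane tensor is embedded with a
    zero out-of-plane block in the reference element frame.
    """
    if not getattr(frames, "F_rel", None):
        raise ValueError("frames carry no deformation gradients")
    F = np.asarray(frames.F_rel[-1])  # (m, 3, 2), local-2D reference basis
    C2 = np.einsum("mki,mkj->mij", F, F)
    E2 = 0.5 * (C2 - np.eye(2))
    ref = frames.configurations[0]
    return _embed_2d(E2, element_triads(ref))


def inplane_green_lagrange(mesh_a: TriangleSurfaceMesh,
                           mesh_b: TriangleSurfaceMesh) -> np.ndarray:
    """Step-2 strain from nodal coordinates of two same-topology meshes.

    Per triangle: 2x2 deformation gradient mapping mesh_a edges to
    mesh_b edges in mesh_a's tangent frame, E2D = 1/2 (F^T F - I2),
    embedded into 3x3 with zero out-of-plane components in mesh_a's
    local frame (then expressed in world coordinates).
    """
    if mesh_a.faces.shape != mesh_b.faces.shape or \
            np.any(mesh_a.faces != mesh_b.faces):
        raise ValueError("meshes must share topology")
    ta = element_triads(mesh_a)
    pa = mesh_a.vertices[mesh_a.faces]
    pb = mesh_b.vertices[mesh_b.faces]
    ga = np.stack([pa[:, 1] - pa[:, 0], pa[:, 2] - pa[:, 0]], axis=2)
    gb = np.stack([pb[:, 1] - pb[:, 0], pb[:, 2] - pb[:, 0]], axis=2)
    # reference edges in the 2D tangent frame
    Dm = np.einsum("mrj,mjc->mrc", ta[:, :2, :], ga)  # (m, 2, 2)
    det = Dm[:, 0, 0] * Dm[:, 1, 1] - Dm[:, 0, 1] * Dm[:, 1, 0]
    if np.any(np.abs(det) < 1e-12):
        bad = np.where(np.abs(det) < 1e-12)[0]
        raise ValueError(f"degenerate triangle(s): {bad[:10].tolist()}")
    Dm_inv = np.empty_like(Dm)
    Dm_inv[:, 0, 0] = Dm[:, 1, 1]
    Dm_inv[:, 1, 1] = Dm[:, 0, 0]
    Dm_inv[:, 0, 1] = -Dm[:, 0, 1]
    Dm_inv[:, 1, 0] = -Dm[:, 1, 0]
    Dm_inv /= det[:, None, None]
    F = gb @ Dm_inv                      # (m, 3, 2): world <- tangent 2D
    C2 = np.einsum("mki,mkj->mij", F, F)
    E2 = 0.5 * (C2 - np.eye(2))
    return _embed_2d(E2, ta)


def compose_total_strain(E_fe: np.ndarray, E_2d: np.ndarray,
                         frame_policy: str = "synthetic_closed_local",
                         ref_mesh: TriangleSurfaceMesh = None,
                         closed_mesh: TriangleSurfaceMesh = None
                         ) -> np.ndarray:
    """Elementwise tensor sum E_total = E_FE + E_2D(3D).

    With the default policy the FE addend is rotated from the reference
    element frame into the synthetic-closed element frame before
    summation (per-element rotation conjugation); ``reference_local``
    instead rotates the in-plane addend back to the reference frame.
    Passing the two meshes is required for either rotation; without
    them the tensors are summed as given.
    """
    E_fe = np.asarray(E_fe, float)
    E_2d = np.asarray(E_2d, float)
    if E_fe.shape != E_2d.shape:
        raise ValueError("per-element tensor lists differ in length")
    if frame_policy not in ("synthetic_closed_local", "reference_local",
                            "as_given"):
        raise ValueError(f"unknown frame_policy {frame_policy!r}")
    if frame_policy == "as_given" or ref_mesh is None or closed_mesh is None:
        return E_fe + E_2d
    Bref = element_triads(ref_mesh)
    Bcls = element_triads(closed_mesh)
    # world rotation taking the reference triad onto the closed triad:
    # R = sum_a e_a_cls (x) e_a_ref  (triad rows are the basis vectors)
    R = np.einsum("mai,maj->mij", Bcls, Bref)
    if frame_policy == "synthetic_closed_local":
        E_fe_rot = np.einsum("mij,mjk,mlk->mil", R, E_fe, R)
        return E_fe_rot + E_2d
    Rt = np.transpose(R, (0, 2, 1))
    E_2d_rot = np.einsum("mij,mjk,mlk->mil", Rt, E_2d, Rt)
    return E_fe + E_2d_rot


def scalar_measures(E: np.ndarray):
    """(eeff, eGL) per element from symmetric strain tensors.

    eeff is the Frobenius norm of the deviator E' = E - tr(E)/3 I and
    eGL the Frobenius norm of E itself, so eeff <= eGL always.
    """
    E = np.asarray(E, float)
    asym = np.abs(E - np.transpose(E, (0, 2, 1))).max(initial=0)
    if asym > 1e-8:
        raise ValueError(f"non-symmetric strain tensor (max asym {asym:.2e})")
    tr = np.trace(E, axis1=1, axis2=2)
    Edev = E - tr[:, None, None] / 3.0 * np.eye(3)
    eeff = np.sqrt(np.einsum("mij,mij->m", Edev, Edev))
    egl = np.sqrt(np.einsum("mij,mij->m", E, E))
    return eeff, egl


def build_strain_field(E_total, areal, labels, reference="open",
                       areal_components=None) -> StrainField:
    eeff, egl = scalar_measures(E_total)
    return StrainField(E_total, np.asarray(areal, float), eeff, egl,
                       np.asarray(labels), reference, areal_components)


def per_leaflet_summary(field: StrainField,
                        ref_areas: np.ndarray = None):
    """Area-weighted mean and min/max of each scalar per leaflet.

    Returns a DataFrame with one row per (leaflet, measure).
    """
    import pandas as pd
    labels = np.asarray(field.leaflet_label)
    present = np.unique(labels)
    if ref_areas is None:
        ref_areas = np.ones(len(labels))
    ref_areas = np.asarray(ref_areas, float)
    rows = []
    for lab in present:
        sel = labels == lab
        if not np.any(sel):
            raise ValueError(f"leaflet label {lab} has no elements")
        w = ref_areas[sel]
        for name, vals in (("areal", field.areal),
                           ("effective", field.effective),
                           ("magnitude", field.magnitude)):
            v = vals[sel]
            rows.append({
                "leaflet": int(lab), "measure": name,
                "mean": float(np.sum(w * v) / np.sum(w)),
                "min": float(v.min()), "max": float(v.max()),
            })
    return pd.DataFrame(rows)


def export_strain_vtk(field: StrainField, mesh: TriangleSurfaceMesh,
                      path) -> None:
    """Write the mesh with per-cell strain arrays as legacy ASCII VTK."""
    with open(str(path), "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nstrain field\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        for pt in mesh.vertices:
            fh.write(f"{pt[0]:.9g} {pt[1]:.9g} {pt[2]:.9g}\n")
        fh.write(f"POLYGONS {len(mesh.faces)} {4 * len(mesh.faces)}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        fh.write(f"CELL_DATA {len(mesh.faces)}\n")
        for name, vals in (("areal", field.areal),
                           ("effective", field.effective),
                           ("magnitude", field.magnitude)):
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.9g}" for v in vals) + "\n")
        fh.write("SCALARS leaflet int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(v)) for v in field.leaflet_label) + "\n")
        fh.write("TENSORS E_total double\n")
        for E in field.E_total:
            for r in range(3):
                fh.write(f"{E[r,0]:.9g} {E[r,1]:.9g} {E[r,2]:.9g}\n")
            fh.write("\n")
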