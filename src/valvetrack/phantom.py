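"""Synthetic aortic-valve phantoms with analytic ground truth.

Generates trileaflet / bicuspid / unicuspid medial surfaces (leaflets as
cylindrically arranged parabolic-sag patches between a crown-shaped
attachment ring and scalloped free edges), closed-form deformation maps
whose exact strain is known analytically, and blurred/noisy grayscale +
label volume pairs emulating 4D TEE or 4D CT frames. Everything is
seeded and bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np

from .image import ImageVolume, voxelize_surface
from .mesh import TriangleSurfaceMesh

__all__ = [
    "ValveShapeParams",
    "DeformationSpec",
    "ImageSynthesisSpec",
    "generate_valve_surface",
    "apply_analytic_deformation",
    "synthesize_volumes",
    "annulus_trajectory",
    "PhantomImages",
]


@dataclass(frozen=True)
class ValveShapeParams:
    """Parametric valve shape.

    annulus_radius, commissure_height, belly_sag, target_edge in mm;
    n_leaflets in {1, 2, 3}. fusion_pattern marks a bicuspid valve that
    arose from fusing two of three anatomical leaflets: the fused pair
    is modeled as a single 240-degree entity with one leaflet label.
    irregularity adds a smooth seeded per-phantom shape perturbation.
    """

    annulus_radius: float = 12.0
    commissure_height: float = 9.0
    belly_sag: float = 2.0
    n_leaflets: int = 3
    fusion_pattern: Optional[str] = None
    target_edge: float = 0.8
    seed: int = 0
    irregularity: float = 0.1

    def __post_init__(self):
        if self.annulus_radius <= 0:
            raise ValueError("annulus_radius must be > 0")
        if self.commissure_height < 0:
            raise ValueError("commissure_height must be >= 0")
        if self.target_edge <= 0:
            raise ValueError("target_edge must be > 0")
        if self.n_leaflets not in (1, 2, 3):
            raise ValueError("n_leaflets must be 1, 2 or 3")


def _sector_widths(p: ValveShapeParams) -> np.ndarray:
    if p.n_leaflets == 3:
        return np.full(3, 2 * np.pi / 3)
    if p.n_leaflets == 2:
        if p.fusion_pattern:
            return np.array([4 * np.pi / 3, 2 * np.pi / 3])
        return np.array([np.pi, np.pi])
    return np.array([2 * np.pi])


def _leaflet_point(p: ValveShapeParams, th0, dth, s, t):
    """Map leaflet parameters (s in [0,1] annulus->free edge, t across
    the sector) to world coordinates."""
    R, Hc, sag = p.annulus_radius, p.commissure_height, p.belly_sag
    theta = th0 + t * dth
    z_a = Hc * (1 + np.cos(2 * np.pi * t)) / 2
    z_f = Hc - 0.5 * sag * np.sin(np.pi * t)
    r_f = R * (1 - 0.25 * np.sin(np.pi * t))
    r = (1 - s) * R + s * r_f - sag * np.sin(np.pi * s) * np.sin(np.pi * t)
    z = (1 - s) * z_a + s * z_f
    return np.stack([r * np.cos(theta), r * np.sin(theta),
                     np.broadcast_to(z, np.shape(r * np.cos(theta)))], axis=-1)


def _column_length(p, th0, dth, t, n=33):
    s = np.linspace(0.0, 1.0, n)
    pts = _leaflet_point(p, th0, dth, s, np.full(n, t))
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _zipper(cols):
    """Triangulate strips between consecutive vertex columns (greedy
    shortest-diagonal); cols is a list of (index_array, position_array)."""
    faces = []
    for (ia, pa), (ib, pb) in zip(cols[:-1], cols[1:]):
        i = k = 0
        while i < len(ia) - 1 or k < len(ib) - 1:
            adv_a = i < len(ia) - 1
            adv_b = k < len(ib) - 1
            if adv_a and adv_b:
                if (np.linalg.norm(pa[i + 1] - pb[k])
                        <= np.linalg.norm(pb[k + 1] - pa[i])):
                    adv_b = False
                else:
                    adv_a = False
            if adv_a:
                faces.append((ia[i], ib[k], ia[i + 1]))
                i += 1
            else:
                faces.append((ib[k], ib[k + 1], ia[i]))
                k += 1
    return faces


def generate_valve_surface(shape: ValveShapeParams) -> TriangleSurfaceMesh:
    """Build the open-configuration medial surface.

    Boundary decomposes into one closed annulus loop (attachment
    crescents joined at commissures) plus one free-edge curve per
    leaflet; per-element labels are 1-based leaflet ids.
    """
    p = shape
    widths = _sector_widths(p)
    edges_phi = np.concatenate([[0.0], np.cumsum(widths)])
    verts: list[np.ndarray] = []
    faces: list[tuple] = []
    labels: list[int] = []
    annulus: set[int] = set()
    free_edge: set[int] = set()
    commissure_ids: dict[bytes, int] = {}

    def add_vertex(pt):
        verts.append(np.asarray(pt, float))
        return len(verts) - 1

    for li in range(len(widths)):
        th0, dth = edges_phi[li], widths[li]
        arc = p.annulus_radius * dth
        m = max(6, int(round(arc / p.target_edge)))
        cols = []
        for j in range(m + 1):
            t = j / m
            if j in (0, m):
                pt = _leaflet_point(p, th0, dth, 0.0, float(t))
                key = (np.round(pt, 9) + 0.0).tobytes()  # +0.0 folds -0.0
                if key in commissure_ids:
                    vid = commissure_ids[key]
                else:
                    vid = add_vertex(pt)
                    commissure_ids[key] = vid
                annulus.add(vid)
                cols.append((np.array([vid]), pt[None, :]))
                continue
            length = _column_length(p, th0, dth, t)
            K = max(1, int(round(length / p.target_edge)))
            s = np.linspace(0.0, 1.0, K + 1)
            pts = _leaflet_point(p, th0, dth, s, np.full(K + 1, t))
            ids = np.array([add_vertex(q) for q in pts])
            annulus.add(int(ids[0]))
            free_edge.add(int(ids[-1]))
            cols.append((ids, pts))
        for f in _zipper(cols):
            faces.append(f)
            labels.append(li + 1)

    vertices = np.array(verts)
    faces = np.array(faces, dtype=np.int64)
    labels = np.array(labels, dtype=np.int64)
    free_edge -= annulus

    # seeded smooth irregularity: radial modulation by low-order harmonics
    if p.irregularity > 0:
        rng = np.random.default_rng(p.seed)
        amp = rng.normal(0.0, p.irregularity, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        zphase = rng.uniform(0, 2 * np.pi)
        theta = np.arctan2(vertices[:, 1], vertices[:, 0])
        zn = vertices[:, 2] / max(p.commissure_height, 1e-9)
        # smooth (C-inf) window vanishing at the annulus plane and apex
        window = np.sin(np.pi * zn) * (1.0 + 0.3 * np.sin(2 * np.pi * zn
                                                          + zphase))
        mod = sum(amp[k] * np.sin((k + 1) * theta + phase[k])
                  for k in range(3)) * window
        rho = np.linalg.norm(vertices[:, :2], axis=1)
        keep = rho > 1e-9
        scale = np.where(keep, (rho + mod) / np.where(keep, rho, 1.0), 1.0)
        # keep the boundary rings exact so node-set geometry stays clean
        bnd = np.zeros(len(vertices), bool)
        bnd[list(annulus | free_edge)] = True
        scale[bnd] = 1.0
        vertices = vertices * np.stack([scale, scale, np.ones_like(scale)],
                                       axis=1)

    mesh = TriangleSurfaceMesh(vertices, faces, labels,
                               np.array(sorted(annulus), dtype=np.int64),
                               np.array(sorted(free_edge), dtype=np.int64))
    mesh.assert_no_degenerate()
    return mesh


# --- analytic deformations -------------------------------------------


@dataclass(frozen=True)
class DeformationSpec:
    """Explicit differentiable point-map used as ground truth.

    kinds:
      identity
      uniform_scale: scale (>0), center (3,)
      rigid: rotvec (3,), translation (3,), center (3,)
      closure_billow: amplitude a >= 0 (mm of inward radial motion),
        height_ref h (mm), radius_ref R0 (mm), axial_drop d (mm).
        u = -(z/h)^2 (1 - (rho/R0)^4) (a rho_hat + d z_hat):
        the annulus plane (z = 0) and the attachment crown
        (rho = R0) stay exactly fixed, like leaflets billowing toward
        the ventricle while the root holds.
    """

    kind: str = "identity"
    scale: float = 1.0
    center: Optional[np.ndarray] = None
    rotvec: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    amplitude: float = 0.0
    height_ref: float = 9.0
    radius_ref: float = 24.0
    axial_drop: float = 0.0

    def __post_init__(self):
        if self.kind not in ("identity", "uniform_scale", "rigid",
                             "closure_billow"):
            raise ValueError(f"unknown deformation kind {self.kind!r}")
        if self.kind == "uniform_scale" and self.scale <= 0:
            raise ValueError("scale factor must be > 0")
        if self.kind == "closure_billow":
            if self.amplitude < 0:
                raise ValueError("billow amplitude must be >= 0")
            if self.height_ref <= 0:
                raise ValueError("height_ref must be > 0")

    def resolved_for(self, mesh: TriangleSurfaceMesh) -> "DeformationSpec":
        """Fill a missing center with the mesh vertex centroid."""
        if self.kind in ("uniform_scale", "rigid") and self.center is None:
            return replace(self, center=mesh.vertices.mean(axis=0))
        return self

    # point map -------------------------------------------------------
    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        if self.kind == "identity":
            return pts.copy()
        if self.kind == "uniform_scale":
            c = np.zeros(3) if self.center is None else np.asarray(self.center)
            return c + self.scale * (pts - c)
        if self.kind == "rigid":
            c = np.zeros(3) if self.center is None else np.asarray(self.center)
            R = _rotmat(np.asarray(self.rotvec, float))
            return c + (R @ (pts - c).T).T + np.asarray(self.translation, float)
        # closure_billow
        a, h, d = self.amplitude, self.height_ref, self.axial_drop
        R0 = self.radius_ref
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        rho = np.hypot(x, y)
        q = (z / h) ** 2
        g = 1.0 - (rho / R0) ** 4
        safe = np.where(rho > 1e-12, rho, 1.0)
        ux = -a * q * g * x / safe
        uy = -a * q * g * y / safe
        uz = -d * q * g
        return pts + np.stack([ux, uy, uz], axis=1)

    def jacobian(self, pts: np.ndarray) -> np.ndarray:
        """Analytic per-point deformation gradient F = d(phi)/dx, (n,3,3)."""
        pts = np.asarray(pts, dtype=float)
        n = len(pts)
        if self.kind == "identity":
            return np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
        if self.kind == "uniform_scale":
            return np.broadcast_to(self.scale * np.eye(3), (n, 3, 3)).copy()
        if self.kind == "rigid":
            R = _rotmat(np.asarray(self.rotvec, float))
            return np.broadcast_to(R, (n, 3, 3)).copy()
        a, h, d = self.amplitude, self.height_ref, self.axial_drop
        R0 = self.radius_ref
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        rho = np.hypot(x, y)
        safe = np.where(rho > 1e-12, rho, 1.0)
        q = (z / h) ** 2
        dq = 2 * z / h ** 2
        g = 1.0 - (rho / R0) ** 4
        dg = -4.0 * rho ** 3 / R0 ** 4          # dg/drho
        # d/dxj of g(rho)/rho = (dg*rho - g) * xj / rho^3
        w = (dg * safe - g) / safe ** 3
        F = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
        F[:, 0, 0] += -a * q * (g / safe + x * x * w)
        F[:, 0, 1] += -a * q * x * y * w
        F[:, 0, 2] += -a * dq * g * x / safe
        F[:, 1, 0] += -a * q * x * y * w
        F[:, 1, 1] += -a * q * (g / safe + y * y * w)
        F[:, 1, 2] += -a * dq * g * y / safe
        F[:, 2, 0] += -d * q * dg * x / safe
        F[:, 2, 1] += -d * q * dg * y / safe
        F[:, 2, 2] += -d * dq * g
        return F


def _rotmat(rotvec: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.from_rotvec(rotvec).as_matrix()


def apply_analytic_deformation(mesh: TriangleSurfaceMesh,
                               spec: DeformationSpec) -> TriangleSurfaceMesh:
    """Apply the spec's point-map to every vertex (topology preserved).

    Raises if any triangle is flipped or degenerated by the map.
    """
    spec = spec.resolved_for(mesh)
    out = mesh.with_vertices(spec.apply(mesh.vertices))
    dots = np.einsum("ij,ij->i", mesh.normals, out.normals)
    areas = out.areas
    bad = np.where((dots <= 0) | (areas <= 1e-12))[0]
    if bad.size:
        raise ValueError("deformation inverts or degenerates triangle(s): "
                         f"{bad[:10].tolist()}")
    return out


def annulus_trajectory(mesh: TriangleSurfaceMesh,
                       spec: DeformationSpec) -> np.ndarray:
    """Per-annulus-node total displacement (mm) under the spec's map."""
    if not len(mesh.annulus_nodes):
        raise ValueError("mesh has an empty annulus node set")
    spec = spec.resolved_for(mesh)
    pts = mesh.vertices[mesh.annulus_nodes]
    return spec.apply(pts) - pts


# --- image synthesis --------------------------------------------------


@dataclass(frozen=True)
class ImageSynthesisSpec:
    """Grid geometry and appearance model for synthetic frame pairs."""

    spacing: tuple = (0.6, 0.6, 0.6)
    extent: tuple = (64, 64, 64)
    blur_sigma: float = 0.8
    noise_sd: float = 5.0
    foreground_intensity: float = 180.0
    background_intensity: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @staticmethod
    def tee_preset(**kw) -> "ImageSynthesisSpec":
        """TEE-like: strong blur (effective B-mode resolution), low
        contrast and heavy noise."""
        defaults = dict(blur_sigma=1.2, noise_sd=12.0,
                        foreground_intensity=170.0,
                        background_intensity=50.0)
        defaults.update(kw)
        return ImageSynthesisSpec(**defaults)

    @staticmethod
    def ct_preset(**kw) -> "ImageSynthesisSpec":
        """CT-like: sharper, higher contrast, less noise."""
        defaults = dict(blur_sigma=0.5, noise_sd=3.0,
                        foreground_intensity=300.0,
                        background_intensity=30.0)
        defaults.update(kw)
        return ImageSynthesisSpec(**defaults)


class PhantomImages(NamedTuple):
    gray_open: ImageVolume
    gray_closed: ImageVolume
    labels_open: ImageVolume
    labels_closed: ImageVolume


def _reference_grid(meshes, spec: ImageSynthesisSpec) -> ImageVolume:
    lo = np.min([m.vertices.min(axis=0) for m in meshes], axis=0)
    hi = np.max([m.vertices.max(axis=0) for m in meshes], axis=0)
    half = max(m.thickness for m in meshes) / 2
    spacing = np.asarray(spec.spacing, float)
    extent = np.asarray(spec.extent, int)
    size_mm = spacing * (extent - 1)
    need = (hi - lo) + 2 * half + 4 * spacing  # >= 2-voxel margin each side
    if np.any(need > size_mm):
        raise ValueError(
            f"grid extent {tuple(extent)} at spacing {tuple(spacing)} too "
            f"small to hold both configurations with a 2-voxel margin")
    center = (hi + lo) / 2
    origin = center - size_mm / 2
    return ImageVolume(np.zeros(tuple(extent)), spacing, origin,
                       np.eye(3), kind="grayscale")


def synthesize_volumes(mesh_open: TriangleSurfaceMesh,
                       mesh_closed: TriangleSurfaceMesh,
                       spec: ImageSynthesisSpec) -> PhantomImages:
    """Rasterize both configurations and derive grayscale frames.

    Grayscale = background + contrast * gaussian-blurred indicator
    + seeded additive Gaussian noise (one independent draw per frame).
    """
    from scipy.ndimage import gaussian_filter
    ref = _reference_grid([mesh_open, mesh_closed], spec)
    labels_open = voxelize_surface(mesh_open, ref)
    labels_closed = voxelize_surface(mesh_closed, ref)
    rng = np.random.default_rng(spec.seed)
    sig_vox = spec.blur_sigma / np.asarray(spec.spacing)
    grays = []
    for lab in (labels_open, labels_closed):
        ind = (lab.values > 0).astype(np.float64)
        g = spec.background_intensity + (
            spec.foreground_intensity - spec.background_intensity
        ) * gaussian_filter(ind, sigma=sig_vox)
        if spec.noise_sd > 0:
            g = g + rng.normal(0.0, spec.noise_sd, size=g.shape)
        grays.append(ref.like(g, kind="grayscale"))
    return PhantomImages(grays[0], grays[1], labels_open, labels_closed)
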