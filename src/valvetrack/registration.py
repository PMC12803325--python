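"""Greedy multi-resolution affine + diffeomorphic registration.

Transforms are pull-back maps: ``T.apply(x_fixed)`` returns the
corresponding point in the moving image, the convention needed to
resample a moving image onto the fixed grid. The deformable stage
optimizes a stationary velocity field (SVF): per-iteration metric
forces are smoothed (gradient_sigma), folded into the velocity with a
first-order Lie-bracket (BCH) correction, the velocity re-smoothed
(field_sigma), and the displacement obtained by scaling-and-squaring,
which keeps the map diffeomorphic (positive Jacobian).

Metrics: SSD for binary/segmentation images, local NCC (box kernel,
default radius 2 voxels) for grayscale. Three pyramid levels with an
iteration schedule of 100x50x10 (coarse to fine) by default.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import ImageVolume
from .mesh import TriangleSurfaceMesh

__all__ = [
    "RegistrationSchedule",
    "SpatialTransform",
    "AffineTransform",
    "DenseTransform",
    "CompositeTransform",
    "affine_register",
    "deformable_register",
    "compose",
    "warp_image",
    "warp_mesh",
]


@dataclass
class RegistrationSchedule:
    """Multi-resolution schedule and metric configuration."""

    iterations: tuple = (100, 50, 10)    # coarse -> fine
    metric: str = "SSD"                  # SSD | NCC
    ncc_radius: int = 2                  # voxels (box kernel)
    gradient_sigma: float = 1.7          # voxels, update smoothing
    field_sigma: float = 0.7             # voxels, velocity smoothing
    svf_integration_steps: int = 6       # scaling-and-squaring doublings
    step_size: float = 2.0               # voxels, max update per iteration
    affine_iterations: tuple = None      # defaults to `iterations`

    def __post_init__(self):
        if len(self.iterations) < 1:
            raise ValueError("need at least one pyramid level")
        if self.metric not in ("SSD", "NCC"):
            raise ValueError("metric must be 'SSD' or 'NCC'")
        if self.ncc_radius < 0 or self.gradient_sigma < 0 \
                or self.field_sigma < 0:
            raise ValueError("radii and sigmas must be >= 0")
        if self.affine_iterations is None:
            self.affine_iterations = tuple(self.iterations)


# --- transforms -------------------------------------------------------


class SpatialTransform:
    """Base: a map from fixed-space world points to moving-space points."""

    kind = "base"

    def apply(self, pts: np.ndarray, strict: bool = False) -> np.ndarray:
        """Map fixed-space points to moving space. With strict=True a
        dense member raises on points outside its grid; otherwise the
        displacement is edge-clamped (background handling is done by
        the image resampler)."""
        raise NotImplementedError

    def inverse(self) -> "SpatialTransform":
        raise NotImplementedError


class AffineTransform(SpatialTransform):
    kind = "affine"

    def __init__(self, matrix: np.ndarray):
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine matrix is singular")

    @staticmethod
    def identity() -> "AffineTransform":
        return AffineTransform(np.eye(4))

    def apply(self, pts, strict: bool = False):
        pts = np.atleast_2d(np.asarray(pts, float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self):
        return AffineTransform(np.linalg.inv(self.matrix))

    def save(self, path):
        np.savetxt(str(path), self.matrix, fmt="%.17g")

    @staticmethod
    def load(path):
        return AffineTransform(np.loadtxt(str(path)))


class DenseTransform(SpatialTransform):
    """SVF-parameterized dense transform on a reference grid.

    velocity: (3, nx, ny, nz) stationary velocity in voxel units of
    `grid`; the exponentiated displacement (also voxel units) is cached.
    apply() adds the interpolated world-mm displacement to the input.
    """

    kind = "dense"

    def __init__(self, velocity: np.ndarray, grid: ImageVolume,
                 n_squarings: int = 6, displacement: np.ndarray = None):
        self.velocity = np.asarray(velocity, dtype=float)
        self.grid = grid
        self.n_squarings = int(n_squarings)
        if displacement is None:
            displacement = exp_velocity(self.velocity, self.n_squarings)
        self.displacement = displacement

    def apply(self, pts, strict: bool = False):
        pts = np.atleast_2d(np.asarray(pts, float))
        idx = self.grid.world_to_index(pts)
        shape = np.array(self.grid.shape)
        if strict and (np.any(idx < -0.51) or np.any(idx > shape - 0.49)):
            raise ValueError("point outside dense-field domain "
                             "(no extrapolation)")
        disp_vox = np.stack([
            ndimage.map_coordinates(self.displacement[c], idx.T, order=1,
                                    mode="nearest")
            for c in range(3)], axis=1)
        disp_mm = (self.grid.direction
                   @ (disp_vox * self.grid.spacing).T).T
        return pts + disp_mm

    def inverse(self):
        return DenseTransform(-self.velocity, self.grid, self.n_squarings)

    def jacobian_determinant(self) -> np.ndarray:
        return _jacobian_det(self.displacement)

    def save(self, path):
        """Displacement field as a 3-component NIfTI (world mm)."""
        from .image import write_image
        disp_mm = np.einsum("ab,bijk->aijk", self.grid.direction,
                            self.displacement
                            * self.grid.spacing[:, None, None, None])
        vol = np.moveaxis(disp_mm, 0, -1)
        import SimpleITK as sitk
        im = sitk.GetImageFromArray(
            np.ascontiguousarray(vol.transpose(2, 1, 0, 3)), isVector=True)
        im.SetSpacing(tuple(float(s) for s in self.grid.spacing))
        im.SetOrigin(tuple(float(o) for o in self.grid.origin))
        im.SetDirection(tuple(self.grid.direction.flatten()))
        sitk.WriteImage(im, str(path))


class CompositeTransform(SpatialTransform):
    """Ordered composition; members are applied first-to-last."""

    kind = "composite"

    def __init__(self, transforms):
        transforms = list(transforms)
        if not transforms:
            raise ValueError("empty transform list")
        self.transforms = transforms

    def apply(self, pts, strict: bool = False):
        out = np.atleast_2d(np.asarray(pts, float))
        for t in self.transforms:
            out = t.apply(out, strict=strict)
        return out

    def inverse(self):
        return CompositeTransform([t.inverse()
                                   for t in reversed(self.transforms)])

    def save(self, path):
        path = Path(path)
        manifest = []
        for i, t in enumerate(self.transforms):
            member = path.with_suffix(f".member{i}."
                                      + ("txt" if t.kind == "affine"
                                         else "nii.gz"))
            t.save(member)
            manifest.append({"kind": t.kind, "file": member.name})
        path.write_text(json.dumps(manifest, indent=2))


def compose(transforms) -> CompositeTransform:
    """Point-level composition (apply = sequential member application)."""
    flat = []
    for t in transforms:
        if isinstance(t, CompositeTransform):
            flat.extend(t.transforms)
        else:
            flat.append(t)
    return CompositeTransform(flat)


def numerical_inverse_points(t: SpatialTransform, pts: np.ndarray,
                             tol_mm: float = 0.05, max_iter: int = 50):
    """Fixed-point inversion: find y with t(y) = pts."""
    pts = np.atleast_2d(np.asarray(pts, float))
    y = pts.copy()
    for _ in range(max_iter):
        r = t.apply(y) - pts
        y = y - r
        if np.abs(r).max() < tol_mm:
            break
    return y


# --- SVF machinery ----------------------------------------------------


def _compose_disp(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Displacement of the composition x -> x + d2 + d1(x + d2)."""
    shape = d1.shape[1:]
    grid = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]].astype(float)
    coords = grid + d2
    out = np.empty_like(d1)
    for c in range(3):
        out[c] = d2[c] + ndimage.map_coordinates(d1[c], coords, order=1,
                                                 mode="nearest")
    return out


def exp_velocity(v: np.ndarray, n_squarings: int = 6) -> np.ndarray:
    """Scaling-and-squaring exponential of a stationary velocity field."""
    d = v / (2.0 ** n_squarings)
    for _ in range(n_squarings):
        d = _compose_disp(d, d)
    return d


def _jacobian_det(disp: np.ndarray) -> np.ndarray:
    J = np.empty(disp.shape[1:] + (3, 3))
    for c in range(3):
        for ax in range(3):
            J[..., c, ax] = np.gradient(disp[c], axis=ax)
        J[..., c, c] += 1.0
    return np.linalg.det(J)


def _lie_bracket(v: np.ndarray, u: np.ndarray) -> np.ndarray:
    """[v, u] = Jv u - Ju v (first-order BCH correction term)."""
    out = np.empty_like(v)
    gv = [[np.gradient(v[c], axis=ax) for ax in range(3)] for c in range(3)]
    gu = [[np.gradient(u[c], axis=ax) for ax in range(3)] for c in range(3)]
    for c in range(3):
        out[c] = sum(gv[c][ax] * u[ax] - gu[c][ax] * v[ax]
                     for ax in range(3))
    return out


# --- pyramid and sampling --------------------------------------------


def _downsample(arr: np.ndarray) -> np.ndarray:
    sm = ndimage.gaussian_filter(arr, sigma=1.0)
    return sm[::2, ::2, ::2]


def _pyramid(arr: np.ndarray, levels: int):
    out = [np.asarray(arr, dtype=float)]
    for _ in range(levels - 1):
        out.append(_downsample(out[-1]))
    return out[::-1]  # coarse first


def _warp_arr(moving: np.ndarray, disp: np.ndarray) -> np.ndarray:
    shape = moving.shape
    grid = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]].astype(float)
    return ndimage.map_coordinates(moving, grid + disp, order=1,
                                   mode="constant", cval=0.0)


# --- metric forces ----------------------------------------------------


def _ssd_force(fixed: np.ndarray, warped: np.ndarray):
    """(metric value, force field pointing downhill for the moving warp)."""
    diff = warped - fixed
    grad = np.stack(np.gradient(warped), axis=0)
    force = -2.0 * diff[None] * grad
    return float(np.mean(diff * diff)), force


def _ncc_force(fixed: np.ndarray, warped: np.ndarray, radius: int):
    """Local normalized cross-correlation (box kernel) value and force."""
    size = 2 * radius + 1
    mean = lambda a: ndimage.uniform_filter(a, size=size, mode="nearest")
    fi = fixed - mean(fixed)
    wa = warped - mean(warped)
    sff = mean(fi * fi)
    sww = mean(wa * wa)
    sfw = mean(fi * wa)
    # floor each local variance separately: patches with little
    # structure (background, pure noise) must neither blow up the
    # correlation force nor compete with genuinely structured regions,
    # so the floor is a substantial fraction of the global variance
    eps = (0.3 * float(fixed.std())) ** 2 + 1e-12
    denom = (sff + eps) * (sww + eps)
    cc = sfw * sfw / denom
    # force = d(cc)/d(warped intensity) * grad(warped)
    coef = 2.0 * sfw / denom * (fi - sfw / (sww + eps) * wa)
    grad = np.stack(np.gradient(warped), axis=0)
    force = coef[None] * grad
    return float(-np.mean(cc)), force


def _metric_and_force(fixed, warped, sched: RegistrationSchedule):
    if sched.metric == "SSD":
        return _ssd_force(fixed, warped)
    return _ncc_force(fixed, warped, sched.ncc_radius)


# --- affine registration ---------------------------------------------


def _level_grid(img: ImageVolume, level_shape) -> ImageVolume:
    """Geometry of a factor-2^k downsampled grid (same origin frame)."""
    factor = np.array(img.shape) / np.array(level_shape)
    return ImageVolume(np.zeros(level_shape), img.spacing * factor,
                       img.origin, img.direction, "grayscale")


def _apply_affine_index(moving: np.ndarray, A_idx: np.ndarray,
                        b_idx: np.ndarray) -> np.ndarray:
    return ndimage.affine_transform(moving, A_idx, offset=b_idx, order=1,
                                    mode="constant", cval=0.0)


def affine_register(fixed: ImageVolume, moving: ImageVolume,
                    sched: RegistrationSchedule = None) -> AffineTransform:
    """Gradient-descent affine registration over the image pyramid.

    Initialized by matching the (geometric) centers of the two grids;
    guarantees the final metric does not exceed the initial one.
    Returns the world-mm pull-back map fixed -> moving.
    """
    sched = sched or RegistrationSchedule()
    if fixed.values.size == 0 or moving.values.size == 0:
        raise ValueError("empty image")
    if float(np.ptp(fixed.values)) == 0 or float(np.ptp(moving.values)) == 0:
        raise ValueError("constant image cannot drive registration")
    levels = len(sched.affine_iterations)
    fpyr = _pyramid(np.asarray(fixed.values, float), levels)
    mpyr = _pyramid(np.asarray(moving.values, float), levels)

    # world-frame affine x_mov = A x_fix + b, initialized by matching the
    # intensity centers of the two images (their geometric grid centers
    # when the intensity distributions are symmetric)
    cf = fixed.index_to_world((np.array(fixed.shape) - 1) / 2.0)
    A = np.eye(3)
    b = _intensity_center(moving) - _intensity_center(fixed)

    for lvl in range(levels):
        fl, ml = fpyr[lvl], mpyr[lvl]
        fgrid = _level_grid(fixed, fl.shape)
        mgrid = _level_grid(moving, ml.shape)
        n_iter = sched.affine_iterations[lvl]
        A, b = _affine_descent(fl, ml, fgrid, mgrid, A, b, cf, n_iter, sched)

    mat = np.eye(4)
    mat[:3, :3] = A
    mat[:3, 3] = b + cf - A @ cf  # stored about the origin
    return AffineTransform(mat)


def _intensity_center(img: ImageVolume) -> np.ndarray:
    w = np.asarray(img.values, float)
    # suppress the background mode so thin bright structures dominate
    w = np.maximum(w - (w.mean() + 2.0 * w.std()), 0.0)
    if w.sum() <= 0:
        w = np.maximum(np.asarray(img.values, float)
                       - float(np.mean(img.values)), 0.0)
    tot = w.sum()
    if tot <= 0:
        return img.index_to_world((np.array(img.shape) - 1) / 2.0)
    idx = np.indices(img.shape).reshape(3, -1)
    com_idx = (idx * w.reshape(1, -1)).sum(axis=1) / tot
    return img.index_to_world(com_idx)


def _affine_world_to_index(A, b, cf, fgrid, mgrid):
    """Convert world affine (about cf) into an index-space map
    idx_mov = Ai idx_fix + bi for ndimage.affine_transform."""
    Df = fgrid.direction * fgrid.spacing[None, :]
    Dm_inv = np.linalg.inv(mgrid.direction * mgrid.spacing[None, :])
    Ai = Dm_inv @ A @ Df
    bi = Dm_inv @ (A @ (fgrid.origin - cf) + cf + b - mgrid.origin)
    return Ai, bi


def _affine_metric(fl, ml, fgrid, mgrid, A, b, cf, sched):
    Ai, bi = _affine_world_to_index(A, b, cf, fgrid, mgrid)
    warped = _apply_affine_index(ml, Ai, bi)
    val, force = _metric_and_force(fl, warped, sched)
    if not np.isfinite(val):
        raise ValueError("non-finite registration metric")
    return val, force, warped


def _affine_gradients(fl, fgrid, cf, force):
    """World-space metric gradients (downhill) wrt A and b."""
    idx = np.mgrid[0:fl.shape[0], 0:fl.shape[1], 0:fl.shape[2]]
    world = (fgrid.origin[:, None, None, None]
             + np.einsum("ab,b...->a...", fgrid.direction,
                         idx * fgrid.spacing[:, None, None, None]))
    rel = world - cf[:, None, None, None]
    # chain the index-space force to world: grad_world = M^-T grad_idx
    M = fgrid.direction * fgrid.spacing[None, :]
    fw = np.einsum("ab,b...->a...", np.linalg.inv(M.T), force)
    gA = (fw.reshape(3, -1) @ rel.reshape(3, -1).T) / fl.size
    gb = fw.reshape(3, -1).mean(axis=1)
    return gA, gb


def _affine_descent(fl, ml, fgrid, mgrid, A, b, cf, n_iter, sched):
    """Backtracking gradient descent at one level: a translation-only
    phase (robust capture) followed by the full affine."""
    extent = float(np.max(np.array(fl.shape) * fgrid.spacing))
    val, force, _ = _affine_metric(fl, ml, fgrid, mgrid, A, b, cf, sched)
    n_trans = max(int(n_iter) // 2, 1)
    for phase, n_phase in (("trans", n_trans), ("full", int(n_iter)),
                           ("trans", n_trans)):
        step = 1.0 * float(min(fgrid.spacing))
        for _ in range(n_phase):
            gA, gb = _affine_gradients(fl, fgrid, cf, force)
            if phase == "trans":
                gA = np.zeros((3, 3))
            # scale linear-part gradient so a unit step moves the far
            # corner of the image by `step` mm
            gnorm = max(np.abs(gb).max(), np.abs(gA).max() * extent / 2.0,
                        1e-30)
            dA, db = gA / gnorm, gb / gnorm
            improved = False
            s = step
            for _ in range(8):
                A_t = A + s * dA
                b_t = b + s * db
                try:
                    v_t, f_t, _ = _affine_metric(fl, ml, fgrid, mgrid,
                                                 A_t, b_t, cf, sched)
                except np.linalg.LinAlgError:
                    s *= 0.5
                    continue
                if v_t < val:
                    A, b, val, force = A_t, b_t, v_t, f_t
                    improved = True
                    break
                s *= 0.5
            if improved:
                step = min(max(s * 2.0, 0.05 * float(min(fgrid.spacing))),
                           2.0 * float(min(fgrid.spacing)))
            else:
                step *= 0.25
                if step < 1e-4 * float(min(fgrid.spacing)):
                    break
    return A, b


# --- deformable registration -----------------------------------------


def deformable_register(fixed: ImageVolume, moving: ImageVolume,
                        init: SpatialTransform = None,
                        sched: RegistrationSchedule = None
                        ) -> DenseTransform:
    """Greedy SVF optimization; returns the dense pull-back transform.

    The moving image is first resampled through `init` (usually the
    affine stage); the returned dense transform therefore acts on that
    pre-warped moving image — compose as ``compose([dense, init])`` to
    map fixed coordinates all the way into the original moving frame.
    """
    sched = sched or RegistrationSchedule()
    if init is not None:
        moving_arr = warp_image(moving, init, mode="linear",
                                out_ref=fixed).values.astype(float)
    else:
        moving_arr = np.asarray(moving.values, float)
        if moving_arr.shape != tuple(fixed.shape):
            raise ValueError("without init, fixed and moving must share "
                             "a grid")
    levels = len(sched.iterations)
    fpyr = _pyramid(np.asarray(fixed.values, float), levels)
    mpyr = _pyramid(moving_arr, levels)

    v = None
    for lvl in range(levels):
        fl, ml = fpyr[lvl], mpyr[lvl]
        if v is None:
            v = np.zeros((3,) + fl.shape)
        else:
            v = _upsample_velocity(v, fl.shape)
        v = _svf_level(fl, ml, v, sched.iterations[lvl], sched)
    disp = exp_velocity(v, sched.svf_integration_steps)
    return DenseTransform(v, _level_grid(fixed, fixed.shape),
                          sched.svf_integration_steps, displacement=disp)


def _upsample_velocity(v: np.ndarray, shape) -> np.ndarray:
    out = np.empty((3,) + tuple(shape))
    src = np.array(v.shape[1:], float)
    dst = np.array(shape, float)
    grid = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]].astype(float)
    for ax in range(3):
        grid[ax] *= (src[ax] - 1) / max(dst[ax] - 1, 1)
    scale = dst / src
    for c in range(3):
        out[c] = ndimage.map_coordinates(v[c], grid, order=1,
                                         mode="nearest") * scale[c]
    return out


def _svf_level(fl, ml, v, n_iter, sched: RegistrationSchedule):
    """Guarded greedy SVF iteration at one pyramid level.

    Each update is accepted only if the metric improves; otherwise the
    step scale is halved. This keeps the level monotone in the metric
    while allowing full greedy progress when the force field is
    informative."""
    disp = exp_velocity(v, sched.svf_integration_steps)
    val, force = _metric_and_force(fl, _warp_arr(ml, disp), sched)
    scale = sched.step_size
    for _ in range(int(n_iter)):
        u = np.stack([ndimage.gaussian_filter(force[c], sched.gradient_sigma)
                      for c in range(3)])
        umax = np.abs(u).max()
        if umax < 1e-30:
            break
        u *= scale / umax
        # BCH with first-order Lie bracket correction
        v_new = v + u + 0.5 * _lie_bracket(v, u)
        v_new = np.stack([ndimage.gaussian_filter(v_new[c],
                                                  sched.field_sigma)
                          for c in range(3)])
        disp_new = exp_velocity(v_new, sched.svf_integration_steps)
        if _jacobian_det(disp_new).min() <= 0:
            # folding: treat as a rejected step
            scale *= 0.5
            if scale < 0.02 * sched.step_size:
                break
            continue
        val_new, force_new = _metric_and_force(fl, _warp_arr(ml, disp_new),
                                               sched)
        if val_new < val:
            v, disp, val, force = v_new, disp_new, val_new, force_new
            scale = min(scale * 1.25, sched.step_size)
        else:
            scale *= 0.5
            if scale < 0.02 * sched.step_size:
                break
    return v


# --- warping ----------------------------------------------------------


def warp_image(image: ImageVolume, t: SpatialTransform,
               mode: str = "linear", out_ref: ImageVolume = None,
               label_sigma_vox: float = 0.2) -> ImageVolume:
    """Resample `image` through the pull-back map t onto out_ref's grid.

    linear: trilinear interpolation (background 0 outside).
    label: per-label Gaussian pre-smoothing (sigma 0.2 voxel) then
    argmax voting; the output label set is a subset of the input's.
    """
    if mode not in ("linear", "label"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    ref = out_ref if out_ref is not None else image
    idx = np.indices(ref.shape).reshape(3, -1).T
    pts = ref.index_to_world(idx)
    mapped = t.apply(pts)
    midx = image.world_to_index(mapped).T  # (3, n)
    if mode == "linear":
        vals = ndimage.map_coordinates(np.asarray(image.values, float),
                                       midx, order=1, mode="constant",
                                       cval=0.0)
        return ref.like(vals.reshape(ref.shape), kind="grayscale")
    labels = np.unique(image.values)
    scores = np.full(len(idx), -np.inf)
    out = np.zeros(len(idx), dtype=np.int64)
    for lab in labels:
        ind = (image.values == lab).astype(float)
        if label_sigma_vox > 0:
            ind = ndimage.gaussian_filter(ind, sigma=label_sigma_vox)
        sc = ndimage.map_coordinates(ind, midx, order=1, mode="constant",
                                     cval=1.0 if lab == 0 else 0.0)
        take = sc > scores
        out[take] = lab
        scores[take] = sc[take]
    return ref.like(out.reshape(ref.shape), kind="labels")


def warp_mesh(mesh: TriangleSurfaceMesh, t: SpatialTransform
              ) -> TriangleSurfaceMesh:
    """Apply t to every vertex (world mm); topology/labels/sets kept.

    Note: t is a pull-back map; to push a mesh forward along a
    registration, pass ``t.inverse()``. Vertices outside a dense
    member's domain raise (no extrapolation).
    """
    return mesh.with_vertices(t.apply(mesh.vertices, strict=True))
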