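"""Low-level vectorized triangle geometry kernels.

Exact closest-point-on-triangle queries with cKDTree candidate pruning;
used by surface voxelization, surface-distance evaluation and remeshing.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    p0, p1, p2 = (vertices[faces[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)


def triangle_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Unit normals following the face winding (right-hand rule)."""
    p0, p1, p2 = (vertices[faces[:, i]] for i in range(3))
    n = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(n, axis=1)
    norm = np.where(norm < 1e-300, 1.0, norm)
    return n / norm[:, None]


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle tri[i] to points[i] (Ericson, vectorized).

    points: (n, 3); tri: (n, 3, 3). Returns (n, 3).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class SurfaceDistanceQuery:
    """Nearest-point queries against a triangle soup.

    Candidate faces come from the k nearest face centroids plus the faces
    incident to the nearest vertex, then the exact point-triangle distance
    is minimized over candidates.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 16):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.k = int(min(k, len(self.faces)))
        p = self.vertices[self.faces]
        self._centroids = p.mean(axis=1)
        self._ctree = cKDTree(self._centroids)
        self._vtree = cKDTree(self.vertices)
        # vertex -> incident faces (ragged, stored flat)
        nv = len(self.vertices)
        counts = np.zeros(nv, dtype=np.int64)
        np.add.at(counts, self.faces.ravel(), 1)
        order = np.argsort(self.faces.ravel(), kind="stable")
        self._vf_flat = np.repeat(np.arange(len(self.faces)), 3)[order]
        self._vf_start = np.concatenate([[0], np.cumsum(counts)])

    def _vertex_faces(self, v: np.ndarray) -> list[np.ndarray]:
        return [self._vf_flat[self._vf_start[i]:self._vf_start[i + 1]] for i in v]

    def query(self, points: np.ndarray):
        """Return (distances, closest_points, face_indices) for each point."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        _, cand = self._ctree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        _, nv = self._vtree.query(points)
        vf = self._vertex_faces(np.atleast_1d(nv))
        best_d = np.full(n, np.inf)
        best_p = np.zeros((n, 3))
        best_f = np.zeros(n, dtype=np.int64)

        # pack candidates into one flat batch
        extra = max(len(f) for f in vf) if vf else 0
        width = cand.shape[1] + extra
        flat = np.zeros((n, width), dtype=np.int64)
        flat[:, :cand.shape[1]] = cand
        for i, f in enumerate(vf):
            flat[i, cand.shape[1]:cand.shape[1] + len(f)] = f
            if len(f) < extra:
                flat[i, cand.shape[1] + len(f):] = cand[i, 0]
        fi = flat.ravel()
        pi = np.repeat(points, width, axis=0)
        cp = closest_point_on_triangles(pi, self.vertices[self.faces[fi]])
        d = np.linalg.norm(cp - pi, axis=1).reshape(n, width)
        j = np.argmin(d, axis=1)
        rows = np.arange(n)
        best_d = d[rows, j]
        best_f = flat[rows, j]
        best_p = cp.reshape(n, width, 3)[rows, j]
        return best_d, best_p, best_f


def sample_triangles(vertices: np.ndarray, faces: np.ndarray, step: float):
    """Deterministic barycentric-grid samples on each triangle.

    Returns (points, face_index). Sample spacing is at most `step` so that
    the point cloud is within ~step/2 of the continuous surface everywhere.
    """
    pts_out = []
    fid_out = []
    p = vertices[faces]
    e1 = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
    e2 = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    e3 = np.linalg.norm(p[:, 2] - p[:, 1], axis=1)
    lmax = np.maximum(e1, np.maximum(e2, e3))
    nsub = np.maximum(1, np.ceil(lmax / step).astype(int))
    for n in np.unique(nsub):
        sel = np.where(nsub == n)[0]
        # barycentric lattice with n subdivisions
        ij = [(i, j) for i in range(n + 1) for j in range(n + 1 - i)]
        bary = np.array([[i / n, j / n, (n - i - j) / n] for i, j in ij])
        pts = np.einsum("sk,fkd->fsd", bary, p[sel])
        pts_out.append(pts.reshape(-1, 3))
        fid_out.append(np.repeat(sel, len(bary)))
    return np.concatenate(pts_out), np.concatenate(fid_out)
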