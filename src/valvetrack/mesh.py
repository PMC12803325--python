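"""Triangle surface meshes for valve leaflets.

The central container is :class:`TriangleSurfaceMesh`: a medial leaflet
surface in world millimetres with per-element leaflet labels, a uniform
shell thickness, and the two boundary node sets that drive the closure
simulation -- the annulus (attachment ring, prescribed displacement) and
the leaflet free edges (unconstrained).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import (SurfaceDistanceQuery, triangle_areas,
                        triangle_normals)

__all__ = [
    "TriangleSurfaceMesh",
    "extract_node_sets",
    "smooth_preserving_boundary",
    "remesh_to_edge_length",
    "save_mesh",
    "load_mesh",
]


@dataclass
class TriangleSurfaceMesh:
    """Open triangle surface with leaflet labels and boundary node sets.

    vertices : (n, 3) float, world mm
    faces : (m, 3) int, 0-based CCW triples
    leaflet_label : (m,) int, label per element (1-based leaflet ids)
    annulus_nodes / free_edge_nodes : int arrays of vertex indices
    thickness : uniform shell thickness in mm
    """

    vertices: np.ndarray
    faces: np.ndarray
    leaflet_label: np.ndarray = None
    annulus_nodes: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    free_edge_nodes: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    thickness: float = 1.2

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.leaflet_label is None:
            self.leaflet_label = np.ones(len(self.faces), dtype=np.int64)
        self.leaflet_label = np.asarray(self.leaflet_label, dtype=np.int64)
        self.annulus_nodes = np.asarray(self.annulus_nodes, dtype=np.int64)
        self.free_edge_nodes = np.asarray(self.free_edge_nodes, dtype=np.int64)
        self.validate()

    def validate(self):
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if len(self.faces) and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if len(self.leaflet_label) != len(self.faces):
            raise ValueError("one leaflet label per face required")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if np.intersect1d(self.annulus_nodes, self.free_edge_nodes).size:
            raise ValueError("annulus and free-edge node sets must be disjoint")

    # --- geometry -----------------------------------------------------
    @property
    def areas(self) -> np.ndarray:
        return triangle_areas(self.vertices, self.faces)

    @property
    def normals(self) -> np.ndarray:
        return triangle_normals(self.vertices, self.faces)

    @property
    def centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    @property
    def edges_unique(self) -> np.ndarray:
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        return np.unique(e, axis=0)

    @property
    def edge_lengths(self) -> np.ndarray:
        e = self.edges_unique
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                              axis=1)

    @property
    def median_edge_length(self) -> float:
        return float(np.median(self.edge_lengths))

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def boundary_edges(self) -> np.ndarray:
        """Edges used by exactly one face, as sorted (n, 2) index pairs."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def boundary_vertices(self) -> np.ndarray:
        return np.unique(self.boundary_edges())

    def assert_no_degenerate(self, min_area: float = 1e-12):
        bad = np.where(self.areas <= min_area)[0]
        if bad.size:
            raise ValueError(f"degenerate triangle(s) with area <= {min_area}: "
                             f"elements {bad[:10].tolist()}")

    def with_vertices(self, vertices: np.ndarray) -> "TriangleSurfaceMesh":
        """Same topology/labels/sets with replaced vertex coordinates."""
        return replace(self, vertices=np.asarray(vertices, dtype=np.float64))

    def copy(self) -> "TriangleSurfaceMesh":
        return TriangleSurfaceMesh(
            self.vertices.copy(), self.faces.copy(), self.leaflet_label.copy(),
            self.annulus_nodes.copy(), self.free_edge_nodes.copy(),
            self.thickness)


# --- boundary decomposition ------------------------------------------


def _boundary_chains(bedges: np.ndarray):
    """Split the boundary graph into chains between junction vertices.

    Junctions are boundary vertices of boundary-degree >= 3 (commissures
    have degree 4). Without junctions every connected component is a
    closed loop. Returns a list of vertex-index paths; closed paths
    repeat the first vertex at the end.
    """
    adj: dict[int, list[int]] = {}
    for u, v in bedges:
        adj.setdefault(int(u), []).append(int(v))
        adj.setdefault(int(v), []).append(int(u))
    degree = {v: len(n) for v, n in adj.items()}
    junctions = {v for v, d in degree.items() if d >= 3}
    used = set()
    chains = []

    def edge_key(u, v):
        return (min(u, v), max(u, v), adj[u].count(v))

    used_edges = set()

    def take(u, v):
        key = (min(u, v), max(u, v))
        used_edges.add(key)

    def is_used(u, v):
        return (min(u, v), max(u, v)) in used_edges

    # chains starting at junctions
    for j in sorted(junctions):
        for nb in sorted(adj[j]):
            if is_used(j, nb):
                continue
            path = [j, nb]
            take(j, nb)
            while path[-1] not in junctions:
                cur = path[-1]
                nxt = [w for w in adj[cur] if not is_used(cur, w)]
                if not nxt:
                    break
                w = sorted(nxt)[0]
                take(cur, w)
                path.append(w)
            chains.append(path)
    # remaining pure loops (no junction on them)
    for v in sorted(adj):
        for nb in sorted(adj[v]):
            if is_used(v, nb):
                continue
            path = [v, nb]
            take(v, nb)
            while True:
                cur, prev = path[-1], path[-2]
                nxt = [w for w in adj[cur] if not is_used(cur, w)]
                if not nxt:
                    break
                w = sorted(nxt)[0]
                take(cur, w)
                path.append(w)
                if w == v:
                    break
            chains.append(path)
    return chains, junctions


def extract_node_sets(mesh: TriangleSurfaceMesh):
    """Decompose the mesh boundary into the annulus loop and free-edge curves.

    The annulus is identified as the closed boundary cycle farthest from
    the valve's central axis (the attachment ring sits at maximal radius,
    whereas free edges sweep inward). For a boundary without junction
    vertices and a single loop (e.g. a disc), that loop is the annulus
    and the free-edge set is empty.

    Returns ``(annulus_nodes, free_edge_curves)`` where the second item
    is a list of vertex-index paths.
    """
    bedges = mesh.boundary_edges()
    if not len(bedges):
        raise ValueError("mesh has no boundary; expected a surface with boundary")
    chains, junctions = _boundary_chains(bedges)

    # central axis: principal normal direction of the surface, through the
    # area centroid
    areas = mesh.areas
    centroid = (mesh.centroids * areas[:, None]).sum(0) / areas.sum()
    # axis = smallest-variance direction of boundary vertices is unstable
    # for crown shapes; use the mean face normal direction instead
    mean_n = (mesh.normals * areas[:, None]).sum(0)
    if np.linalg.norm(mean_n) < 1e-9:
        # fall back to PCA of the vertices
        u, s, vt = np.linalg.svd(mesh.vertices - mesh.vertices.mean(0))
        mean_n = vt[2]
    axis = mean_n / np.linalg.norm(mean_n)

    def mean_radius(path):
        p = mesh.vertices[np.asarray(path, int)] - centroid
        radial = p - np.outer(p @ axis, axis)
        return float(np.linalg.norm(radial, axis=1).mean())

    if not junctions:
        # each chain is already a closed loop
        loops = [c for c in chains if c[0] == c[-1]]
        if not loops:
            raise ValueError("boundary decomposition failed: open chains "
                             "without junction vertices")
        radii = [mean_radius(c) for c in loops]
        order = np.argsort(radii)[::-1]
        if len(loops) > 1 and radii[order[0]] < 1.25 * radii[order[1]]:
            raise ValueError(
                "ambiguous annulus: two closed boundary loops have similar "
                f"mean radius ({radii[order[0]]:.2f} vs {radii[order[1]]:.2f} mm)")
        annulus = np.unique(loops[order[0]])
        free_curves = [loops[i] for i in range(len(loops)) if i != order[0]]
        return annulus, free_curves

    # with junctions: pick the outermost set of chains forming a closed cycle
    order = np.argsort([-mean_radius(c) for c in chains])
    selected = []
    deg: dict[int, int] = {}

    def can_add(path):
        for v in (path[0], path[-1]):
            if deg.get(v, 0) >= 2:
                return False
        return True

    for i in order:
        c = chains[i]
        if c[0] == c[-1] and len(junctions) > 1:
            continue  # closed sub-loop cannot be part of the annulus ring
        if not can_add(c):
            continue
        selected.append(i)
        deg[c[0]] = deg.get(c[0], 0) + 1
        deg[c[-1]] = deg.get(c[-1], 0) + 1
        if all(deg.get(j, 0) == 2 for j in junctions):
            break
    if not all(deg.get(j, 0) == 2 for j in junctions):
        raise ValueError("boundary decomposition failed: could not assemble a "
                         "closed annulus cycle through the junction vertices")
    annulus = np.unique(np.concatenate([chains[i] for i in selected]))
    free_curves = [chains[i] for i in range(len(chains)) if i not in selected]
    # junction vertices belong to the annulus; free curves keep them only
    # as endpoints
    return annulus, free_curves


# --- smoothing --------------------------------------------------------


def smooth_preserving_boundary(mesh: TriangleSurfaceMesh, iterations: int,
                               step: float = 0.5) -> TriangleSurfaceMesh:
    """Umbrella (uniform Laplacian) smoothing with boundary vertices fixed.

    Interior vertices move toward the mean of their 1-ring by `step`
    each iteration; every boundary vertex stays exactly in place.
    """
    if not 0 < step < 1:
        raise ValueError("step must lie in (0, 1)")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mesh.copy()
    v = mesh.vertices.copy()
    n = len(v)
    e = mesh.edges_unique
    boundary = np.zeros(n, dtype=bool)
    boundary[mesh.boundary_vertices()] = True
    interior = ~boundary
    for _ in range(int(iterations)):
        acc = np.zeros_like(v)
        cnt = np.zeros(n)
        np.add.at(acc, e[:, 0], v[e[:, 1]])
        np.add.at(acc, e[:, 1], v[e[:, 0]])
        np.add.at(cnt, e[:, 0], 1)
        np.add.at(cnt, e[:, 1], 1)
        mean = acc[interior] / cnt[interior, None]
        v[interior] += step * (mean - v[interior])
    return mesh.with_vertices(v)


# --- isotropic remeshing ---------------------------------------------


class _EditableMesh:
    """Mutable triangle mesh for incremental remeshing."""

    def __init__(self, vertices, faces, boundary_flags):
        self.v = [np.array(p, dtype=float) for p in vertices]
        self.f = [list(map(int, f)) for f in faces]
        self.alive = [True] * len(self.f)
        self.bnd = list(map(bool, boundary_flags))
        self.vf: list[set] = [set() for _ in self.v]
        for i, f in enumerate(self.f):
            for vid in f:
                self.vf[vid].add(i)

    def face_verts(self, i):
        return [self.v[j] for j in self.f[i]]

    def edges(self):
        seen = {}
        for i, f in enumerate(self.f):
            if not self.alive[i]:
                continue
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                key = (a, b) if a < b else (b, a)
                seen.setdefault(key, []).append(i)
        return seen

    def add_vertex(self, p, boundary):
        self.v.append(np.asarray(p, float))
        self.bnd.append(boundary)
        self.vf.append(set())
        return len(self.v) - 1

    def add_face(self, f):
        self.f.append(list(f))
        self.alive.append(True)
        idx = len(self.f) - 1
        for vid in f:
            self.vf[vid].add(idx)
        return idx

    def kill_face(self, i):
        self.alive[i] = False
        for vid in self.f[i]:
            self.vf[vid].discard(i)

    def face_normal(self, i):
        a, b, c = self.face_verts(i)
        n = np.cross(b - a, c - a)
        ln = np.linalg.norm(n)
        return n / ln if ln > 1e-300 else np.zeros(3)

    def face_area(self, i):
        a, b, c = self.face_verts(i)
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a))

    def split_pass(self, high):
        """Midpoint-split all edges longer than `high` (batched)."""
        any_split = True
        rounds = 0
        while any_split and rounds < 12:
            rounds += 1
            any_split = False
            edges = self.edges()
            items = [((a, b), fs) for (a, b), fs in edges.items()
                     if np.linalg.norm(self.v[a] - self.v[b]) > high]
            items.sort(key=lambda kv: -np.linalg.norm(self.v[kv[0][0]]
                                                      - self.v[kv[0][1]]))
            dirty = set()
            for (a, b), fs in items:
                if any(f in dirty or not self.alive[f] for f in fs):
                    continue
                mid = self.add_vertex(0.5 * (self.v[a] + self.v[b]),
                                      boundary=(len(fs) == 1))
                for fidx in fs:
                    f = self.f[fidx]
                    c = [x for x in f if x not in (a, b)][0]
                    # preserve winding
                    i_a = f.index(a)
                    if f[(i_a + 1) % 3] == b:
                        n1, n2 = (a, mid, c), (mid, b, c)
                    else:
                        n1, n2 = (mid, a, c), (b, mid, c)
                    self.kill_face(fidx)
                    dirty.add(self.add_face(n1))
                    dirty.add(self.add_face(n2))
                any_split = True

    def vertex_neighbors(self, vid):
        out = set()
        for f in self.vf[vid]:
            out.update(self.f[f])
        out.discard(vid)
        return out

    def collapse_pass(self, low, high):
        edges = self.edges()
        touched = set()
        for (a, b), fs in sorted(edges.items(),
                                 key=lambda kv: np.linalg.norm(self.v[kv[0][0]]
                                                               - self.v[kv[0][1]])):
            if np.linalg.norm(self.v[a] - self.v[b]) >= low:
                break
            if a in touched or b in touched:
                continue
            if self.bnd[a] and self.bnd[b]:
                continue
            if not all(self.alive[f] for f in fs):
                continue
            # link condition
            shared = self.vertex_neighbors(a) & self.vertex_neighbors(b)
            opp = set()
            for f in fs:
                opp.update(x for x in self.f[f] if x not in (a, b))
            if shared != opp:
                continue
            if self.bnd[a]:
                keep, drop, pos = a, b, self.v[a]
            elif self.bnd[b]:
                keep, drop, pos = b, a, self.v[b]
            else:
                keep, drop = a, b
                pos = 0.5 * (self.v[a] + self.v[b])
            # validity: no long edges, no normal flips
            ok = True
            new_faces = []
            for fidx in list(self.vf[drop]):
                if fidx in fs:
                    continue
                f = [keep if x == drop else x for x in self.f[fidx]]
                if len(set(f)) < 3:
                    ok = False
                    break
                new_faces.append((fidx, f))
            if ok:
                old_keep = self.v[keep].copy()
                self.v[keep] = pos
                for fidx, f in new_faces:
                    pa, pb, pc = self.v[f[0]], self.v[f[1]], self.v[f[2]]
                    n_new = np.cross(pb - pa, pc - pa)
                    area2 = np.linalg.norm(n_new)
                    if area2 < 1e-12:
                        ok = False
                        break
                    self.v[keep] = old_keep
                    n_old = self.face_normal(fidx)
                    self.v[keep] = pos
                    if np.dot(n_new / area2, n_old) < 0.2:
                        ok = False
                        break
                    for u, w in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                        if np.linalg.norm(self.v[u] - self.v[w]) > high:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    self.v[keep] = old_keep
            if not ok:
                continue
            for fidx in fs:
                self.kill_face(fidx)
            for fidx, f in new_faces:
                self.kill_face(fidx)
                self.add_face(f)
            touched.update(shared)
            touched.add(keep)
            touched.add(drop)

    def flip_pass(self):
        edges = self.edges()
        valence = [len(self.vertex_neighbors(i)) if self.vf[i] else 0
                   for i in range(len(self.v))]
        existing = set(edges.keys())
        touched = set()
        for (a, b), fs in sorted(edges.items()):
            if len(fs) != 2:
                continue
            if any(x in touched for x in (a, b)):
                continue
            if not all(self.alive[f] for f in fs):
                continue
            f1, f2 = fs
            c = [x for x in self.f[f1] if x not in (a, b)][0]
            d = [x for x in self.f[f2] if x not in (a, b)][0]
            key_cd = (c, d) if c < d else (d, c)
            if key_cd in existing:
                continue

            def tgt(v):
                return 4 if self.bnd[v] else 6

            def cost(vals):
                return sum((valence[v] + dv - tgt(v)) ** 2
                           for v, dv in vals)

            before = cost([(a, 0), (b, 0), (c, 0), (d, 0)])
            after = cost([(a, -1), (b, -1), (c, 1), (d, 1)])
            if after >= before:
                continue
            # geometric validity: new triangles must agree with old normals
            n_old = self.face_normal(f1) + self.face_normal(f2)
            ln = np.linalg.norm(n_old)
            if ln < 1e-12:
                continue
            n_old /= ln
            t1 = (c, d, a) if self._winding_ok(f1, a, b) else (d, c, a)
            t2 = (d, c, b) if self._winding_ok(f1, a, b) else (c, d, b)
            ok = True
            for t in (t1, t2):
                pa, pb, pc = self.v[t[0]], self.v[t[1]], self.v[t[2]]
                n = np.cross(pb - pa, pc - pa)
                area2 = np.linalg.norm(n)
                if area2 < 1e-12 or np.dot(n / area2, n_old) < 0.3:
                    ok = False
                    break
            if not ok:
                continue
            self.kill_face(f1)
            self.kill_face(f2)
            self.add_face(t1)
            self.add_face(t2)
            valence[a] -= 1
            valence[b] -= 1
            valence[c] += 1
            valence[d] += 1
            existing.discard((a, b) if a < b else (b, a))
            existing.add(key_cd)
            touched.update((a, b, c, d))

    def _winding_ok(self, fidx, a, b):
        f = self.f[fidx]
        i = f.index(a)
        return f[(i + 1) % 3] == b

    def relax_pass(self, query: SurfaceDistanceQuery, step=0.5):
        alive_v = sorted({vid for i, f in enumerate(self.f) if self.alive[i]
                          for vid in f})
        nbrs = {vid: self.vertex_neighbors(vid) for vid in alive_v}
        newpos = {}
        for vid in alive_v:
            if self.bnd[vid] or not nbrs[vid]:
                continue
            mean = np.mean([self.v[w] for w in nbrs[vid]], axis=0)
            newpos[vid] = self.v[vid] + step * (mean - self.v[vid])
        if newpos:
            ids = list(newpos)
            pts = np.array([newpos[i] for i in ids])
            _, proj, _ = query.query(pts)
            for i, vid in enumerate(ids):
                self.v[vid] = proj[i]

    def compact(self):
        faces = [self.f[i] for i in range(len(self.f)) if self.alive[i]]
        used = sorted({v for f in faces for v in f})
        remap = {old: new for new, old in enumerate(used)}
        verts = np.array([self.v[i] for i in used])
        faces = np.array([[remap[v] for v in f] for f in faces], dtype=np.int64)
        bnd = np.array([self.bnd[i] for i in used], dtype=bool)
        return verts, faces, bnd


def remesh_to_edge_length(mesh: TriangleSurfaceMesh, target_mm: float,
                          iterations: int = 6) -> TriangleSurfaceMesh:
    """Isotropic incremental remeshing toward a uniform target edge length.

    Split / collapse / flip / tangential-relax passes in the usual
    incremental style, with every boundary vertex either kept exactly or
    created as a midpoint of an existing boundary segment so the boundary
    polylines are preserved. Leaflet labels transfer by nearest original
    element; node sets are re-classified against the original sets.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    mesh.assert_no_degenerate()
    boundary_flags = np.zeros(len(mesh.vertices), dtype=bool)
    boundary_flags[mesh.boundary_vertices()] = True
    em = _EditableMesh(mesh.vertices, mesh.faces, boundary_flags)
    query = SurfaceDistanceQuery(mesh.vertices, mesh.faces)
    # tangential relaxation biases edges ~20% short of the sizing used
    # for split/collapse; compensate so the median lands on target
    sizing = 1.2 * target_mm
    high, low = 4 / 3 * sizing, 4 / 5 * sizing
    for _ in range(int(iterations)):
        em.split_pass(high)
        em.collapse_pass(low, high)
        em.flip_pass()
        em.relax_pass(query)
    verts, faces, bnd = em.compact()
    # final projection: pull every interior vertex back onto the
    # original surface (collapses place vertices at chord midpoints)
    interior = ~bnd
    if np.any(interior):
        _, proj, _ = query.query(verts[interior])
        verts[interior] = proj

    # transfer labels from nearest original element centroid
    cent = verts[faces].mean(axis=1)
    tree = cKDTree(mesh.centroids)
    _, nearest = tree.query(cent)
    labels = mesh.leaflet_label[nearest]

    out = TriangleSurfaceMesh(verts, faces, labels, thickness=mesh.thickness)
    out.assert_no_degenerate()
    # re-classify boundary nodes against the original node sets
    bverts = out.boundary_vertices()
    ann, fe = np.zeros(0, int), np.zeros(0, int)
    if len(mesh.annulus_nodes) and len(mesh.free_edge_nodes):
        ta = cKDTree(mesh.vertices[mesh.annulus_nodes])
        tf = cKDTree(mesh.vertices[mesh.free_edge_nodes])
        da, _ = ta.query(out.vertices[bverts])
        df, _ = tf.query(out.vertices[bverts])
        ann = bverts[da <= df]
        fe = bverts[da > df]
    elif len(mesh.annulus_nodes):
        ann = bverts
    out.annulus_nodes = ann
    out.free_edge_nodes = fe
    return out


# --- IO ---------------------------------------------------------------


def save_mesh(mesh: TriangleSurfaceMesh, path) -> None:
    """Write STL/PLY (geometry only, via trimesh) or legacy ASCII VTK.

    The VTK writer stores leaflet labels as CELL_DATA, a boundary-class
    POINT_DATA array (0 interior, 1 annulus, 2 free edge) and the shell
    thickness, so it round-trips the full container.
    """
    path = str(path)
    if path.endswith((".stl", ".ply")):
        import trimesh
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                             process=False)
        tm.export(path)
        return
    if not path.endswith(".vtk"):
        raise ValueError(f"unsupported mesh format: {path}")
    bclass = np.zeros(len(mesh.vertices), dtype=int)
    bclass[mesh.annulus_nodes] = 1
    bclass[mesh.free_edge_nodes] = 2
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(json.dumps({"thickness": mesh.thickness}) + "\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"POLYGONS {len(mesh.faces)} {4 * len(mesh.faces)}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        fh.write(f"CELL_DATA {len(mesh.faces)}\n")
        fh.write("SCALARS leaflet int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(x) for x in mesh.leaflet_label) + "\n")
        fh.write(f"POINT_DATA {len(mesh.vertices)}\n")
        fh.write("SCALARS boundary_class int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(x) for x in bclass) + "\n")


def load_mesh(path) -> TriangleSurfaceMesh:
    path = str(path)
    if path.endswith((".stl", ".ply")):
        import trimesh
        tm = trimesh.load(path, process=False)
        return TriangleSurfaceMesh(np.asarray(tm.vertices),
                                   np.asarray(tm.faces))
    if not path.endswith(".vtk"):
        raise ValueError(f"unsupported mesh format: {path}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta = {}
    try:
        meta = json.loads(lines[1])
    except (json.JSONDecodeError, IndexError):
        pass
    i = 0
    verts = faces = labels = bclass = None
    while i < len(lines):
        tok = lines[i].split()
        if tok and tok[0] == "POINTS":
            n = int(tok[1])
            vals = " ".join(lines[i + 1:i + 1 + n]).split()
            verts = np.array(vals, float).reshape(n, 3)
            i += n
        elif tok and tok[0] == "POLYGONS":
            n = int(tok[1])
            rows = [lines[i + 1 + j].split() for j in range(n)]
            faces = np.array([[r[1], r[2], r[3]] for r in rows], dtype=np.int64)
            i += n
        elif tok and tok[0] == "SCALARS" and tok[1] == "leaflet":
            n = len(faces)
            vals = " ".join(lines[i + 2:i + 2 + n]).split()
            labels = np.array(vals[:n], dtype=np.int64)
            i += n + 1
        elif tok and tok[0] == "SCALARS" and tok[1] == "boundary_class":
            n = len(verts)
            vals = " ".join(lines[i + 2:i + 2 + n]).split()
            bclass = np.array(vals[:n], dtype=np.int64)
            i += n + 1
        i += 1
    if verts is None or faces is None:
        raise ValueError(f"could not parse VTK polydata from {path}")
    ann = np.where(bclass == 1)[0] if bclass is not None else np.zeros(0, int)
    fe = np.where(bclass == 2)[0] if bclass is not None else np.zeros(0, int)
    return TriangleSurfaceMesh(verts, faces, labels, ann, fe,
                               thickness=float(meta.get("thickness", 1.2)))
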