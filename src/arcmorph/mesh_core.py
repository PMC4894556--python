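"""Triangle-mesh I/O, geometric measures, remeshing/smoothing and surface distances.

All coordinates are millimetres; areas mm^2, volumes mm^3.  The
:class:`TriangleSurface` is the carrier type used by every other module:
a plain vertex/face array pair with consistent face orientation, cleaned of
duplicate vertices and zero-area faces.  Meshes may be open (boundary loops
are allowed and preserved); the enclosed volume is only defined for closed
surfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

__all__ = [
    "TriangleSurface",
    "DensityScan",
    "read_surface",
    "write_surface",
    "surface_measures",
    "remesh_and_smooth",
    "select_mesh_density",
    "surface_distance",
    "point_triangle_distances",
]

_SUPPORTED = {".vtk", ".ply", ".stl", ".obj"}


class MeshError(ValueError):
    """Raised for invalid or unsupported mesh input."""


@dataclass
class TriangleSurface:
    """Triangulated surface in mm.

    Attributes
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array, consistently oriented
    subject_id : optional label carried through the pipeline
    """

    vertices: np.ndarray
    faces: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (m, 3) triangles")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshError("face index out of range")

    # -- basic geometry ------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals_area(self) -> np.ndarray:
        """Area-weighted face normals (|n_f| = area of face f)."""
        t = self.triangles()
        return 0.5 * np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])

    def face_areas(self) -> np.ndarray:
        return np.linalg.norm(self.face_normals_area(), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def boundary_edges(self) -> np.ndarray:
        """(k, 2) directed edges used by exactly one face."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        key = np.sort(e, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return e[counts[inv] == 1]

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex index loops of the open boundary, sorted by centroid x."""
        edges = self.boundary_edges()
        nxt = {int(a): int(b) for a, b in edges}
        loops: list[np.ndarray] = []
        seen: set[int] = set()
        for start in sorted(nxt):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            cur = nxt[start]
            while cur != start and cur not in seen:
                loop.append(cur)
                seen.add(cur)
                if cur not in nxt:
                    break
                cur = nxt[cur]
            if len(loop) >= 3:
                loops.append(np.asarray(loop))
        loops.sort(key=lambda lp: tuple(self.vertices[lp].mean(axis=0)))
        return loops

    def is_closed(self) -> bool:
        return len(self.boundary_edges()) == 0

    def volume(self) -> float:
        """Enclosed volume by the divergence theorem.

        Raises :class:`MeshError` on open meshes (boundary loops present).
        Outward orientation gives positive volume; the absolute value is
        returned with a warning when the signed volume is negative.
        """
        if not self.is_closed():
            raise MeshError("volume undefined for open mesh")
        # computed about the vertex centroid so the result is independent of
        # the coordinate origin to floating-point accuracy
        t = self.triangles() - self.vertices.mean(axis=0)
        signed = float(np.einsum("ij,ij->", t[:, 0], np.cross(t[:, 1], t[:, 2]))) / 6.0
        if signed < 0:
            warnings.warn("mesh oriented inward; reporting |V|", stacklevel=2)
        return abs(signed)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "TriangleSurface":
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation).T
        if translation is not None:
            v = v + np.asarray(translation)
        return replace(self, vertices=v)

    def copy(self) -> "TriangleSurface":
        return TriangleSurface(self.vertices.copy(), self.faces.copy(), self.subject_id)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass
class DensityScan:
    """Record of a mesh-resolution scan against the original surface area."""

    densities: np.ndarray
    areas: np.ndarray
    reference_area: float
    selected_density: float

    @property
    def deviations(self) -> np.ndarray:
        return np.abs(self.areas - self.reference_area) / self.reference_area


# ---------------------------------------------------------------------------
# cleaning / orientation


def _merge_duplicate_vertices(vertices: np.ndarray, faces: np.ndarray,
                              tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    scaled = np.round(vertices / max(tol, 1e-12)).astype(np.int64)
    _, first, inverse = np.unique(scaled, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return vertices[first[order]], rank[inverse][faces]


def _drop_degenerate_faces(vertices: np.ndarray, faces: np.ndarray,
                           area_tol: float = 1e-12) -> np.ndarray:
    if not len(faces):
        return faces
    distinct = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    t = vertices[faces]
    areas = 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
    return faces[distinct & (areas > area_tol)]


def _orient_consistently(faces: np.ndarray) -> np.ndarray:
    """Flip faces so every interior edge is traversed once in each direction.

    Raises :class:`MeshError` for non-orientable connectivity.
    """
    m = len(faces)
    if m == 0:
        return faces
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            edge_faces.setdefault((min(u, v), max(u, v)), []).append(fi)
    for fs in edge_faces.values():
        if len(fs) > 2:
            raise MeshError("non-manifold edge (shared by >2 faces)")
    out = faces.copy()
    flipped = np.zeros(m, dtype=bool)
    visited = np.zeros(m, dtype=bool)

    def directed_edges(fi: int) -> list[tuple[int, int]]:
        a, b, c = out[fi]
        return [(a, b), (b, c), (c, a)]

    for seed in range(m):
        if visited[seed]:
            continue
        stack = [seed]
        visited[seed] = True
        while stack:
            fi = stack.pop()
            for u, v in directed_edges(fi):
                for fj in edge_faces[(min(u, v), max(u, v))]:
                    if fj == fi:
                        continue
                    same_dir = (u, v) in directed_edges(fj)
                    if not visited[fj]:
                        if same_dir:
                            out[fj] = out[fj][::-1]
                            flipped[fj] = True
                        visited[fj] = True
                        stack.append(fj)
                    elif same_dir:
                        raise MeshError("non-orientable surface")
    return out


def clean_surface(s: TriangleSurface, tol: float = 1e-8) -> TriangleSurface:
    """Merge duplicate vertices, drop degenerate faces, fix orientation."""
    v, f = _merge_duplicate_vertices(s.vertices, s.faces, tol)
    f = _drop_degenerate_faces(v, f)
    used = np.unique(f)
    remap = -np.ones(len(v), dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = TriangleSurface(v[used], remap[f], s.subject_id)
    out.faces = _orient_consistently(out.faces)
    # prefer outward orientation for closed meshes
    if out.is_closed() and len(out.faces):
        t = out.triangles()
        signed = np.einsum("ij,ij->", t[:, 0], np.cross(t[:, 1], t[:, 2])) / 6.0
        if signed < 0:
            out.faces = out.faces[:, ::-1]
    return out


# ---------------------------------------------------------------------------
# I/O


def _read_vtk_polydata(path: Path) -> tuple[np.ndarray, np.ndarray]:
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise MeshError(f"not a legacy VTK file: {path}")
    if "ascii" not in lines[2].strip().lower():
        raise MeshError("only ASCII legacy VTK supported")
    for ln in lines[3:]:
        tokens.extend(ln.split())
    i = 0
    points = None
    polys = None
    n_tok = len(tokens)
    while i < n_tok:
        t = tokens[i].upper()
        if t == "POINTS":
            n = int(tokens[i + 1])
            vals = tokens[i + 3:i + 3 + 3 * n]
            points = np.array(vals, dtype=float).reshape(n, 3)
            i += 3 + 3 * n
        elif t == "POLYGONS":
            n = int(tokens[i + 1])
            sz = int(tokens[i + 2])
            vals = np.array(tokens[i + 3:i + 3 + sz], dtype=np.int64)
            faces = []
            j = 0
            for _ in range(n):
                k = vals[j]
                if k != 3:
                    raise MeshError("non-triangular face in VTK polydata")
                faces.append(vals[j + 1:j + 4])
                j += k + 1
            polys = np.array(faces, dtype=np.int64)
            i += 3 + sz
        else:
            i += 1
    if points is None or polys is None:
        raise MeshError("VTK file missing POINTS or POLYGONS")
    return points, polys


def _write_vtk_polydata(path: Path, s: TriangleSurface) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\narcmorph surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {s.n_vertices} float\n")
        for p in s.vertices:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {s.n_faces} {4 * s.n_faces}\n")
        for f in s.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _reject_non_triangular(path: Path, suffix: str) -> None:
    """Fail on quad/polygon faces in ASCII OBJ and PLY sources.

    trimesh would silently triangulate them; the pipeline contract is
    triangle meshes in, so mixed-degree faces are an input error.
    """
    if suffix == ".obj":
        with open(path, errors="ignore") as fh:
            for line in fh:
                if line.startswith("f ") and len(line.split()) > 4:
                    raise MeshError("non-triangular face")
    elif suffix == ".ply":
        try:
            head = path.read_bytes()[:4096].decode("ascii", errors="ignore")
        except OSError:
            return
        if "format ascii" not in head:
            return
        text = path.read_text(errors="ignore").splitlines()
        try:
            n_vert = next(int(l.split()[-1]) for l in text if l.startswith("element vertex"))
            end = next(i for i, l in enumerate(text) if l.strip() == "end_header")
        except StopIteration:
            return
        for line in text[end + 1 + n_vert:]:
            parts = line.split()
            if parts and parts[0].isdigit() and int(parts[0]) != 3:
                raise MeshError("non-triangular face")


def read_surface(path: str | Path, fmt: str | None = None,
                 subject_id: str | None = None) -> TriangleSurface:
    """Read a surface mesh (.vtk legacy polydata, .ply, .stl, .obj) and clean it."""
    path = Path(path)
    if not path.exists():
        raise MeshError(f"no such file: {path}")
    suffix = ("." + fmt.lower()) if fmt else path.suffix.lower()
    if suffix not in _SUPPORTED:
        raise MeshError(f"unsupported format {suffix!r}")
    if suffix == ".vtk":
        v, f = _read_vtk_polydata(path)
    else:
        _reject_non_triangular(path, suffix)
        m = trimesh.load(str(path), file_type=suffix[1:], process=False, force="mesh")
        if m.faces.shape[1] != 3:
            raise MeshError("non-triangular face")
        v, f = np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=np.int64)
    return clean_surface(TriangleSurface(v, f, subject_id or path.stem))


def write_surface(s: TriangleSurface, path: str | Path, fmt: str | None = None) -> Path:
    path = Path(path)
    suffix = ("." + fmt.lower()) if fmt else path.suffix.lower()
    if suffix not in _SUPPORTED:
        raise MeshError(f"unsupported format {suffix!r}")
    if suffix == ".vtk":
        _write_vtk_polydata(path, s)
    else:
        s.to_trimesh().export(str(path), file_type=suffix[1:])
    return path


# ---------------------------------------------------------------------------
# measures


def surface_measures(s: TriangleSurface) -> tuple[float, float | None]:
    """Return (A_surf [mm^2], V [mm^3] or None for open meshes)."""
    a = s.area()
    if s.is_closed():
        return a, s.volume()
    return a, None


# ---------------------------------------------------------------------------
# remeshing and smoothing


def _collapse_edges(vertices: np.ndarray, faces: np.ndarray, target_faces: int) -> tuple[np.ndarray, np.ndarray]:
    """Greedy shortest-edge collapse (midpoint placement) to a face-count target."""
    import heapq

    v = vertices.copy()
    parent = np.arange(len(v))

    def root(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def current_faces() -> np.ndarray:
        f = np.vectorize(root)(faces) if len(faces) else faces
        f = _drop_degenerate_faces(v, f)
        return f

    heap: list[tuple[float, int, int]] = []
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    lens = np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)
    for (a, b), L in zip(e, lens):
        heapq.heappush(heap, (float(L), int(a), int(b)))

    # live face bookkeeping: count removals incrementally
    n_faces = len(_drop_degenerate_faces(v, faces))
    vert_faces: dict[int, set[int]] = {}
    fa = faces.copy()
    for fi, (a, b, c) in enumerate(fa):
        for x in (a, b, c):
            vert_faces.setdefault(int(x), set()).add(fi)
    alive = np.ones(len(fa), dtype=bool)

    while n_faces > target_faces and heap:
        L, a, b = heapq.heappop(heap)
        ra, rb = root(a), root(b)
        if ra == rb:
            continue
        actual = np.linalg.norm(v[ra] - v[rb])
        if abs(actual - L) > 1e-12:
            heapq.heappush(heap, (float(actual), ra, rb))
            continue
        # collapse rb into ra at midpoint
        mid = 0.5 * (v[ra] + v[rb])
        fs = vert_faces.get(ra, set()) | vert_faces.get(rb, set())
        removed = 0
        changed: list[int] = []
        for fi in fs:
            if not alive[fi]:
                continue
            verts = {root(int(x)) for x in fa[fi]}
            if ra in verts and rb in verts:
                alive[fi] = False
                removed += 1
            else:
                changed.append(fi)
        if n_faces - removed < target_faces - 1:
            continue  # overshoot; try another edge
        parent[rb] = ra
        v[ra] = mid
        vert_faces[ra] = {fi for fi in fs if alive[fi]}
        n_faces -= removed
        # re-queue edges around ra
        ring: set[int] = set()
        for fi in vert_faces[ra]:
            for x in fa[fi]:
                rx = root(int(x))
                if rx != ra:
                    ring.add(rx)
        for rx in ring:
            heapq.heappush(heap, (float(np.linalg.norm(v[ra] - v[rx])), ra, rx))

    f = np.array([[root(int(x)) for x in fa[fi]] for fi in range(len(fa)) if alive[fi]],
                 dtype=np.int64).reshape(-1, 3)
    f = _drop_degenerate_faces(v, f)
    used = np.unique(f)
    remap = -np.ones(len(v), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return v[used], remap[f]


def _taubin_smooth(s: TriangleSurface, passband: float, iterations: int) -> TriangleSurface:
    """Two-step (shrink/inflate) smoothing; boundary vertices are pinned."""
    lam = 0.33
    mu = -1.0 / (1.0 / lam - passband)  # k_pb = 1/lam + 1/mu
    n = s.n_vertices
    e = np.concatenate([s.faces[:, [0, 1]], s.faces[:, [1, 2]], s.faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    boundary = np.unique(s.boundary_edges()) if len(s.faces) else np.array([], dtype=int)
    interior = np.ones(n, dtype=bool)
    interior[boundary] = False
    deg = np.zeros(n)
    np.add.at(deg, e[:, 0], 1.0)
    np.add.at(deg, e[:, 1], 1.0)
    deg[deg == 0] = 1.0
    v = s.vertices.copy()
    for _ in range(iterations):
        for w in (lam, mu):
            nb = np.zeros_like(v)
            np.add.at(nb, e[:, 0], v[e[:, 1]])
            np.add.at(nb, e[:, 1], v[e[:, 0]])
            delta = nb / deg[:, None] - v
            v[interior] += w * delta[interior]
    return replace(s, vertices=v)


def remesh_and_smooth(s: TriangleSurface, target_density: float,
                      passband: float = 0.1, iterations: int = 30) -> TriangleSurface:
    """Re-mesh to ``target_density`` faces/mm^2 and apply passband smoothing.

    Face count after remeshing is within ~10 % of density * A_surf; the
    two-step smoother is non-shrinking (area change <= 1 % at the default
    passband) and keeps boundary loops fixed.
    """
    if target_density <= 0:
        raise MeshError("target_density must be positive")
    area = s.area()
    target_faces = int(round(target_density * area))
    n_loops = len(s.boundary_loops())
    if target_faces < max(4, 3 * n_loops):
        raise MeshError("density too low to preserve topology")
    v, f = s.vertices, s.faces
    # refine first if we need more faces
    while len(f) < target_faces:
        v, f = trimesh.remesh.subdivide(v, f)
    if len(f) > target_faces:
        v, f = _collapse_edges(v, f, target_faces)
    out = clean_surface(TriangleSurface(v, f, s.subject_id))
    if iterations > 0:
        out = _taubin_smooth(out, passband, iterations)
    return out


def select_mesh_density(s: TriangleSurface, densities: Sequence[float],
                        tolerance: float = 0.005, passband: float = 0.1,
                        iterations: int = 0) -> DensityScan:
    """Scan mesh resolutions and pick the lowest whose area error is within tolerance.

    Deviation of each re-meshed model is measured against the original
    surface area; the selected density is the smallest passing one.
    """
    densities = np.asarray(sorted(densities), dtype=float)
    if not len(densities):
        raise MeshError("empty density list")
    ref = s.area()
    areas = []
    for d in densities:
        areas.append(remesh_and_smooth(s, d, passband=passband, iterations=iterations).area())
    areas = np.asarray(areas)
    dev = np.abs(areas - ref) / ref
    ok = np.nonzero(dev <= tolerance)[0]
    if not len(ok):
        raise MeshError(
            f"no scanned density meets tolerance {tolerance:.3%}; best deviation {dev.min():.3%}")
    return DensityScan(densities, areas, ref, float(densities[ok[0]]))


# ---------------------------------------------------------------------------
# distances


def _pair_point_triangle(P: np.ndarray, tri: np.ndarray):
    """Exact squared distances and closest points for aligned (point, triangle) pairs."""
    A, B, C = tri[:, 0], tri[:, 1], tri[:, 2]
    E0, E1 = B - A, C - A
    a = np.einsum("ij,ij->i", E0, E0)
    b = np.einsum("ij,ij->i", E0, E1)
    c = np.einsum("ij,ij->i", E1, E1)
    det = np.maximum(a * c - b * b, 1e-30)
    D = P - A
    d = np.einsum("ij,ij->i", E0, D)
    e = np.einsum("ij,ij->i", E1, D)
    s = (c * d - b * e) / det
    t = (a * e - b * d) / det
    best_d2 = np.full(len(P), np.inf)
    best_q = np.zeros_like(P)

    def consider(q, mask=None):
        nonlocal best_d2, best_q
        dd = np.einsum("ij,ij->i", q - P, q - P)
        if mask is not None:
            dd = np.where(mask, dd, np.inf)
        better = dd < best_d2
        best_d2[better] = dd[better]
        best_q[better] = q[better]

    inside = (s >= 0.0) & (t >= 0.0) & (s + t <= 1.0)
    consider(A + s[:, None] * E0 + t[:, None] * E1, inside)
    for orig, edge, ee in ((A, E0, a), (A, E1, c),
                           (B, C - B, np.einsum("ij,ij->i", C - B, C - B))):
        u = np.clip(np.einsum("ij,ij->i", edge, P - orig) / np.maximum(ee, 1e-30), 0.0, 1.0)
        consider(orig + u[:, None] * edge)
    return best_d2, best_q


def point_triangle_distances(points: np.ndarray, surface: TriangleSurface,
                             return_closest: bool = False):
    """Exact minimum distance from each point to the surface's triangles.

    Candidate triangles are pre-filtered with a KD-tree over triangle
    centroids: a triangle can only hold the closest point if its centroid
    lies within (distance to the nearest centroid) + (largest triangle
    circumscribed radius) of the query, so the filter is conservative and
    the result exact.  Returns distances, and optionally the closest points.
    """
    from scipy.spatial import cKDTree

    P = np.atleast_2d(np.asarray(points, dtype=float))
    tri = surface.triangles()
    if len(tri) == 0 or len(P) == 0:
        raise MeshError("empty mesh or point set")
    npts, ntri = len(P), len(tri)
    if npts * ntri <= 200_000:   # small problems: plain all-pairs evaluation
        pi = np.repeat(np.arange(npts), ntri)
        ti = np.tile(np.arange(ntri), npts)
        d2, q = _pair_point_triangle(P[pi], tri[ti])
        d2 = d2.reshape(npts, ntri)
        idx = np.argmin(d2, axis=1)
        best = d2[np.arange(npts), idx]
        if return_closest:
            return np.sqrt(best), q.reshape(npts, ntri, 3)[np.arange(npts), idx]
        return np.sqrt(best)
    centroids = tri.mean(axis=1)
    r_tri = np.sqrt(np.max(np.sum((tri - centroids[:, None, :])**2, axis=2), axis=1))
    tree = cKDTree(centroids)
    h, _ = tree.query(P)
    cand = tree.query_ball_point(P, h + r_tri.max() + 1e-9)
    counts = np.fromiter((len(c) for c in cand), dtype=np.int64, count=npts)
    flat_t = np.fromiter((t for c in cand for t in c), dtype=np.int64,
                         count=int(counts.sum()))
    flat_p = np.repeat(np.arange(npts), counts)
    d2, q = _pair_point_triangle(P[flat_p], tri[flat_t])
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    best = np.minimum.reduceat(d2, starts)
    dist = np.sqrt(best)
    if return_closest:
        closest = np.empty_like(P)
        for i in range(npts):
            seg = slice(starts[i], starts[i] + counts[i])
            j = int(np.argmin(d2[seg]))
            closest[i] = q[seg][j]
        return dist, closest
    return dist


def surface_distance(a: TriangleSurface, b: TriangleSurface,
                     supersample: bool = False) -> tuple[float, float]:
    """Symmetric surface distance (max, mean) in mm.

    Vertices of each mesh are measured against the other's triangles; with
    ``supersample`` face barycenters are added to the sample set.
    """
    def samples(s: TriangleSurface) -> np.ndarray:
        if supersample:
            return np.vstack([s.vertices, s.triangles().mean(axis=1)])
        return s.vertices

    d_ab = point_triangle_distances(samples(a), b)
    d_ba = point_triangle_distances(samples(b), a)
    all_d = np.concatenate([d_ab, d_ba])
    return float(all_d.max()), float(all_d.mean())
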