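"""Triangulated-surface types, mesh I/O, and the atrial-surface preprocessing chain.

Leaflet surfaces arrive as triangulated meshes (PLY/STL/OBJ) in millimetres.
Before registration they are cleaned (unreferenced points, duplicate and
zero-area cells removed), Taubin-smoothed, and remeshed to a fixed uniform
node budget so that every surface in a cohort carries the same number of
vertices. An optional clip along a closed margin curve isolates the atrial
side of a closed segmentation model.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import trimesh as _trimesh
from sklearn.cluster import KMeans

__all__ = [
    "TriMesh",
    "LeafletSurface",
    "BoundaryCurve",
    "read_mesh",
    "write_mesh",
    "write_cell_field_csv",
    "read_curve_csv",
    "clean_mesh",
    "taubin_smooth",
    "remesh_uniform",
    "clip_by_curve",
    "preprocess_surface",
]


class MeshFormatError(ValueError):
    """Raised when a file does not contain a usable triangulated surface."""


@dataclasses.dataclass
class TriMesh:
    """A triangulated surface: V×3 vertex coordinates (mm) and F×3 faces.

    Faces are 0-based vertex index triples, counter-clockwise when viewed
    from the outward (atrial) side.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be V x 3")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be F x 3")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    # -- basic queries -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norms = np.linalg.norm(cross, axis=1)
        norms = np.where(norms == 0.0, 1.0, norms)
        return cross / norms[:, None]

    def area(self) -> float:
        return float(self.face_areas().sum())

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of incident face areas."""
        fa = self.face_areas()
        va = np.zeros(self.n_vertices)
        np.add.at(va, self.faces.ravel(), np.repeat(fa / 3.0, 3))
        return va

    def boundary_edges(self) -> np.ndarray:
        """Edges referenced by exactly one face, as (E, 2) index pairs."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        key = np.sort(e, axis=1)
        _, idx, counts = np.unique(
            key, axis=0, return_index=True, return_counts=True
        )
        return key[np.sort(idx[counts == 1])]

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())

    # -- conversion ----------------------------------------------------
    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: _trimesh.Trimesh) -> "TriMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


@dataclasses.dataclass
class BoundaryCurve:
    """Ordered 3D polyline (mm) marking the leaflet margin."""

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("curve points must be P x 3")
        if len(self.points) < 3:
            raise ValueError("curve needs at least 3 points")
        if self.closed:
            seg = np.diff(
                np.vstack([self.points, self.points[:1]]), axis=0
            )
            if np.any(np.linalg.norm(seg, axis=1) == 0.0):
                raise ValueError("closed curve has coincident consecutive points")

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Segment start and end points, wrapping if closed."""
        p = self.points
        if self.closed:
            return p, np.roll(p, -1, axis=0)
        return p[:-1], p[1:]


PHASES = ("diastole", "systole")


@dataclasses.dataclass
class LeafletSurface:
    """One leaflet's atrial surface at one cardiac phase."""

    mesh: TriMesh
    label: str
    phase: str
    subject_id: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

_KNOWN_FORMATS = {"ply", "stl", "obj"}


def _split_quad(vertices: np.ndarray, quad: Sequence[int]) -> list[tuple[int, int, int]]:
    """Split a quad along its shorter diagonal; ties -> lowest vertex index."""
    a, b, c, d = quad
    diag_ac = np.linalg.norm(vertices[a] - vertices[c])
    diag_bd = np.linalg.norm(vertices[b] - vertices[d])
    if diag_ac < diag_bd or (diag_ac == diag_bd and min(a, c) <= min(b, d)):
        return [(a, b, c), (a, c, d)]
    return [(a, b, d), (b, c, d)]


def _read_obj(path: Path) -> TriMesh:
    vertices: list[list[float]] = []
    faces: list[tuple[int, int, int]] = []
    raw_quads: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                vertices.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                if len(idx) == 3:
                    faces.append(tuple(idx))
                elif len(idx) == 4:
                    raw_quads.append(idx)
                else:
                    raise MeshFormatError(
                        f"{path}: only triangle and quad faces supported"
                    )
    varr = np.asarray(vertices, dtype=float)
    for q in raw_quads:
        faces.extend(_split_quad(varr, q))
    if not faces:
        raise MeshFormatError(f"{path}: no faces found")
    return TriMesh(varr, np.asarray(faces))


def read_mesh(path: str | Path, format: Optional[str] = None) -> TriMesh:
    """Read a PLY, STL, or OBJ surface.

    STL vertices are welded at 1e-6 mm tolerance (STL stores facets
    independently). Quads are split along the shorter diagonal.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _KNOWN_FORMATS:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    if fmt == "obj":
        return _read_obj(path)
    try:
        tm = _trimesh.load(str(path), file_type=fmt, process=False)
    except Exception as exc:  # parsing failure from trimesh
        raise MeshFormatError(f"cannot read {path}: {exc}") from exc
    if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"{path}: no triangulated surface content")
    mesh = TriMesh.from_trimesh(tm)
    if fmt == "stl":
        mesh = _weld_vertices(mesh, tol=1e-6)
    return mesh


def _weld_vertices(mesh: TriMesh, tol: float) -> TriMesh:
    key = np.round(mesh.vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return TriMesh(mesh.vertices[np.sort(first)], rank[inverse][mesh.faces])


def write_mesh(mesh: TriMesh, path: str | Path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _KNOWN_FORMATS:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    mesh.to_trimesh().export(str(path), file_type=fmt)


def write_cell_field_csv(
    values: np.ndarray, path: str | Path, name: str = "value", kind: str = "cell"
) -> None:
    """Write a per-cell (or per-vertex) scalar field as a two-column CSV."""
    import pandas as pd

    col = "cell_id" if kind == "cell" else "vertex_id"
    pd.DataFrame({col: np.arange(len(values)), name: np.asarray(values)}).to_csv(
        path, index=False
    )


def read_curve_csv(path: str | Path, closed: bool = True) -> BoundaryCurve:
    """Read a margin curve from CSV: one x,y,z point per line."""
    pts = np.loadtxt(path, delimiter=",", ndmin=2)
    return BoundaryCurve(pts[:, :3], closed=closed)


# ----------------------------------------------------------------------
# Cleaning
# ----------------------------------------------------------------------

def clean_mesh(mesh: TriMesh, area_tol: float = 1e-12) -> TriMesh:
    """Remove duplicate faces, zero-area faces, and unreferenced vertices.

    Coordinates of surviving vertices are never modified.
    """
    faces = mesh.faces
    # drop exact duplicates (same vertex triple in any order), keep first
    key = np.sort(faces, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    faces = faces[np.sort(first)]
    # drop degenerate cells
    v = mesh.vertices
    cross = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    faces = faces[areas > area_tol]
    if len(faces) == 0:
        raise ValueError("degenerate surface: no faces remain after cleaning")
    # drop unreferenced vertices
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(mesh.vertices[used], remap[faces])


# ----------------------------------------------------------------------
# Taubin smoothing
# ----------------------------------------------------------------------

def _taubin_coefficients(pass_band: float, lam: float = 0.33) -> tuple[float, float]:
    """Map a pass band k_pb to the (lambda, mu) shrink/inflate pair.

    Uses the transfer-function relation k_pb = 1/lambda + 1/mu with lambda
    fixed at 0.33. For pass bands at or beyond 1/lambda (where a fixed
    lambda could no longer satisfy the relation with mu < 0) lambda is
    reduced to 0.9/k_pb so both coefficients shrink toward zero and the
    filter approaches the identity.
    """
    if pass_band <= 0:
        raise ValueError("pass_band must be positive")
    if pass_band >= 1.0 / lam:
        lam = 0.9 / pass_band
    mu = 1.0 / (pass_band - 1.0 / lam)
    return lam, mu


def _vertex_neighbors(mesh: TriMesh) -> list[np.ndarray]:
    edges = np.vstack(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    nbr: list[list[int]] = [[] for _ in range(mesh.n_vertices)]
    for a, b in edges:
        nbr[a].append(b)
        nbr[b].append(a)
    return [np.asarray(n, dtype=np.int64) for n in nbr]


def taubin_smooth(
    mesh: TriMesh, iterations: int = 10, pass_band: float = 0.05
) -> TriMesh:
    """Taubin (shrink/inflate) smoothing with free-edge preservation.

    Interior vertices receive the standard umbrella Laplacian. Boundary
    vertices are smoothed only *along* the boundary polyline: the umbrella
    vector over their two boundary neighbours is projected onto the local
    polyline tangent, so the free edge is redistributed but never eroded
    inward. Boundary vertices with an irregular number of boundary
    neighbours are held fixed.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mesh.copy()
    lam, mu = _taubin_coefficients(pass_band)

    neighbors = _vertex_neighbors(mesh)
    bedges = mesh.boundary_edges()
    boundary_nbr: dict[int, list[int]] = {}
    for a, b in bedges:
        boundary_nbr.setdefault(int(a), []).append(int(b))
        boundary_nbr.setdefault(int(b), []).append(int(a))

    interior = np.array(
        [i for i in range(mesh.n_vertices) if i not in boundary_nbr], dtype=np.int64
    )
    bnd_regular = np.array(
        [i for i, n in boundary_nbr.items() if len(n) == 2], dtype=np.int64
    )
    bnd_pairs = (
        np.array([boundary_nbr[i] for i in bnd_regular], dtype=np.int64)
        if len(bnd_regular)
        else np.zeros((0, 2), dtype=np.int64)
    )

    # CSR-style flattening of interior neighbourhoods for vectorized umbrella
    if len(interior):
        counts = np.array([len(neighbors[i]) for i in interior])
        flat = np.concatenate([neighbors[i] for i in interior])
        offsets = np.concatenate([[0], np.cumsum(counts)])
    v = mesh.vertices.copy()

    def _step(pts: np.ndarray, factor: float) -> np.ndarray:
        out = pts.copy()
        if len(interior):
            sums = np.add.reduceat(pts[flat], offsets[:-1], axis=0)
            umbrella = sums / counts[:, None] - pts[interior]
            out[interior] = pts[interior] + factor * umbrella
        if len(bnd_regular):
            p1 = pts[bnd_pairs[:, 0]]
            p2 = pts[bnd_pairs[:, 1]]
            d = 0.5 * (p1 + p2) - pts[bnd_regular]
            t = p1 - p2
            t /= np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-300)
            out[bnd_regular] = pts[bnd_regular] + factor * (
                np.sum(d * t, axis=1, keepdims=True) * t
            )
        return out

    for _ in range(iterations):
        v = _step(v, lam)
        v = _step(v, mu)
    return TriMesh(v, mesh.faces.copy())


# ----------------------------------------------------------------------
# Uniform remeshing (area-weighted centroidal clustering)
# ----------------------------------------------------------------------

def remesh_uniform(mesh: TriMesh, n_nodes: int = 1000, seed: int = 0) -> TriMesh:
    """Remesh to exactly ``n_nodes`` uniformly distributed vertices.

    The surface is midpoint-subdivided to a fine proxy, fine vertices are
    partitioned into ``n_nodes`` area-weighted centroidal clusters
    (seeded k-means), and the cluster adjacency on the fine triangulation
    is dualized into the output triangles. Cluster sites are projected
    back onto the input surface, which keeps total area within a couple
    of percent on smooth leaflet-scale surfaces.
    """
    if n_nodes < 4:
        raise ValueError("n_nodes must be >= 4")
    base = clean_mesh(mesh)
    if base.n_faces < 1 or base.area() <= 0:
        raise ValueError("remesh requires a surface with positive area")

    for attempt in range(3):
        result = _remesh_once(base, n_nodes, seed + 1009 * attempt)
        if result is not None:
            return result
    raise ValueError(
        f"cannot seat {n_nodes} uniform nodes on this surface; "
        "reduce n_nodes or provide a finer/larger mesh"
    )


def _remesh_once(base: TriMesh, n_nodes: int, seed: int) -> Optional[TriMesh]:
    fine = base
    target_fine = max(18 * n_nodes, 4000)
    guard = 0
    while fine.n_vertices < target_fine and guard < 6:
        vv, ff = _trimesh.remesh.subdivide(fine.vertices, fine.faces)
        fine = TriMesh(vv, ff)
        guard += 1

    weights = fine.vertex_areas()
    km = KMeans(
        n_clusters=n_nodes,
        n_init=1,
        random_state=seed % (2**31),
        algorithm="lloyd",
    )
    labels = km.fit_predict(fine.vertices, sample_weight=weights)

    # dual triangulation: each fine face spanning 3 clusters -> one triangle
    fl = labels[fine.faces]
    distinct = (
        (fl[:, 0] != fl[:, 1]) & (fl[:, 1] != fl[:, 2]) & (fl[:, 0] != fl[:, 2])
    )
    tri = fl[distinct]
    if len(tri) == 0:
        return None
    key = np.sort(tri, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    tri = tri[np.sort(first)]
    if len(np.unique(tri)) != n_nodes:
        return None  # a cluster ended up with no dual triangle; retry

    # place sites at weighted cluster centroids projected onto the surface
    sites = np.zeros((n_nodes, 3))
    wsum = np.zeros(n_nodes)
    np.add.at(sites, labels, fine.vertices * weights[:, None])
    np.add.at(wsum, labels, weights)
    empty = wsum <= 0
    if np.any(empty):
        return None
    sites /= wsum[:, None]
    from ._proximity import closest_on_surface

    closest, _, _ = closest_on_surface(base, sites)
    sites = np.asarray(closest)

    # clusters touching an open boundary get their site *on* the boundary
    # polyline, otherwise the dual triangulation erodes the free edge
    bedges = fine.boundary_edges()
    if len(bedges):
        bverts = np.unique(bedges)
        bnd_sites = np.zeros((n_nodes, 3))
        bnd_w = np.zeros(n_nodes)
        np.add.at(bnd_sites, labels[bverts], fine.vertices[bverts] * weights[bverts, None])
        np.add.at(bnd_w, labels[bverts], weights[bverts])
        on_bnd = bnd_w > 0
        if np.any(on_bnd):
            cand = bnd_sites[on_bnd] / bnd_w[on_bnd, None]
            sites[on_bnd] = _project_to_polyline(
                cand, fine.vertices[bedges[:, 0]], fine.vertices[bedges[:, 1]]
            )
    out = TriMesh(sites, tri)
    return _orient_consistently(out, base)


def _project_to_polyline(
    points: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray
) -> np.ndarray:
    """Closest points on a set of segments for each query point."""
    d = seg_b - seg_a
    len2 = np.maximum(np.einsum("ij,ij->i", d, d), 1e-300)
    diff = points[:, None, :] - seg_a[None, :, :]
    t = np.clip(np.einsum("psj,sj->ps", diff, d) / len2, 0.0, 1.0)
    proj = seg_a[None] + t[..., None] * d[None]
    d2 = np.einsum("psj->ps", (points[:, None, :] - proj) ** 2)
    best = np.argmin(d2, axis=1)
    return proj[np.arange(len(points)), best]


def _orient_consistently(mesh: TriMesh, reference: TriMesh) -> TriMesh:
    """Flip output faces whose normal opposes the nearest reference face."""
    from ._proximity import closest_on_surface

    centers = mesh.vertices[mesh.faces].mean(axis=1)
    _, _, fid = closest_on_surface(reference, centers)
    ref_normals = reference.face_normals()[fid]
    flip = np.sum(mesh.face_normals() * ref_normals, axis=1) < 0
    faces = mesh.faces.copy()
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return TriMesh(mesh.vertices, faces)


# ----------------------------------------------------------------------
# Clip by margin curve
# ----------------------------------------------------------------------

def _signed_side_field(mesh: TriMesh, curve: BoundaryCurve) -> np.ndarray:
    """Signed distance-like field: + on the (tangent x surface-normal) side."""
    starts, ends = curve.segments()
    seg = ends - starts
    seg_len2 = np.maximum(np.einsum("ij,ij->i", seg, seg), 1e-300)

    v = mesh.vertices
    # closest point on each curve segment for every vertex
    diff = v[:, None, :] - starts[None, :, :]
    t = np.clip(np.einsum("vsj,sj->vs", diff, seg) / seg_len2, 0.0, 1.0)
    proj = starts[None] + t[..., None] * seg[None]
    d2 = np.einsum("vsj->vs", (v[:, None, :] - proj) ** 2)
    nearest = np.argmin(d2, axis=1)
    idx = np.arange(len(v))
    p_near = proj[idx, nearest]
    tangent = seg[nearest] / np.sqrt(seg_len2[nearest])[:, None]

    # surface normal at the projected curve location
    from ._proximity import closest_on_surface

    _, _, fid = closest_on_surface(mesh, p_near)
    normal = mesh.face_normals()[fid]
    left = np.cross(tangent, normal)
    left /= np.maximum(np.linalg.norm(left, axis=1, keepdims=True), 1e-300)
    return np.einsum("ij,ij->i", v - p_near, left)


def clip_by_curve(
    mesh: TriMesh, curve: BoundaryCurve, side: str = "positive"
) -> TriMesh:
    """Clip a surface along a closed margin curve.

    Every vertex is assigned a signed side value relative to the projected
    curve (positive on the side of curve-tangent x surface-normal);
    crossing triangles are split along the interpolated zero set and the
    largest connected component on the requested side is returned.
    """
    if not curve.closed:
        raise ValueError("clipping requires a closed curve")
    if side not in ("positive", "negative"):
        raise ValueError("side must be 'positive' or 'negative'")
    s = _signed_side_field(mesh, curve)
    if side == "negative":
        s = -s
    if np.all(s >= 0):
        return mesh.copy()
    if np.all(s < 0):
        raise ValueError("curve does not separate surface: nothing on chosen side")
    clipped = _clip_by_field(mesh, s)
    return _largest_component(clipped)


def _clip_by_field(mesh: TriMesh, s: np.ndarray, keep: float = 0.0) -> TriMesh:
    """Keep the s >= keep region, splitting triangles across the level set."""
    verts = [mesh.vertices]
    new_index: dict[tuple[int, int], int] = {}
    next_id = mesh.n_vertices
    extra: list[np.ndarray] = []

    def cut_point(a: int, b: int) -> int:
        nonlocal next_id
        key = (a, b) if a < b else (b, a)
        if key not in new_index:
            ta = s[a] - keep
            tb = s[b] - keep
            t = ta / (ta - tb)
            extra.append(mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a]))
            new_index[key] = next_id
            next_id += 1
        return new_index[key]

    faces_out: list[tuple[int, int, int]] = []
    inside = s >= keep
    for tri in mesh.faces:
        flags = inside[tri]
        n_in = int(flags.sum())
        if n_in == 3:
            faces_out.append(tuple(tri))
        elif n_in == 0:
            continue
        elif n_in == 1:
            # rotate so vertex 0 is inside
            order = np.roll(tri, -int(np.argmax(flags)))
            a, b, c = order
            ab = cut_point(a, b)
            ac = cut_point(a, c)
            faces_out.append((a, ab, ac))
        else:  # two inside
            order = np.roll(tri, -int(np.argmin(flags)))
            a, b, c = order  # a outside, b and c inside
            ab = cut_point(a, b)
            ca = cut_point(c, a)
            faces_out.append((ab, b, c))
            faces_out.append((ab, c, ca))
    if not faces_out:
        raise ValueError("curve does not separate surface: empty clip result")
    all_verts = np.vstack(verts + [np.asarray(extra)]) if extra else mesh.vertices
    return clean_mesh(TriMesh(all_verts, np.asarray(faces_out)))


def _largest_component(mesh: TriMesh) -> TriMesh:
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    e = np.vstack(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    adj = sp.coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])),
        shape=(mesh.n_vertices, mesh.n_vertices),
    )
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp <= 1:
        return mesh
    areas = np.zeros(n_comp)
    fa = mesh.face_areas()
    np.add.at(areas, comp[mesh.faces[:, 0]], fa)
    keep = int(np.argmax(areas))
    faces = mesh.faces[comp[mesh.faces[:, 0]] == keep]
    return clean_mesh(TriMesh(mesh.vertices, faces))


# ----------------------------------------------------------------------
# Preprocessing chain
# ----------------------------------------------------------------------

def preprocess_surface(
    mesh: TriMesh,
    curve: Optional[BoundaryCurve] = None,
    side: str = "positive",
    smooth_iterations: int = 10,
    pass_band: float = 0.05,
    n_nodes: int = 1000,
    seed: int = 0,
) -> TriMesh:
    """Full atrial-surface chain: (clip) -> clean -> Taubin -> uniform remesh."""
    out = mesh
    if curve is not None:
        out = clip_by_curve(out, curve, side=side)
    out = clean_mesh(out)
    out = taubin_smooth(out, iterations=smooth_iterations, pass_band=pass_band)
    return remesh_uniform(out, n_nodes=n_nodes, seed=seed)
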