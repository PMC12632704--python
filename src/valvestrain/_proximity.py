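"""Exact point-to-surface closest-point queries.

Candidate triangles are prefiltered with a KD-tree over face centroids and
the prefilter is made exact by a bound check: after the candidate pass
yields an upper bound d for a query point, any face whose centroid lies
within d + r_max (r_max = largest face circumradius-like bound) is also
examined. Point-to-triangle projection itself comes from
``trimesh.triangles.closest_point``.
"""

from __future__ import annotations

import numpy as np
import trimesh.triangles as _tri
from scipy.spatial import cKDTree

from .mesh_core import TriMesh

__all__ = ["closest_on_surface"]


def closest_on_surface(
    mesh: TriMesh, points: np.ndarray, k: int = 32
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closest surface points, distances, and face ids for query points."""
    points = np.asarray(points, dtype=float)
    tris = mesh.vertices[mesh.faces]  # (F, 3, 3)
    centers = tris.mean(axis=1)
    # max distance from a centroid to its triangle's vertices
    vert_radius = np.linalg.norm(tris - centers[:, None, :], axis=2).max(axis=1)
    r_max = float(vert_radius.max())

    tree = cKDTree(centers)
    k = min(k, len(centers))
    center_d, cand = tree.query(points, k=k)
    if k == 1:
        center_d = center_d[:, None]
        cand = cand[:, None]

    n = len(points)
    best_d2 = np.full(n, np.inf)
    best_pt = np.zeros((n, 3))
    best_id = np.zeros(n, dtype=np.int64)

    def _update(pt_idx: np.ndarray, face_idx: np.ndarray) -> None:
        """Exact distances for (point, face) pairs; keep per-point minimum."""
        proj = _tri.closest_point(tris[face_idx], points[pt_idx])
        d2 = np.einsum("ij,ij->i", points[pt_idx] - proj, points[pt_idx] - proj)
        np.minimum.at(best_d2, pt_idx, d2)
        better = d2 <= best_d2[pt_idx]
        best_pt[pt_idx[better]] = proj[better]
        best_id[pt_idx[better]] = face_idx[better]

    pt_idx = np.repeat(np.arange(n), k)
    _update(pt_idx, cand.ravel())

    # exactness pass: faces whose centroid could still beat the bound
    bound = np.sqrt(best_d2) + r_max
    extra = tree.query_ball_point(points, bound)
    pts_list: list[int] = []
    faces_list: list[int] = []
    cand_sets = [set(row) for row in cand]
    for i, lst in enumerate(extra):
        missing = [f for f in lst if f not in cand_sets[i]]
        pts_list.extend([i] * len(missing))
        faces_list.extend(missing)
    if pts_list:
        _update(np.asarray(pts_list), np.asarray(faces_list))
    return best_pt, np.sqrt(best_d2), best_id
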