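"""Surface-agreement and strain-accuracy metrics.

Shape agreement between a registered surface and its target is reported as
the mean symmetric distance (MSD) and the 95th-percentile Hausdorff
distance (HD95). Both pool the bidirectional vertex-to-surface closest
point distances (A vertices to surface B, and B vertices to surface A)
into one sample; distances are exact point-to-triangle distances, in mm.
Strain accuracy is the unweighted mean absolute error between per-cell
fields on the same mesh.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._proximity import closest_on_surface
from .mesh_core import TriMesh

__all__ = ["ShapeErrorReport", "surface_distances", "msd", "hausdorff95", "strain_mae"]


@dataclasses.dataclass
class ShapeErrorReport:
    msd: float
    hd95: float
    n_samples_ab: int
    n_samples_ba: int


def _point_to_surface(points: np.ndarray, mesh: TriMesh) -> np.ndarray:
    _, dist, _ = closest_on_surface(mesh, points)
    return np.asarray(dist, dtype=float)


def surface_distances(A: TriMesh, B: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    """Vertex-to-surface distances A->B and B->A (mm)."""
    if A.n_faces == 0 or B.n_faces == 0:
        raise ValueError("cannot measure distances to an empty mesh")
    return _point_to_surface(A.vertices, B), _point_to_surface(B.vertices, A)


def msd(A: TriMesh, B: TriMesh, pooled: bool = True) -> float:
    """Mean symmetric surface distance in mm.

    ``pooled=True`` (default) takes the mean of the union of both
    direction's distance samples; ``pooled=False`` averages the two
    directional means.
    """
    d_ab, d_ba = surface_distances(A, B)
    if pooled:
        return float(np.concatenate([d_ab, d_ba]).mean())
    return float(0.5 * (d_ab.mean() + d_ba.mean()))


def hausdorff95(A: TriMesh, B: TriMesh) -> float:
    """95th percentile (linear interpolation) of pooled bidirectional distances."""
    d_ab, d_ba = surface_distances(A, B)
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95.0))


def shape_error_report(A: TriMesh, B: TriMesh) -> ShapeErrorReport:
    d_ab, d_ba = surface_distances(A, B)
    pooled = np.concatenate([d_ab, d_ba])
    return ShapeErrorReport(
        msd=float(pooled.mean()),
        hd95=float(np.percentile(pooled, 95.0)),
        n_samples_ab=len(d_ab),
        n_samples_ba=len(d_ba),
    )


def strain_mae(estimated: np.ndarray, reference: np.ndarray) -> float:
    """Unweighted mean absolute error between per-cell strain fields."""
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(
            f"field size mismatch: {est.shape} vs {ref.shape}"
        )
    return float(np.abs(est - ref).mean())
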