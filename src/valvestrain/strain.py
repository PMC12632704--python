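"""Per-triangle membrane strain between two corresponded surface meshes.

Given a reference (mid-diastolic) and deformed (mid-systolic) mesh with
identical connectivity, each triangle's deformation gradient is the linear
map carrying the reference tangent basis and unit normal onto the deformed
ones:

    F = [T1 T2 n_def] [t1 t2 n_ref]^-1        (columns)

with t1 = v1 - v0, t2 = v2 - v0 and n = t1 x t2 / ||t1 x t2||. Using *unit*
normals in both bases means the out-of-plane direction carries zero strain:
this is a membrane measure — thickness change is unobservable from surfaces.

Derived fields: areal strain (A_def - A_ref)/A_ref, right Cauchy-Green
tensor C = F^T F, Green-Lagrange tensor E = (C - I)/2 and its largest
eigenvalue (1st principal strain, the maximum tensile strain).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .mesh_core import TriMesh

__all__ = [
    "CorrespondedPair",
    "StrainField",
    "StrainSummary",
    "deformation_gradient",
    "areal_strain",
    "green_lagrange",
    "strain_field",
    "strain_summary",
    "weighted_quantile",
]

_DEGENERATE_AREA = 1e-12


@dataclasses.dataclass
class CorrespondedPair:
    """Reference/deformed mesh pair with index-wise vertex correspondence."""

    ref_mesh: TriMesh
    def_mesh: TriMesh

    def __post_init__(self) -> None:
        if self.ref_mesh.n_vertices != self.def_mesh.n_vertices:
            raise ValueError("corresponded meshes must share the vertex count")
        if not np.array_equal(self.ref_mesh.faces, self.def_mesh.faces):
            raise ValueError("corresponded meshes must share the face list")
        for name, mesh in (("reference", self.ref_mesh), ("deformed", self.def_mesh)):
            bad = np.nonzero(mesh.face_areas() <= _DEGENERATE_AREA)[0]
            if len(bad):
                raise ValueError(
                    f"{name} mesh has zero-area cell(s), first at cell {bad[0]}"
                )


@dataclasses.dataclass
class StrainField:
    """Per-cell strain quantities plus area-weighted vertex averages."""

    F: np.ndarray              # (C, 3, 3)
    C: np.ndarray              # (C, 3, 3) right Cauchy-Green
    E: np.ndarray              # (C, 3, 3) Green-Lagrange
    areal: np.ndarray          # (C,)
    principal1: np.ndarray     # (C,)
    principal1_dir: np.ndarray # (C, 3)
    vertex_areal: np.ndarray
    vertex_principal1: np.ndarray
    ref_areas: np.ndarray      # (C,) reference cell areas (weights)


@dataclasses.dataclass
class StrainSummary:
    median: float
    iqr: float
    mean: float
    sd: float
    billow_flag: bool


def _tangent_basis(tri: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """t1, t2 and the unit normal of a stack of triangles (C, 3, 3)."""
    t1 = tri[:, 1] - tri[:, 0]
    t2 = tri[:, 2] - tri[:, 0]
    cross = np.cross(t1, t2)
    norm = np.linalg.norm(cross, axis=1)
    if np.any(norm <= 2.0 * _DEGENERATE_AREA):
        bad = int(np.argmax(norm <= 2.0 * _DEGENERATE_AREA))
        raise ValueError(f"degenerate triangle at cell {bad}")
    return t1, t2, cross / norm[:, None]


def deformation_gradient(ref_tri: np.ndarray, def_tri: np.ndarray) -> np.ndarray:
    """Deformation gradient(s) for one triangle or a (C, 3, 3) stack.

    Maps t1 -> T1, t2 -> T2 and the reference unit normal to the deformed
    unit normal exactly.
    """
    ref = np.asarray(ref_tri, dtype=float)
    dfm = np.asarray(def_tri, dtype=float)
    single = ref.ndim == 2
    if single:
        ref = ref[None]
        dfm = dfm[None]
    t1, t2, n_ref = _tangent_basis(ref)
    T1, T2, n_def = _tangent_basis(dfm)
    B_ref = np.stack([t1, t2, n_ref], axis=2)  # columns
    B_def = np.stack([T1, T2, n_def], axis=2)
    F = B_def @ np.linalg.inv(B_ref)
    return F[0] if single else F


def areal_strain(pair: CorrespondedPair) -> np.ndarray:
    """Per-cell relative area change (A_def - A_ref) / A_ref."""
    a_ref = pair.ref_mesh.face_areas()
    a_def = pair.def_mesh.face_areas()
    return (a_def - a_ref) / a_ref


def green_lagrange(F: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Green-Lagrange tensor E = (F^T F - I)/2 with its largest eigenpair.

    The eigenvector sign is fixed so its largest-magnitude component is
    positive; if the top two eigenvalues are numerically tied (< 1e-12
    apart) the reported direction is the eigenvector best aligned with the
    first tangent axis convention (handled in :func:`strain_field`).
    """
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite deformation gradient")
    single = F.ndim == 2
    if single:
        F = F[None]
    C = np.einsum("cji,cjk->cik", F, F)
    E = 0.5 * (C - np.eye(3))
    vals, vecs = np.linalg.eigh(E)  # ascending
    p1 = vals[:, -1]
    d = vecs[:, :, -1]
    # deterministic sign: largest-magnitude component positive
    comp = np.argmax(np.abs(d), axis=1)
    sign = np.sign(d[np.arange(len(d)), comp])
    sign = np.where(sign == 0, 1.0, sign)
    d = d * sign[:, None]
    if single:
        return E[0], float(p1[0]), d[0]
    return E, p1, d


def strain_field(pair: CorrespondedPair) -> StrainField:
    """Full per-cell strain field with area-weighted vertex averages."""
    ref_tris = pair.ref_mesh.vertices[pair.ref_mesh.faces]
    def_tris = pair.def_mesh.vertices[pair.def_mesh.faces]
    F = deformation_gradient(ref_tris, def_tris)
    E, p1, d1 = green_lagrange(F)
    C = np.einsum("cji,cjk->cik", F, F)

    # eigen-tie determinism: align direction with t1 when the top pair is tied
    vals = np.linalg.eigvalsh(E)
    tied = (vals[:, -1] - vals[:, -2]) < 1e-12
    if np.any(tied):
        t1 = ref_tris[:, 1] - ref_tris[:, 0]
        t1 = t1 / np.linalg.norm(t1, axis=1, keepdims=True)
        idx = np.nonzero(tied)[0]
        for c in idx:
            w, v = np.linalg.eigh(E[c])
            top = np.abs(w - w[-1]) < 1e-12
            cand = v[:, top]
            scores = np.abs(cand.T @ t1[c])
            best = cand[:, int(np.argmax(scores))]
            if best[np.argmax(np.abs(best))] < 0:
                best = -best
            d1[c] = best

    a_ref = pair.ref_mesh.face_areas()
    areal = (pair.def_mesh.face_areas() - a_ref) / a_ref

    nv = pair.ref_mesh.n_vertices
    faces = pair.ref_mesh.faces
    wsum = np.zeros(nv)
    v_areal = np.zeros(nv)
    v_p1 = np.zeros(nv)
    np.add.at(wsum, faces.ravel(), np.repeat(a_ref, 3))
    np.add.at(v_areal, faces.ravel(), np.repeat(a_ref * areal, 3))
    np.add.at(v_p1, faces.ravel(), np.repeat(a_ref * p1, 3))
    wsum = np.maximum(wsum, 1e-300)
    return StrainField(
        F=F,
        C=C,
        E=E,
        areal=areal,
        principal1=p1,
        principal1_dir=d1,
        vertex_areal=v_areal / wsum,
        vertex_principal1=v_p1 / wsum,
        ref_areas=a_ref,
    )


def weighted_quantile(
    values: np.ndarray, q: float | np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted quantile with Hazen-type plotting positions.

    Sorted values receive cumulative positions (cumw_i - w_i/2) / W and the
    quantile is linearly interpolated between them; with equal weights the
    median reduces to the familiar midpoint of the two central order
    statistics.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("empty field")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    pos = (np.cumsum(w) - 0.5 * w) / w.sum()
    return np.interp(q, pos, v)


def strain_summary(
    values: np.ndarray,
    weights: np.ndarray | None = None,
    billow_threshold: float = 0.5,
) -> StrainSummary:
    """Area-weighted distribution summary with the billow signature flag.

    The flag marks leaflets whose weighted median *and* IQR of the field
    both exceed ``billow_threshold`` (default 0.5), the signature
    associated with leaflet billow/prolapse.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty field")
    if weights is None:
        weights = np.ones_like(values)
    q1, q2, q3 = weighted_quantile(values, [0.25, 0.5, 0.75], weights)
    wsum = weights.sum()
    mean = float((values * weights).sum() / wsum)
    var = float(((values - mean) ** 2 * weights).sum() / wsum)
    iqr = float(q3 - q1)
    median = float(q2)
    return StrainSummary(
        median=median,
        iqr=iqr,
        mean=mean,
        sd=float(np.sqrt(var)),
        billow_flag=bool(median > billow_threshold and iqr > billow_threshold),
    )
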