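"""Synthetic leaflet and valve surfaces with analytic ground-truth strain.

Real inputs are segmentation-derived atrial surfaces at mid-diastole and
mid-systole. This module emulates them: dome-shaped leaflets over an
elliptical annulus (~1000 uniformly distributed nodes), smooth closed-form
inter-phase deformations (rigid motion, stretch, shear, billowing bumps
that invert local concavity), and multi-subject cohorts with per-leaflet
labels. Every deformation carries an exact Jacobian, so per-cell reference
strain is available in closed form — the role the FEA benchmark and
patient data play for the real pipeline.

The generator emulates geometry and deformation only; it does not simulate
echo image formation, speckle, or segmentation error beyond optional
coordinate noise.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.spatial

from .mesh_core import LeafletSurface, TriMesh, remesh_uniform
from .strain import StrainField, green_lagrange

__all__ = [
    "SyntheticLeafletSpec",
    "AnalyticDeformation",
    "SyntheticCohort",
    "make_dome_leaflet",
    "apply_deformation",
    "make_cohort",
    "make_valve",
    "billow_signature_deformation",
]


@dataclasses.dataclass
class SyntheticLeafletSpec:
    """Dome leaflet over an elliptical annulus (semi-axes a, b, in mm)."""

    annulus_radii: tuple[float, float] = (12.0, 9.0)
    dome_height: float = 4.0
    n_nodes: int = 1000
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.annulus_radii
        if a <= 0 or b <= 0 or self.dome_height < 0:
            raise ValueError("annulus radii must be positive, dome height >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _disk_points(n_rings: int) -> np.ndarray:
    """Near-uniform unit-disk sampling: center + concentric rings."""
    pts = [(0.0, 0.0)]
    for k in range(1, n_rings + 1):
        r = k / n_rings
        m = 6 * k
        theta = 2.0 * np.pi * np.arange(m) / m + (np.pi / m) * (k % 2)
        pts.extend(zip(r * np.cos(theta), r * np.sin(theta)))
    return np.asarray(pts)


def make_dome_leaflet(spec: SyntheticLeafletSpec) -> TriMesh:
    """Smooth dome z = h (1 - rho^2) over an ellipse, remeshed to n_nodes."""
    a, b = spec.annulus_radii
    n_rings = max(12, int(np.ceil(np.sqrt(spec.n_nodes))))
    uv = _disk_points(n_rings)
    rho2 = np.sum(uv * uv, axis=1)
    xyz = np.column_stack(
        [a * uv[:, 0], b * uv[:, 1], spec.dome_height * (1.0 - rho2)]
    )
    tri2d = scipy.spatial.Delaunay(uv)
    faces = tri2d.simplices.copy()
    # enforce CCW orientation viewed from +z (the atrial side of the dome)
    p = uv[faces]
    signed = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = signed < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    mesh = remesh_uniform(TriMesh(xyz, faces), n_nodes=spec.n_nodes, seed=spec.seed)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        mesh = TriMesh(
            mesh.vertices + rng.normal(0.0, spec.noise_sd, mesh.vertices.shape),
            mesh.faces,
        )
    return mesh


# ----------------------------------------------------------------------
# Closed-form deformations
# ----------------------------------------------------------------------

@dataclasses.dataclass
class AnalyticDeformation:
    """A diffeomorphism phi: R^3 -> R^3 with exact Jacobian.

    ``mapping(points)`` maps an (n, 3) array; ``jac(points)`` returns the
    (n, 3, 3) Jacobian stack. Build instances through the constructors
    below; ``compose`` chains maps (outermost last) with the chain rule.
    """

    kind: str
    mapping: Callable[[np.ndarray], np.ndarray]
    jac: Callable[[np.ndarray], np.ndarray]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.mapping(np.asarray(points, dtype=float))

    def jacobian(self, points: np.ndarray) -> np.ndarray:
        return self.jac(np.asarray(points, dtype=float))

    # -- constructors --------------------------------------------------
    @staticmethod
    def identity() -> "AnalyticDeformation":
        return AnalyticDeformation(
            "identity",
            lambda p: p.copy(),
            lambda p: np.broadcast_to(np.eye(3), (len(p), 3, 3)).copy(),
        )

    @staticmethod
    def rigid(rotation: np.ndarray, translation: np.ndarray) -> "AnalyticDeformation":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be a proper orthogonal matrix")
        return AnalyticDeformation(
            "rigid",
            lambda p: p @ R.T + t,
            lambda p: np.broadcast_to(R, (len(p), 3, 3)).copy(),
        )

    @staticmethod
    def uniform_scale(s: float, center: Sequence[float] = (0, 0, 0)) -> "AnalyticDeformation":
        if s <= 0:
            raise ValueError("scale must be positive")
        c = np.asarray(center, dtype=float)
        return AnalyticDeformation(
            "uniform_scale",
            lambda p: c + s * (p - c),
            lambda p: np.broadcast_to(s * np.eye(3), (len(p), 3, 3)).copy(),
        )

    @staticmethod
    def uniaxial_stretch(
        lam: float, axis: Sequence[float], center: Sequence[float] = (0, 0, 0)
    ) -> "AnalyticDeformation":
        if lam <= 0:
            raise ValueError("stretch ratio must be positive")
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
        c = np.asarray(center, dtype=float)
        J = np.eye(3) + (lam - 1.0) * np.outer(a, a)
        return AnalyticDeformation(
            "uniaxial_stretch",
            lambda p: p + (lam - 1.0) * ((p - c) @ a)[:, None] * a,
            lambda p: np.broadcast_to(J, (len(p), 3, 3)).copy(),
        )

    @staticmethod
    def shear(
        k: float,
        direction: Sequence[float] = (1, 0, 0),
        gradient_axis: Sequence[float] = (0, 1, 0),
        center: Sequence[float] = (0, 0, 0),
    ) -> "AnalyticDeformation":
        """Simple shear: displacement k * <x-c, gradient_axis> * direction."""
        u = np.asarray(direction, dtype=float)
        u = u / np.linalg.norm(u)
        v = np.asarray(gradient_axis, dtype=float)
        v = v / np.linalg.norm(v)
        c = np.asarray(center, dtype=float)
        J = np.eye(3) + k * np.outer(u, v)
        return AnalyticDeformation(
            "shear",
            lambda p: p + k * ((p - c) @ v)[:, None] * u,
            lambda p: np.broadcast_to(J, (len(p), 3, 3)).copy(),
        )

    @staticmethod
    def billow(
        amplitude: float,
        center: Sequence[float] = (0.0, 0.0),
        radius: float = 8.0,
        direction: Sequence[float] = (0, 0, 1),
    ) -> "AnalyticDeformation":
        """Gaussian bump: phi(x) = x + A exp(-||x_plane - c||^2 / r^2) e.

        The bump profile depends only on the coordinates orthogonal to the
        displacement direction, so det J = 1 identically and the map is a
        diffeomorphism for any amplitude. Positive amplitude billows the
        dome toward the atrium (inverting concavity at large A); negative
        amplitude tethers it.
        """
        if radius <= 0:
            raise ValueError("radius must be positive")
        e = np.asarray(direction, dtype=float)
        e = e / np.linalg.norm(e)
        c2 = np.asarray(center, dtype=float)
        # orthonormal in-plane basis (orthogonal to e)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(e[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(e, helper)
        u /= np.linalg.norm(u)
        v = np.cross(e, u)
        A, r2 = amplitude, radius * radius
        c3 = c2[0] * u + c2[1] * v if len(c2) == 2 else np.asarray(c2, float)

        def _g(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
            d = p - c3
            pu = d @ u
            pv = d @ v
            g = np.exp(-(pu * pu + pv * pv) / r2)
            return g, pu, pv

        def mapping(p: np.ndarray) -> np.ndarray:
            g, _, _ = _g(p)
            return p + A * g[:, None] * e

        def jac(p: np.ndarray) -> np.ndarray:
            g, pu, pv = _g(p)
            grad = (-2.0 / r2) * (pu[:, None] * u + pv[:, None] * v) * g[:, None]
            return np.eye(3) + A * np.einsum("i,nj->nij", e, grad)

        return AnalyticDeformation("billow", mapping, jac)

    @staticmethod
    def tether(
        amplitude: float,
        center: Sequence[float] = (0.0, 0.0),
        radius: float = 8.0,
    ) -> "AnalyticDeformation":
        d = AnalyticDeformation.billow(-abs(amplitude), center, radius)
        return AnalyticDeformation("tether", d.mapping, d.jac)

    @staticmethod
    def compose(parts: Sequence["AnalyticDeformation"]) -> "AnalyticDeformation":
        """Apply ``parts`` left to right: phi = parts[-1] o ... o parts[0]."""
        parts = list(parts)

        def mapping(p: np.ndarray) -> np.ndarray:
            out = p
            for d in parts:
                out = d.mapping(out)
            return out

        def jac(p: np.ndarray) -> np.ndarray:
            J = np.broadcast_to(np.eye(3), (len(p), 3, 3)).copy()
            cur = p
            for d in parts:
                J = np.einsum("nij,njk->nik", d.jac(cur), J)
                cur = d.mapping(cur)
            return J

        return AnalyticDeformation("compose", mapping, jac)


def _truth_strain(mesh: TriMesh, d: AnalyticDeformation) -> StrainField:
    """Per-cell ground-truth strain from the analytic Jacobian at centroids.

    The Jacobian is restricted to each reference triangle's tangent basis
    exactly as the discrete measure: F = [J t1, J t2, n_def][t1, t2, n_ref]^-1
    with n_def the unit normal of the mapped tangent plane.
    """
    tris = mesh.vertices[mesh.faces]
    cent = tris.mean(axis=1)
    J = d.jacobian(cent)
    t1 = tris[:, 1] - tris[:, 0]
    t2 = tris[:, 2] - tris[:, 0]
    cr = np.cross(t1, t2)
    a_ref = 0.5 * np.linalg.norm(cr, axis=1)
    n_ref = cr / (2.0 * a_ref)[:, None]
    T1 = np.einsum("nij,nj->ni", J, t1)
    T2 = np.einsum("nij,nj->ni", J, t2)
    CR = np.cross(T1, T2)
    a_def = 0.5 * np.linalg.norm(CR, axis=1)
    n_def = CR / (2.0 * a_def)[:, None]
    B_ref = np.stack([t1, t2, n_ref], axis=2)
    B_def = np.stack([T1, T2, n_def], axis=2)
    F = B_def @ np.linalg.inv(B_ref)
    E, p1, d1 = green_lagrange(F)
    C = np.einsum("cji,cjk->cik", F, F)
    areal = a_def / a_ref - 1.0

    nv = mesh.n_vertices
    wsum = np.zeros(nv)
    v_areal = np.zeros(nv)
    v_p1 = np.zeros(nv)
    np.add.at(wsum, mesh.faces.ravel(), np.repeat(a_ref, 3))
    np.add.at(v_areal, mesh.faces.ravel(), np.repeat(a_ref * areal, 3))
    np.add.at(v_p1, mesh.faces.ravel(), np.repeat(a_ref * p1, 3))
    wsum = np.maximum(wsum, 1e-300)
    return StrainField(
        F=F, C=C, E=E, areal=areal, principal1=p1, principal1_dir=d1,
        vertex_areal=v_areal / wsum, vertex_principal1=v_p1 / wsum,
        ref_areas=a_ref,
    )


def apply_deformation(
    mesh: TriMesh, d: AnalyticDeformation
) -> tuple[TriMesh, StrainField]:
    """Map the mesh through phi and return the analytic per-cell truth strain."""
    J = d.jacobian(mesh.vertices)
    if np.any(np.linalg.det(J) <= 0):
        raise ValueError("deformation folds the surface (non-positive Jacobian)")
    deformed = TriMesh(d(mesh.vertices), mesh.faces.copy())
    return deformed, _truth_strain(mesh, d)


# ----------------------------------------------------------------------
# Cohorts and valves
# ----------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticCohort:
    """Per-(subject, label) diastole/systole pairs with index-wise truth."""

    leaflets: dict  # (subject_id, label) -> {"diastole": LeafletSurface, "systole": ...}
    truth: dict     # (subject_id, label) -> StrainField on the diastolic mesh
    deformations: dict  # (subject_id, label) -> AnalyticDeformation
    seed: int


def _default_deformation(
    kind: str, rng: np.random.Generator, amplitude: float = 4.0
) -> AnalyticDeformation:
    jitter = 1.0 + 0.1 * rng.standard_normal()
    if kind == "identity":
        return AnalyticDeformation.identity()
    if kind == "billow":
        return AnalyticDeformation.billow(
            amplitude * jitter,
            center=(rng.uniform(-2, 2), rng.uniform(-2, 2)),
            radius=8.0,
        )
    if kind == "tether":
        return AnalyticDeformation.tether(amplitude * jitter, radius=8.0)
    if kind == "uniform_scale":
        return AnalyticDeformation.uniform_scale(1.0 + 0.2 * jitter)
    raise ValueError(f"unknown cohort deformation kind: {kind}")


def make_cohort(
    n_subjects: int,
    labels: Sequence[str] = ("anterior",),
    deformation: str = "billow",
    amplitude: float = 4.0,
    n_nodes: int = 1000,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Reproducible multi-subject cohort with analytic ground truth.

    Subjects vary by annulus-radius jitter (~10 %) and per-subject
    deformation-parameter jitter; each (subject, label) carries a
    diastolic dome, its deformed systolic counterpart (identical
    connectivity), and the closed-form reference strain.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    leaflets: dict = {}
    truth: dict = {}
    defs: dict = {}
    for s in range(n_subjects):
        sid = f"S{s:02d}"
        for li, label in enumerate(labels):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            a = 12.0 * (1.0 + 0.1 * rng.standard_normal())
            b = 9.0 * (1.0 + 0.1 * rng.standard_normal())
            spec = SyntheticLeafletSpec(
                annulus_radii=(abs(a) + 4.0, abs(b) + 3.0),
                dome_height=4.0 * (1.0 + 0.1 * rng.standard_normal()),
                n_nodes=n_nodes,
                noise_sd=noise_sd,
                seed=sub_seed,
            )
            dia = make_dome_leaflet(spec)
            d = _default_deformation(deformation, rng, amplitude)
            sysm, tf = apply_deformation(dia, d)
            key = (sid, label)
            leaflets[key] = {
                "diastole": LeafletSurface(dia, label, "diastole", sid),
                "systole": LeafletSurface(sysm, label, "systole", sid),
            }
            truth[key] = tf
            defs[key] = d
    return SyntheticCohort(leaflets=leaflets, truth=truth, deformations=defs, seed=seed)


def make_valve(
    n_leaflets: int = 3,
    nodes_per_leaflet: int = 1000,
    seed: int = 0,
) -> TriMesh:
    """Assemble a fixture valve: leaflet domes arranged around a center.

    Each leaflet is preprocessed to its own uniform node budget, so a
    three-leaflet valve carries 3 x 1000 = 3000 nodes.
    """
    parts: list[TriMesh] = []
    for k in range(n_leaflets):
        spec = SyntheticLeafletSpec(
            annulus_radii=(10.0, 7.0), dome_height=3.5,
            n_nodes=nodes_per_leaflet, seed=seed + k,
        )
        leaf = make_dome_leaflet(spec)
        ang = 2.0 * np.pi * k / n_leaflets
        R = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0.0],
                [np.sin(ang), np.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        offset = np.array([13.0 * np.cos(ang), 13.0 * np.sin(ang), 0.0])
        parts.append(TriMesh(leaf.vertices @ R.T + offset, leaf.faces))
    vertices = np.vstack([p.vertices for p in parts])
    shift = np.cumsum([0] + [p.n_vertices for p in parts[:-1]])
    faces = np.vstack([p.faces + s for p, s in zip(parts, shift)])
    return TriMesh(vertices, faces)


def billow_signature_deformation(high: bool = True) -> AnalyticDeformation:
    """Deformations for the billow-signature fixture.

    ``high=True`` composes a strong in-plane stretch with a broad billow so
    the analytic 1st-principal-strain field has weighted median and IQR
    both above 0.5 (the billow signature); ``high=False`` is a gentle
    control whose median and IQR stay well below 0.5. The parameter values
    were fixed once by the committed calibration run (scripts/calibrate_fixtures.py).
    """
    if high:
        return AnalyticDeformation.compose(
            [
                AnalyticDeformation.uniform_scale(1.35),
                AnalyticDeformation.billow(11.0, center=(0.0, 0.0), radius=9.0),
            ]
        )
    return AnalyticDeformation.compose(
        [
            AnalyticDeformation.uniform_scale(1.05),
            AnalyticDeformation.billow(1.0, center=(0.0, 0.0), radius=9.0),
        ]
    )
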