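"""Individual-leaflet and population shape/strain pipelines.

Individual-leaflet route: leaflets of one anatomical label are pose-
normalized, a randomly chosen diastolic leaflet serves as the reference
whose node ordering defines the correspondence, DW-CPD carries the
reference onto every other leaflet, generalized Procrustes analysis (GPA,
rigid only — no scaling, which would corrupt strain) yields a mean shape,
and the mean is registered to each subject's diastolic and systolic
surfaces. The two registrations share the mean's indexing, which is what
turns them into a corresponded phase pair for strain.

Population route: GPA + PCA of corresponded whole-valve shapes per phase,
shape reconstruction at +/- k SD along each mode, and diastole->systole
DW-CPD registration of each reconstructed pair for strain.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .mesh_core import LeafletSurface, TriMesh
from .metrics import shape_error_report, ShapeErrorReport
from .registration import RegistrationConfig, register_dwcpd
from .strain import CorrespondedPair, StrainField, StrainSummary, strain_field, strain_summary

__all__ = [
    "ShapeSet",
    "PCAShapeModel",
    "PipelineReport",
    "align_leaflets",
    "establish_correspondence",
    "gpa_mean_shape",
    "pca_shape_model",
    "shape_at_sd",
    "leaflet_strain_pipeline",
    "population_pipeline",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ShapeSet:
    """K index-wise corresponded shapes, each N x 3 (mm)."""

    shapes: np.ndarray  # (K, N, 3)
    ids: list[str]
    faces: Optional[np.ndarray] = None  # shared connectivity, if any

    def __post_init__(self) -> None:
        self.shapes = np.asarray(self.shapes, dtype=float)
        if self.shapes.ndim != 3 or self.shapes.shape[2] != 3:
            raise ValueError("shapes must be K x N x 3")
        if len(self.ids) != len(self.shapes):
            raise ValueError("ids must align with shapes")


@dataclasses.dataclass
class PCAShapeModel:
    mean: np.ndarray            # (N, 3)
    modes: np.ndarray           # (n_modes, 3N), orthonormal rows
    sds: np.ndarray             # per-mode SD of scores, non-increasing
    explained_fraction: np.ndarray


@dataclasses.dataclass
class LeafletRecord:
    subject_id: str
    label: str
    strain: StrainField
    summary: StrainSummary
    quality_diastole: ShapeErrorReport
    quality_systole: ShapeErrorReport


@dataclasses.dataclass
class PipelineReport:
    records: list[LeafletRecord]
    reference_id: str
    seed: int
    config: RegistrationConfig
    skipped: list[tuple[str, str, str]]  # (subject, label, reason)


# ----------------------------------------------------------------------
# Pose normalization
# ----------------------------------------------------------------------

def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _canonical_pose(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray, bool]:
    """Rotation + translation to convention pose; flag if orientation is weak.

    Convention: zero centroid; area-weighted mean normal along +z; the
    leaflet's long in-plane principal axis along +x (so the transverse
    annulus-to-free-edge axis lies along +y), sign fixed by the third
    moment of the y coordinate.
    """
    t = -mesh.centroid()
    v = mesh.vertices + t
    fa = mesh.face_areas()
    normal = (mesh.face_normals() * fa[:, None]).sum(axis=0)
    nn = np.linalg.norm(normal)
    degenerate = nn < 1e-6 * fa.sum()
    if degenerate:
        return np.eye(3), t, True
    R1 = _rotation_between(normal / nn, np.array([0.0, 0.0, 1.0]))
    v = v @ R1.T
    # in-plane principal axis -> +x
    xy = v[:, :2]
    cov = xy.T @ xy / len(xy)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, -1]
    ang = np.arctan2(major[1], major[0])
    ca, sa = np.cos(-ang), np.sin(-ang)
    R2 = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    v = v @ R2.T
    # deterministic sign for y (skewness of the transverse coordinate)
    if np.sum(v[:, 1] ** 3) < 0:
        R3 = np.diag([-1.0, -1.0, 1.0])  # rotate 180 about z
        v = v @ R3.T
    else:
        R3 = np.eye(3)
    return R3 @ R2 @ R1, t, False


def align_leaflets(
    leaflets: Sequence[LeafletSurface],
) -> tuple[list[LeafletSurface], list[bool]]:
    """Pose-normalize each leaflet (centroid to origin, atrial normal +z).

    Returns aligned copies and per-leaflet flags marking surfaces whose
    orientation could not be determined (left at centroid only).
    """
    out: list[LeafletSurface] = []
    flags: list[bool] = []
    for leaf in leaflets:
        R, t, weak = _canonical_pose(leaf.mesh)
        verts = (leaf.mesh.vertices + t) @ R.T
        out.append(
            LeafletSurface(
                TriMesh(verts, leaf.mesh.faces.copy()),
                leaf.label,
                leaf.phase,
                leaf.subject_id,
            )
        )
        flags.append(weak)
        if weak:
            logger.warning(
                "orientation undetermined for %s/%s; centroid-only alignment",
                leaf.subject_id,
                leaf.label,
            )
    return out, flags


# ----------------------------------------------------------------------
# Correspondence and GPA
# ----------------------------------------------------------------------

def establish_correspondence(
    leaflets: Sequence[LeafletSurface],
    reference_index: Optional[int] = None,
    seed: int = 0,
    config: Optional[RegistrationConfig] = None,
) -> tuple[ShapeSet, int]:
    """Reference-indexed correspondences across same-label leaflets.

    A diastolic leaflet is chosen as reference (uniformly at random with
    ``seed`` unless ``reference_index`` is given) and registered onto every
    other leaflet with DW-CPD; each transformed copy inherits the
    reference's node ordering, giving an index-wise ShapeSet. Subjects
    whose registration fails to converge are excluded and logged.
    """
    labels = {l.label for l in leaflets}
    if len(labels) != 1:
        raise ValueError(f"leaflets must share one label, got {sorted(labels)}")
    cfg = config or RegistrationConfig()
    if reference_index is None:
        dia = [i for i, l in enumerate(leaflets) if l.phase == "diastole"]
        if not dia:
            raise ValueError("no diastolic leaflet available as reference")
        rng = np.random.default_rng(seed)
        reference_index = int(dia[rng.integers(len(dia))])
    ref = leaflets[reference_index]
    shapes: list[np.ndarray] = []
    ids: list[str] = []
    for i, leaf in enumerate(leaflets):
        if i == reference_index:
            shapes.append(ref.mesh.vertices.copy())
        else:
            res = register_dwcpd(leaf.mesh, ref.mesh, cfg)
            if not res.converged:
                logger.warning(
                    "registration did not converge for %s/%s; excluded",
                    leaf.subject_id,
                    leaf.label,
                )
                continue
            shapes.append(res.transformed)
        ids.append(leaf.subject_id)
    return (
        ShapeSet(np.asarray(shapes), ids, faces=ref.mesh.faces.copy()),
        reference_index,
    )


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid (rotation + translation, no scaling) least-squares alignment."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = scipy.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    t = mu_d - R @ mu_s
    return R, t


def gpa_mean_shape(
    shapes: ShapeSet, max_iter: int = 50, tol: float = 1e-8
) -> tuple[np.ndarray, ShapeSet]:
    """Generalized Procrustes mean under rigid transforms only.

    Scaling is deliberately excluded: shapes are metric (mm) and any
    Procrustes scale change would alias into strain downstream.
    """
    X = shapes.shapes.copy()
    K = len(X)
    if K == 0:
        raise ValueError("empty shape set")
    mean = X[0].copy()
    for _ in range(max_iter):
        for k in range(K):
            R, t = _kabsch(X[k], mean)
            X[k] = X[k] @ R.T + t
        new_mean = X.mean(axis=0)
        delta = float(np.linalg.norm(new_mean - mean) / max(np.linalg.norm(mean), 1e-300))
        mean = new_mean
        if delta < tol:
            break
    return mean, ShapeSet(X, list(shapes.ids), faces=shapes.faces)


# ----------------------------------------------------------------------
# PCA shape model
# ----------------------------------------------------------------------

def pca_shape_model(aligned: ShapeSet) -> PCAShapeModel:
    """PCA of flattened aligned shapes (sample covariance, K-1 denominator)."""
    X = aligned.shapes
    K, N, _ = X.shape
    mean = X.mean(axis=0)
    if K < 2:
        logger.warning("PCA with a single shape: model has zero modes")
        return PCAShapeModel(
            mean=mean,
            modes=np.zeros((0, 3 * N)),
            sds=np.zeros(0),
            explained_fraction=np.zeros(0),
        )
    D = (X - mean).reshape(K, 3 * N)
    U, s, Vt = scipy.linalg.svd(D, full_matrices=False)
    keep = s > 1e-12 * max(s[0], 1.0)
    n_modes = min(int(keep.sum()), K - 1)
    s = s[:n_modes]
    modes = Vt[:n_modes]
    sds = s / np.sqrt(K - 1)
    var = sds**2
    total = (D**2).sum() / (K - 1)
    return PCAShapeModel(
        mean=mean,
        modes=modes,
        sds=sds,
        explained_fraction=var / max(total, 1e-300),
    )


def shape_at_sd(model: PCAShapeModel, mode: int, k: float) -> np.ndarray:
    """Mean shape displaced k standard deviations along one mode."""
    if not (0 <= mode < len(model.modes)):
        if k == 0:
            return model.mean.copy()
        raise IndexError(f"mode {mode} out of range")
    disp = k * model.sds[mode] * model.modes[mode]
    return model.mean + disp.reshape(-1, 3)


# ----------------------------------------------------------------------
# Pipelines
# ----------------------------------------------------------------------

def _group_by_label(
    cohort: Sequence[LeafletSurface],
) -> dict[str, dict[str, dict[str, LeafletSurface]]]:
    """label -> subject -> phase -> surface."""
    out: dict[str, dict[str, dict[str, LeafletSurface]]] = {}
    for leaf in cohort:
        out.setdefault(leaf.label, {}).setdefault(leaf.subject_id, {})[leaf.phase] = leaf
    return out


def leaflet_strain_pipeline(
    cohort: Sequence[LeafletSurface],
    config: Optional[RegistrationConfig] = None,
    seed: int = 0,
    area_weighted: bool = True,
) -> PipelineReport:
    """Individual-leaflet strain for a cohort of diastole/systole pairs.

    Per label: align -> reference selection -> DW-CPD correspondence ->
    GPA mean -> register the mean to each subject's diastolic and systolic
    mesh -> per-cell strain between the two mean-indexed registrations.
    Stage failures skip the subject/leaflet, never the cohort.
    """
    cfg = config or RegistrationConfig()
    records: list[LeafletRecord] = []
    skipped: list[tuple[str, str, str]] = []
    reference_id = ""

    for label, subjects in sorted(_group_by_label(cohort).items()):
        pairs = {
            sid: phases
            for sid, phases in subjects.items()
            if "diastole" in phases and "systole" in phases
        }
        for sid in subjects:
            if sid not in pairs:
                skipped.append((sid, label, "missing phase"))
        if not pairs:
            continue
        ordered = sorted(pairs)
        all_surfaces = [pairs[sid][ph] for sid in ordered for ph in ("diastole", "systole")]
        aligned, _ = align_leaflets(all_surfaces)
        by_subject = {
            sid: {"diastole": aligned[2 * i], "systole": aligned[2 * i + 1]}
            for i, sid in enumerate(ordered)
        }
        dia_list = [by_subject[sid]["diastole"] for sid in ordered]
        try:
            shapeset, ref_idx = establish_correspondence(
                dia_list, seed=seed, config=cfg
            )
        except ValueError as exc:
            for sid in ordered:
                skipped.append((sid, label, f"correspondence failed: {exc}"))
            continue
        reference_id = dia_list[ref_idx].subject_id
        mean, _ = gpa_mean_shape(shapeset)
        mean_mesh = TriMesh(mean, shapeset.faces)

        for sid in ordered:
            try:
                res_d = register_dwcpd(
                    by_subject[sid]["diastole"].mesh, mean_mesh, cfg
                )
                res_s = register_dwcpd(
                    by_subject[sid]["systole"].mesh, mean_mesh, cfg
                )
                ref_mesh = TriMesh(res_d.transformed, shapeset.faces)
                def_mesh = TriMesh(res_s.transformed, shapeset.faces)
                pair = CorrespondedPair(ref_mesh, def_mesh)
                field = strain_field(pair)
                weights = field.ref_areas if area_weighted else None
                summary = strain_summary(field.principal1, weights)
                records.append(
                    LeafletRecord(
                        subject_id=sid,
                        label=label,
                        strain=field,
                        summary=summary,
                        quality_diastole=shape_error_report(
                            ref_mesh, by_subject[sid]["diastole"].mesh
                        ),
                        quality_systole=shape_error_report(
                            def_mesh, by_subject[sid]["systole"].mesh
                        ),
                    )
                )
            except Exception as exc:  # keep the cohort alive
                logger.warning("skipping %s/%s: %s", sid, label, exc)
                skipped.append((sid, label, str(exc)))
    return PipelineReport(
        records=records,
        reference_id=reference_id,
        seed=seed,
        config=cfg,
        skipped=skipped,
    )


def plot_strain_distributions(report: "PipelineReport", path) -> None:
    """Basic per-leaflet 1st-principal-strain distribution plot (one row
    per subject/leaflet, area-weighted histogram with median marker)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    records = report.records
    if not records:
        raise ValueError("no records to plot")
    fig, axes = plt.subplots(
        len(records), 1, figsize=(6, 1.4 * len(records)), sharex=True, squeeze=False
    )
    for ax, rec in zip(axes[:, 0], records):
        ax.hist(
            rec.strain.principal1,
            bins=40,
            weights=rec.strain.ref_areas,
            density=True,
            alpha=0.7,
        )
        ax.axvline(rec.summary.median, color="k", lw=1)
        ax.set_ylabel(f"{rec.subject_id}\n{rec.label}", rotation=0, ha="right", fontsize=7)
        ax.set_yticks([])
    axes[-1, 0].set_xlabel("1st principal strain")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclasses.dataclass
class PopulationResult:
    model_diastole: PCAShapeModel
    model_systole: PCAShapeModel
    shapes_diastole: dict[float, np.ndarray]  # SD level -> N x 3
    shapes_systole: dict[float, np.ndarray]
    strain: dict[float, StrainField]          # SD level -> strain of dia->sys pair
    faces: np.ndarray


def population_pipeline(
    diastole: ShapeSet,
    systole: ShapeSet,
    sd_levels: Sequence[float] = (-2.0, 0.0, 2.0),
    mode: int = 0,
    config: Optional[RegistrationConfig] = None,
) -> PopulationResult:
    """Whole-valve population analysis on corresponded shapes per phase.

    GPA + PCA run independently per phase; shapes are reconstructed at the
    requested SD levels of one mode, each diastolic reconstruction is
    registered onto its systolic counterpart with DW-CPD, and strain is
    computed on the registered pair.
    """
    if diastole.faces is None:
        raise ValueError("diastolic shape set must carry connectivity")
    cfg = config or RegistrationConfig()
    _, dia_aligned = gpa_mean_shape(diastole)
    _, sys_aligned = gpa_mean_shape(systole)
    model_d = pca_shape_model(dia_aligned)
    model_s = pca_shape_model(sys_aligned)
    faces = diastole.faces
    shapes_d: dict[float, np.ndarray] = {}
    shapes_s: dict[float, np.ndarray] = {}
    strain_by_level: dict[float, StrainField] = {}
    for level in sd_levels:
        sd_shape = shape_at_sd(model_d, mode, level)
        ss_shape = shape_at_sd(model_s, mode, level)
        shapes_d[level] = sd_shape
        shapes_s[level] = ss_shape
        res = register_dwcpd(ss_shape, sd_shape, cfg)
        pair = CorrespondedPair(
            TriMesh(sd_shape, faces), TriMesh(res.transformed, faces)
        )
        strain_by_level[level] = strain_field(pair)
    return PopulationResult(
        model_diastole=model_d,
        model_systole=model_s,
        shapes_diastole=shapes_d,
        shapes_systole=shapes_s,
        strain=strain_by_level,
        faces=faces,
    )
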