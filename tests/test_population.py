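"""Alignment, correspondence, GPA, PCA shape model, and cohort pipelines."""

import numpy as np
import pytest

from valvestrain import fixtures as fx
from valvestrain.mesh_core import LeafletSurface, TriMesh
from valvestrain.population import (
    ShapeSet,
    align_leaflets,
    establish_correspondence,
    gpa_mean_shape,
    leaflet_strain_pipeline,
    pca_shape_model,
    population_pipeline,
    shape_at_sd,
)
from valvestrain.registration import RegistrationConfig


def _rot(axis, deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


def _leaf(mesh, sid="S00", phase="diastole", label="anterior"):
    return LeafletSurface(mesh, label, phase, sid)


# ----------------------------------------------------------------------
# Alignment
# ----------------------------------------------------------------------

def test_align_canonical_leaflet_is_fixed_point(dome300):
    aligned, flags = align_leaflets([_leaf(dome300)])
    again, _ = align_leaflets(aligned)
    np.testing.assert_allclose(
        again[0].mesh.vertices, aligned[0].mesh.vertices, atol=1e-9
    )
    assert not flags[0]


def test_align_recovers_flipped_leaflet(dome300):
    R = _rot([1, 0, 0], 180.0)
    flipped = TriMesh(dome300.vertices @ R.T, dome300.faces)
    aligned, _ = align_leaflets([_leaf(flipped)])
    mesh = aligned[0].mesh
    fa = mesh.face_areas()
    mean_normal = (mesh.face_normals() * fa[:, None]).sum(axis=0)
    assert mean_normal[2] > 0


def test_align_two_poses_of_same_leaflet_coincide(dome300):
    from valvestrain.metrics import msd

    a = TriMesh(
        dome300.vertices @ _rot([0.3, 1, 0.1], 25.0).T + np.array([5.0, -3.0, 2.0]),
        dome300.faces,
    )
    b = TriMesh(
        dome300.vertices @ _rot([1, -0.5, 0.7], -40.0).T + np.array([-1.0, 8.0, 0.5]),
        dome300.faces,
    )
    aligned, _ = align_leaflets([_leaf(a, "A"), _leaf(b, "B")])
    assert msd(aligned[0].mesh, aligned[1].mesh) < 1e-6


# ----------------------------------------------------------------------
# Correspondence
# ----------------------------------------------------------------------

def test_correspondence_single_leaflet_is_reference(dome300):
    shapeset, ref_idx = establish_correspondence([_leaf(dome300)], seed=0)
    assert ref_idx == 0
    np.testing.assert_array_equal(shapeset.shapes[0], dome300.vertices)


def test_correspondence_identical_leaflets_collapse_to_reference(dome300):
    leaflets = [_leaf(dome300.copy(), f"S{i}") for i in range(3)]
    cfg = RegistrationConfig(max_iter=60)
    shapeset, ref_idx = establish_correspondence(leaflets, seed=0, config=cfg)
    ref = shapeset.shapes[ref_idx]
    for row in shapeset.shapes:
        assert np.abs(row - ref).max() < 1e-3


def test_correspondence_requires_single_label(dome300):
    pair = [_leaf(dome300, "A", label="anterior"), _leaf(dome300, "B", label="septal")]
    with pytest.raises(ValueError, match="label"):
        establish_correspondence(pair)


def test_correspondence_reference_seed_is_deterministic(dome300):
    leaflets = [_leaf(dome300.copy(), f"S{i}") for i in range(4)]
    _, idx_a = establish_correspondence(leaflets, seed=7)
    _, idx_b = establish_correspondence(leaflets, seed=7)
    assert idx_a == idx_b


# ----------------------------------------------------------------------
# GPA
# ----------------------------------------------------------------------

def _shapeset(arrays):
    return ShapeSet(np.asarray(arrays), [f"S{i}" for i in range(len(arrays))])


def test_gpa_copies_return_the_shape(dome300):
    mean, _ = gpa_mean_shape(_shapeset([dome300.vertices] * 4))
    np.testing.assert_allclose(mean, dome300.vertices, atol=1e-9)


def test_gpa_rigid_pair_has_zero_spread(dome300):
    moved = dome300.vertices @ _rot([0, 0, 1], 70.0).T + np.array([2.0, 1.0, -4.0])
    mean, aligned = gpa_mean_shape(_shapeset([dome300.vertices, moved]))
    assert np.abs(aligned.shapes[0] - aligned.shapes[1]).max() < 1e-8
    assert np.abs(aligned.shapes[0] - mean).max() < 1e-8


def test_gpa_mean_is_average_of_aligned(dome300):
    rng = np.random.default_rng(0)
    shapes = [dome300.vertices.copy() for _ in range(3)]
    shapes[1] = shapes[1].copy()
    shapes[1][10] += rng.normal(0, 0.5, 3)
    mean, aligned = gpa_mean_shape(_shapeset(shapes))
    np.testing.assert_allclose(mean, aligned.shapes.mean(axis=0), atol=1e-12)


def test_gpa_invariant_under_common_rigid_motion(dome300):
    rng = np.random.default_rng(1)
    shapes = [
        dome300.vertices + rng.normal(0, 0.2, dome300.vertices.shape)
        for _ in range(3)
    ]
    mean_a, _ = gpa_mean_shape(_shapeset(shapes))
    R = _rot([1, 1, 0], 33.0)
    t = np.array([4.0, 0.0, -2.0])
    moved = [s @ R.T + t for s in shapes]
    mean_b, _ = gpa_mean_shape(_shapeset(moved))
    # compare via Procrustes distance: align mean_b back onto mean_a
    from valvestrain.population import _kabsch

    Rk, tk = _kabsch(mean_b, mean_a)
    np.testing.assert_allclose(mean_b @ Rk.T + tk, mean_a, atol=1e-8)


# ----------------------------------------------------------------------
# PCA shape model
# ----------------------------------------------------------------------

def test_pca_one_factor_family(dome300):
    u = np.zeros_like(dome300.vertices)
    u[:, 2] = np.linspace(-1, 1, len(u))
    shapes = [dome300.vertices + t * u for t in (-2, -1, 0, 1, 2)]
    model = pca_shape_model(_shapeset(shapes))
    assert model.explained_fraction[0] > 0.999
    np.testing.assert_allclose(model.mean, dome300.vertices, atol=1e-12)


def test_pca_modes_orthonormal_and_sds_sorted(dome300):
    rng = np.random.default_rng(2)
    shapes = [dome300.vertices + rng.normal(0, 0.3, dome300.vertices.shape) for _ in range(5)]
    model = pca_shape_model(_shapeset(shapes))
    gram = model.modes @ model.modes.T
    assert np.abs(gram - np.eye(len(gram))).max() < 1e-10
    assert np.all(np.diff(model.sds) <= 1e-12)
    assert model.explained_fraction.sum() <= 1.0 + 1e-10
    assert len(model.modes) == min(len(shapes) - 1, 3 * dome300.n_vertices)


def test_shape_at_sd_linearity(dome300):
    rng = np.random.default_rng(3)
    shapes = [dome300.vertices + rng.normal(0, 0.3, dome300.vertices.shape) for _ in range(4)]
    model = pca_shape_model(_shapeset(shapes))
    np.testing.assert_allclose(shape_at_sd(model, 0, 0.0), model.mean, atol=1e-12)
    avg = 0.5 * (shape_at_sd(model, 0, 2.0) + shape_at_sd(model, 0, -2.0))
    np.testing.assert_allclose(avg, model.mean, atol=1e-10)


def test_pca_single_shape_warns_and_has_no_modes(dome300):
    model = pca_shape_model(_shapeset([dome300.vertices]))
    assert len(model.modes) == 0
    np.testing.assert_allclose(shape_at_sd(model, 0, 0.0), model.mean)


# ----------------------------------------------------------------------
# Pipelines
# ----------------------------------------------------------------------

def _cohort_surfaces(cohort):
    return [leaf for phases in cohort.leaflets.values() for leaf in phases.values()]


def test_leaflet_pipeline_null_cohort_strain_free():
    cohort = fx.make_cohort(2, deformation="identity", n_nodes=250, seed=1)
    report = leaflet_strain_pipeline(_cohort_surfaces(cohort), seed=0)
    assert len(report.records) == 2
    for rec in report.records:
        assert abs(rec.summary.median) < 0.02
        assert rec.quality_diastole.msd < 0.5


def test_leaflet_pipeline_deterministic():
    cohort = fx.make_cohort(2, deformation="billow", n_nodes=200, seed=2)
    rep_a = leaflet_strain_pipeline(_cohort_surfaces(cohort), seed=0)
    rep_b = leaflet_strain_pipeline(_cohort_surfaces(cohort), seed=0)
    assert rep_a.reference_id == rep_b.reference_id
    for ra, rb in zip(rep_a.records, rep_b.records):
        assert ra.summary.median == rb.summary.median
        np.testing.assert_array_equal(ra.strain.principal1, rb.strain.principal1)


def test_leaflet_pipeline_skips_missing_phase(dome300):
    surfaces = [
        _leaf(dome300, "S0", "diastole"),
        _leaf(dome300, "S0", "systole"),
        _leaf(dome300, "S1", "diastole"),  # no systole
    ]
    report = leaflet_strain_pipeline(surfaces, seed=0)
    assert ("S1", "anterior", "missing phase") in report.skipped
    assert {r.subject_id for r in report.records} == {"S0"}


def test_strain_distribution_plot_written(tmp_path):
    from valvestrain.population import plot_strain_distributions

    cohort = fx.make_cohort(1, deformation="billow", n_nodes=150, seed=6)
    report = leaflet_strain_pipeline(
        [leaf for phases in cohort.leaflets.values() for leaf in phases.values()],
        seed=0,
    )
    out = tmp_path / "dist.png"
    plot_strain_distributions(report, out)
    assert out.stat().st_size > 0


def test_population_pipeline_single_subject(dome300):
    deformed, _ = fx.apply_deformation(
        dome300, fx.AnalyticDeformation.billow(3.0, radius=8.0)
    )
    dia = ShapeSet(dome300.vertices[None], ["S0"], faces=dome300.faces)
    sysm = ShapeSet(deformed.vertices[None], ["S0"], faces=dome300.faces)
    result = population_pipeline(dia, sysm, sd_levels=(0.0,))
    np.testing.assert_allclose(
        result.model_diastole.mean, result.shapes_diastole[0.0]
    )
    assert len(result.model_diastole.modes) == 0
    assert 0.0 in result.strain


def test_population_pipeline_mean_strain_bounded_by_cohort():
    """Mean-shape strain should not exceed every subject's strain wildly;
    sanity ordering on a constructed cohort with a common deformation."""
    rng = np.random.default_rng(4)
    base = fx.make_dome_leaflet(fx.SyntheticLeafletSpec(n_nodes=200, seed=5))
    d = fx.AnalyticDeformation.billow(3.0, radius=8.0)
    dia_shapes, sys_shapes, subject_medians = [], [], []
    from valvestrain.strain import CorrespondedPair, strain_field, strain_summary

    for k in range(4):
        jitter = rng.normal(0, 0.15, base.vertices.shape)
        dia_v = base.vertices + jitter
        sys_v = d(dia_v)
        dia_shapes.append(dia_v)
        sys_shapes.append(sys_v)
        f = strain_field(CorrespondedPair(TriMesh(dia_v, base.faces), TriMesh(sys_v, base.faces)))
        subject_medians.append(strain_summary(f.principal1, f.ref_areas).median)
    dia = ShapeSet(np.asarray(dia_shapes), [f"S{i}" for i in range(4)], faces=base.faces)
    sysm = ShapeSet(np.asarray(sys_shapes), [f"S{i}" for i in range(4)], faces=base.faces)
    result = population_pipeline(dia, sysm, sd_levels=(0.0,))
    from valvestrain.strain import strain_summary as ss

    mean_field = result.strain[0.0]
    mean_median = ss(mean_field.principal1, mean_field.ref_areas).median
    spread = np.std(subject_medians)
    assert mean_median < max(subject_medians) + 2 * spread + 0.1
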