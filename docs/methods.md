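# Methods

## Problem and scope

`valvestrain` quantifies how much an atrioventricular valve leaflet
stretches between the open (mid-diastolic) and closed (mid-systolic)
cardiac phases, starting from triangulated surface meshes of the leaflet's
atrial side. Segmentation of the underlying 3D echo images is out of
scope; the package takes meshes (PLY/STL/OBJ) and produces per-triangle
strain fields, leaflet-level distribution summaries, and population-level
shape statistics. Because the two phase meshes generally have different
triangulations, the core problem is nonrigid correspondence: which
material point on the diastolic surface becomes which point on the
systolic surface. That correspondence is established by
distance-weighted coherent point drift (DW-CPD) registration.

## Surface preprocessing

Inputs are cleaned (duplicate faces, zero-area cells, unreferenced
vertices removed; surviving coordinates untouched), smoothed, and remeshed
to a fixed uniform budget of 1000 nodes per leaflet so that every surface
in a cohort carries the same number of vertices. All coordinates are
millimetres throughout; no internal rescaling is performed, because the
registration parameters beta (mm) and gamma (1/mm) and the reported
distances carry physical units.

**Taubin smoothing** (default 10 iterations, pass band 0.05) alternates a
shrinking umbrella-Laplacian step (weight lambda) with an inflating step
(weight mu < 0). The pass band k_pb under-determines the pair, so lambda
is fixed at 0.33 and mu follows from the transfer-function relation
k_pb = 1/lambda + 1/mu. For pass bands at or beyond 1/lambda — where no
negative mu exists for a fixed lambda — lambda is reduced to 0.9/k_pb, so
both coefficients shrink toward zero and the filter degrades gracefully to
the identity. Boundary vertices are special-cased: leaflet free edges
must not erode, so the umbrella vector of a boundary vertex (over its two
boundary neighbours) is projected onto the local polyline tangent. The
free edge is therefore only redistributed along itself, never pulled
inward; boundary vertices with an irregular number of boundary neighbours
are held fixed.

**Uniform remeshing** is an area-weighted centroidal-clustering scheme.
The surface is midpoint-subdivided to a fine proxy (≥ ~18x the target
budget), fine vertices are partitioned into exactly `n_nodes` clusters by
weighted k-means (weights = barycentric vertex areas; fixed seed, default
0, for reproducibility), and the cluster adjacency is dualized: every fine
triangle whose three corners lie in three distinct clusters contributes
one output triangle. Cluster sites are the weighted cluster centroids
projected back onto the input surface; clusters that touch an open
boundary have their site projected onto the boundary polyline instead,
which keeps the free edge from eroding (without this the dual mesh loses
~8–10 % of the surface area at leaflet scales). If a cluster ends up
without a dual triangle the clustering is retried with a shifted seed (up
to 3 times) before failing with guidance. The output vertex count equals
the requested budget exactly; total area is preserved to within 2 % on
leaflet-scale surfaces.

**Clipping along a margin curve** assigns every vertex a signed side value
relative to the projected closed curve (sign of the offset along curve
tangent x surface normal), splits triangles crossing the zero level set by
linear interpolation, and returns the largest connected component on the
requested side. Which side is the atrial one is not guessable from the
data, so it is an explicit flag. A curve feature strictly interior to a
single triangle cannot be represented by this vertex-field construction;
curves are expected to be resolved by the mesh, which holds for
margin curves on segmentation-scale meshes.

## Distance-weighted coherent point drift

The moving point set Y (M x 3, the mid-diastolic mesh nodes) is treated as
the centroids of an isotropic Gaussian mixture with uniform priors fitted
to the fixed set X (N x 3, mid-systolic) by EM. An optional uniform
component with weight w absorbs outliers; w defaults to 0 because
segmented leaflet surfaces contain few outliers. The transform is
T(Y) = Y0 + G W, where G is the Gaussian Gram matrix
g_ij = exp(-||y0_i - y0_j||² / (2 beta²)) and W the kernel weights; the
objective is the negative log-likelihood plus the motion-coherence
penalty (alpha/2) tr(Wᵀ G W).

The distance-weighted variant multiplies each E-step numerator by
exp(-gamma d_mn) before normalization. Distant candidate matches are
suppressed, which prevents the spurious global matches that plain CPD
produces when leaflet concavity inverts (billow). The decay is folded
into the Gaussian numerator and the column is renormalized including the
unchanged uniform term, so each fixed point still receives a proper
probability distribution and gamma = 0 reduces *exactly* to standard CPD
(verified per-iteration against an independent scalar-loop CPD
implementation).

Update cycle per iteration:

1. **E-step**: posteriors P_mn from the decayed Gaussian kernels at the
   current T(Y) and sigma²;
2. **M-step**: solve (G + alpha sigma² diag(P1)⁻¹) W = diag(P1)⁻¹ P X − Y0
   (symmetric positive definite; Cholesky with a general-solve fallback);
   rows with posterior mass below 1e-12 are floored at 1e-12;
3. move the points, then update sigma² = Σ P_mn d_mn² / (3 Σ P_mn) at the
   *new* positions, floored at 1e-10.

sigma² is initialized to the mean squared inter-set distance divided by 3.
Convergence is declared when the relative change of the objective falls
below `tol` (default 1e-6), or immediately when sigma² reaches its floor
(perfect alignment; iterating further would make the M-step system
numerically singular). Non-convergence returns a result flagged
`converged=False` with a warning rather than raising.

Defaults are alpha = 1, beta = 5 mm, gamma = 0.05 /mm, the settings used
for leaflet tracking across all valve types; they are deliberately not
normalized away because they encode physical length scales (beta: the
coherence radius of the displacement field; 1/gamma = 20 mm: the distance
at which a candidate match is down-weighted by e).

Known property of the decay: on a pure translation field the DW-CPD fixed
point retains a small (~1–2 %) shrinkage bias in the recovered
displacement, because the decay prefers shorter matches; gamma = 0
recovers translations to machine precision. This is the deliberate price
of locality and is negligible relative to inter-phase leaflet motion.

The Gram matrix is built and solved densely; with M ≤ ~3000 nodes per
valve this is seconds of work, and no low-rank approximation is used.

## Membrane strain

Given two corresponded meshes (identical connectivity, index-wise vertex
correspondence), each triangle's deformation gradient is the unique linear
map carrying the reference edge vectors and unit normal onto the deformed
ones:

    F = [T1  T2  n_def] [t1  t2  n_ref]⁻¹   (columns),

with t1 = v1 − v0, t2 = v2 − v0 and n = t1 x t2 / ||t1 x t2||. Unit
normals are used in both bases, so the out-of-plane direction carries zero
strain: this is a membrane measure, and thickness change is unobservable
from surfaces. Derived quantities per cell: areal strain
(A_def − A_ref)/A_ref with A the half-cross-product triangle area; right
Cauchy–Green tensor C = FᵀF; Green–Lagrange tensor E = (C − I)/2; and the
1st principal strain, the largest eigenvalue of E (maximum tensile
strain), with its eigenvector sign fixed so the largest-magnitude
component is positive. If the top two eigenvalues are numerically tied
(< 1e-12 apart) the reported direction is the candidate best aligned with
the first edge vector — an arbitrary but deterministic tie-break.
Rigid motions produce exactly zero strain; a uniform in-plane scale s
produces areal strain s² − 1 and principal strain (s² − 1)/2.

Vertex fields are reference-area-weighted averages of incident cells, and
distribution summaries (median, IQR, mean, SD) are area-weighted over
cells by default, making both insensitive to mesh resolution; an
unweighted flag exists. Weighted quantiles use Hazen-type plotting
positions ((cumw − w/2)/W with linear interpolation), which reduce to the
familiar midpoint-of-central-order-statistics median for equal weights.
The **billow signature** flag marks a leaflet whose weighted median *and*
IQR of 1st principal strain both exceed 0.5 — the distributional pattern
associated with leaflet billow/prolapse: widespread high stretch (median)
plus strong spatial heterogeneity (IQR).

## Individual-leaflet pipeline

Per anatomical label (anterior / posterior / septal):

1. **Pose normalization**: each leaflet is translated to zero centroid and
   rotated so its area-weighted mean normal (the atrial direction) points
   along +z and its long in-plane principal axis along +x, with the
   transverse sign fixed by the third moment of the y coordinate.
   Degenerate normal consensus leaves the pose unchanged and sets a flag
   (the manual-override hook for badly folded surfaces).
2. **Correspondence**: one diastolic leaflet is selected as the reference
   (uniformly at random under a config seed, or by explicit index; the
   choice is recorded in provenance) and registered *onto* every other
   leaflet with DW-CPD. Each transformed copy inherits the reference's
   node ordering, yielding an index-wise corresponded shape set. The
   direction matters: moving the reference keeps all shapes
   reference-indexed.
3. **Mean shape**: generalized Procrustes analysis under rigid transforms
   only. Scaling is deliberately excluded — shapes are metric (mm) and a
   Procrustes scale factor would alias directly into the strain computed
   downstream.
4. **Phase pair**: the mean shape is registered to each subject's
   diastolic and systolic mesh. The two registrations share the mean's
   indexing, which is exactly what makes them a corresponded pair; strain
   is then computed between them, and registration quality (MSD, HD95
   against the subject's own meshes) is reported alongside.

Stage failures (missing phase, non-convergence, degenerate cells) skip the
subject/leaflet with a logged reason; they never abort the cohort.

## Population pipeline

For whole valves with correspondence already established per phase: GPA
(rigid) aligns the shapes, PCA of the flattened aligned coordinates
(sample covariance, K−1 denominator) gives orthonormal modes and per-mode
SDs, and shapes are reconstructed at chosen SD levels (default −2, 0, +2)
along a mode. Each reconstructed diastolic shape is registered onto its
systolic counterpart with DW-CPD and strain is computed on the registered
pair — mirroring the per-subject analysis at the population level.

## Shape-agreement metrics

MSD is the mean of the pooled bidirectional vertex-to-surface distances
(exact point-to-triangle, mm); HD95 is the 95th percentile (linear
interpolation between order statistics) of the same pooled sample.
Vertex sampling (rather than face supersampling) is the default because
pipeline meshes are uniformly remeshed at 1000 nodes, where vertex
sampling is unbiased. Pooling both directions into one sample (rather
than averaging two directional means) is the common "mean symmetric
surface distance" convention; a flag switches to the averaged variant.
Closest-point queries are KD-tree-prefiltered and made exact by a bound
check (any face whose centroid could still beat the current bound is also
examined).

## Synthetic fixtures

The generator stands in for patient 3DE data and the FEA benchmark: dome
leaflets z = h(1 − rho²) over an elliptical annulus (default semi-axes
12 x 9 mm, height 4 mm — leaflet-scale dimensions), remeshed to 1000 nodes,
with optional seeded coordinate noise. Deformations are closed-form
diffeomorphisms with exact Jacobians: rigid, uniform scale, uniaxial
stretch, simple shear, and a Gaussian "billow" bump
phi(x) = x + A exp(−||x_perp − c||²/r²) e. The bump displaces along a
fixed direction e (the dome axis, +z) with a profile independent of the
e-coordinate, so det J = 1 identically — the map can never fold, and the
Jacobian is exact and simple. For dome leaflets +z is within a few
degrees of the surface normal, so the deformation still reproduces the
concavity-inversion regime that motivates the distance decay. Negative
amplitude gives the tethered counterpart.

Ground-truth strain is the analytic Jacobian at each reference-cell
centroid pushed through the same tangent-basis algebra as the discrete
measure, so discrete and true fields are directly comparable per cell.
Affine deformations agree to machine precision; for curved deformations
the discrepancy is pure discretization error, measured once by the
committed refinement study (`scripts/calibrate_fixtures.py`,
docs/calibration.md) and frozen into test tolerances with ~5x margin.
Cohorts jitter annulus radii (~10 %) and deformation parameters per
subject and are pure functions of (spec, seed).

What the fixtures do *not* emulate: echo image formation, speckle,
segmentation error beyond Gaussian coordinate noise, annular dynamics,
chordal tethering, or independent triangulations of the two phases beyond
what registration-based correspondence already handles. Passing tests
therefore demonstrate correctness of the algorithms under known smooth
deformations, not clinical accuracy on real images.

## Problem sizes and numerical choices

Tests and the acceptance script run leaflets at 250–1000 nodes and
cohorts of 2–3 subjects — large enough to exercise every code path at the
paper-scale node budget where it matters (the budget checks use the full
1000/3000 nodes) while keeping the suite fast. Tolerances: posterior
columns normalize to 1e-10; M-step relative residual < 1e-8; strain
rigid-invariance at 1e-9; discretization tolerances per the calibration
log. Degenerate inputs (zero-area cells, sigma² ≤ 0, w = 1, folded
deformations, empty clip results) raise descriptive errors naming the
offending cell or parameter.

## Known limitations

* Strain is membrane-only; thickness and bending are not resolved.
* The distance decay's locality bias (above) slightly shrinks very smooth
  global motions; set gamma = 0 if pure global alignment is the goal.
* The remeshing dual triangulation assumes a surface fine enough (after
  internal subdivision) that every cluster borders ≥ 2 others; extremely
  coarse or fragmented inputs fail with guidance.
* Pose normalization relies on a consistent atrial orientation of input
  normals; surfaces with near-zero mean normal are flagged, mirroring the
  manual orientation fix used in practice for misoriented valves.
* clip-by-curve requires the curve to be resolved by the mesh resolution.
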