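# valvestrain

Registration-informed leaflet strain for atrioventricular heart valves.

Valve leaflet strain — how much the tissue stretches between the open
(mid-diastolic) and closed (mid-systolic) phases — is a promising marker
of valvular disease mechanics, but measuring it noninvasively from 3D
echo-derived surface models is hard: the two phase meshes have no shared
triangulation, and leaflets can deform dramatically (billow/prolapse
inverts the surface concavity). `valvestrain` is a library + CLI for
researchers working with segmentation-derived leaflet surfaces. It

* preprocesses atrial surface meshes (clean → Taubin smooth → uniform
  remesh to a fixed 1000-node budget; optional clip along a margin curve);
* establishes dense correspondence between phases with
  **distance-weighted coherent point drift (DW-CPD)** registration;
* computes per-triangle **areal** and **Green–Lagrange membrane strain**;
* runs individual-leaflet and population (GPA + PCA) pipelines, with
  synthetic leaflet fixtures carrying analytic ground-truth strain.

## Method at a glance

DW-CPD treats the moving node set Y (M×3, mid-diastole) as centroids of a
Gaussian mixture fitted to the fixed set X (N×3, mid-systole) by EM,
with transform T(Y) = Y₀ + GW, Gram matrix
g_ij = exp(−‖y₀ᵢ−y₀ⱼ‖²/2β²), and objective
E = −Σₙ log p(xₙ) + (α/2) tr(WᵀGW). The E-step posterior is reweighted by
a distance decay,

    P_mn ∝ exp(−‖xₙ − T(yₘ)‖²/2σ²) · exp(−γ‖xₙ − T(yₘ)‖),

which suppresses distant candidate matches and prevents the global
distortions plain CPD produces under concavity inversion; γ = 0 recovers
standard CPD exactly. Defaults: α = 1, β = 5 mm, γ = 0.05 mm⁻¹.

From a corresponded pair, each triangle's deformation gradient is
F = [T₁ T₂ n_def][t₁ t₂ n_ref]⁻¹ (edge vectors and unit normals), giving
areal strain (A_def − A_ref)/A_ref and Green–Lagrange strain
E = (FᵀF − I)/2, whose largest eigenvalue is the 1st principal strain.
A leaflet whose area-weighted median *and* IQR of 1st principal strain
both exceed 0.5 is flagged with the billow signature.

## Worked example

Track a synthetic dome leaflet through a 4 mm billow deformation and
compare the recovered strain with the analytic ground truth:

```python
import numpy as np
from valvestrain import fixtures as fx
from valvestrain import (RegistrationConfig, register_dwcpd, TriMesh,
                         CorrespondedPair, strain_field, strain_summary,
                         msd, hausdorff95)

diastole = fx.make_dome_leaflet(fx.SyntheticLeafletSpec(n_nodes=1000, seed=0))
billow = fx.AnalyticDeformation.billow(amplitude=4.0, center=(0.0, 0.0), radius=8.0)
systole, truth = fx.apply_deformation(diastole, billow)

result = register_dwcpd(fixed=systole, moving=diastole, config=RegistrationConfig())
tracked = TriMesh(result.transformed, diastole.faces)
print(f"converged in {result.n_iter} iterations, "
      f"MSD = {msd(tracked, systole):.2e} mm, HD95 = {hausdorff95(tracked, systole):.2e} mm")

field = strain_field(CorrespondedPair(diastole, tracked))
s = strain_summary(field.principal1, field.ref_areas)
print(f"1st principal strain: median = {s.median:.3f}, IQR = {s.iqr:.3f}, "
      f"billow flag = {s.billow_flag}")
print(f"MAE vs analytic truth: {np.abs(field.principal1 - truth.principal1).mean():.4f}")
```

Output:

```
converged in 17 iterations, MSD = 6.01e-07 mm, HD95 = 1.98e-06 mm
1st principal strain: median = 0.193, IQR = 0.074, billow flag = False
MAE vs analytic truth: 0.0037
```

The registered surface matches the systolic target to sub-micrometre MSD,
and the per-cell 1st principal strain agrees with the closed-form truth to
a mean absolute error of 0.004. A moderate 4 mm billow stretches the
leaflet (median strain 0.19) but does not reach the billow signature
(median and IQR both > 0.5), which marks pathological prolapse.

## Command line

```bash
valvestrain synth --n-subjects 3 --out cohort/          # synthetic cohort
valvestrain register --fixed sys.ply --moving dia.ply --out reg.ply --report reg.json
valvestrain strain --ref dia.ply --def reg.ply --out strain.csv
valvestrain metrics --a reg.ply --b sys.ply --out metrics.json
valvestrain leaflet-pipeline --cohort cohort/cohort.yaml --out report/
valvestrain population --cohort cohort/cohort.yaml --sd -2 --sd 0 --sd 2 --out pop/
```

Every run writes a provenance JSON (config echo, version, seed, input
hashes) beside its outputs.

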