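"""One-off calibration of fixture parameters and discretization tolerances.

Run from the repository root:

    python scripts/calibrate_fixtures.py

Produces the numbers frozen into the test suite and documented in
docs/calibration.md:

* mesh-refinement study of the discrete-vs-analytic strain error for the
  4 mm billow deformation (fixes the MAE tolerances used in tests);
* registration quality on the dome -> billow pair at 1000 nodes (fixes the
  MSD / strain-MAE thresholds);
* analytic strain summaries of the billow-signature deformations (confirms
  the high fixture's weighted median and IQR clear 0.5 with margin and the
  low control stays well below).
"""

from __future__ import annotations

import time

import numpy as np

from valvestrain import fixtures as fx
from valvestrain.mesh_core import TriMesh
from valvestrain.metrics import hausdorff95, msd, strain_mae
from valvestrain.registration import RegistrationConfig, register_dwcpd
from valvestrain.strain import CorrespondedPair, strain_field, strain_summary


def refinement_study() -> None:
    print("# Discrete vs analytic strain, billow amplitude 4 mm, true correspondence")
    d = fx.AnalyticDeformation.billow(4.0, center=(0.0, 0.0), radius=8.0)
    for n in (500, 1000, 2000, 4000):
        mesh = fx.make_dome_leaflet(fx.SyntheticLeafletSpec(n_nodes=n, seed=0))
        deformed, truth = fx.apply_deformation(mesh, d)
        field = strain_field(CorrespondedPair(mesh, deformed))
        print(
            f"n={n:5d}  principal1 MAE={strain_mae(field.principal1, truth.principal1):.5f}"
            f"  areal MAE={strain_mae(field.areal, truth.areal):.5f}"
        )


def registration_study() -> None:
    print("# Registration recovery, dome -> billow (4 mm, 1000 nodes, seed 0)")
    mesh = fx.make_dome_leaflet(fx.SyntheticLeafletSpec(n_nodes=1000, seed=0))
    d = fx.AnalyticDeformation.billow(4.0, center=(0.0, 0.0), radius=8.0)
    deformed, truth = fx.apply_deformation(mesh, d)
    t0 = time.time()
    res = register_dwcpd(deformed, mesh, RegistrationConfig())
    reg = TriMesh(res.transformed, mesh.faces)
    field = strain_field(CorrespondedPair(mesh, reg))
    print(
        f"iters={res.n_iter} time={time.time() - t0:.1f}s "
        f"MSD={msd(reg, deformed):.2e} mm HD95={hausdorff95(reg, deformed):.2e} mm"
    )
    print(
        f"principal1 MAE={strain_mae(field.principal1, truth.principal1):.5f} "
        f"areal MAE={strain_mae(field.areal, truth.areal):.5f}"
    )


def signature_study() -> None:
    print("# Billow-signature fixtures, analytic summaries (area-weighted)")
    for n in (600, 1000):
        mesh = fx.make_dome_leaflet(fx.SyntheticLeafletSpec(n_nodes=n, seed=0))
        for label, high in (("high", True), ("low", False)):
            d = fx.billow_signature_deformation(high)
            _, truth = fx.apply_deformation(mesh, d)
            s = strain_summary(truth.principal1, truth.ref_areas)
            print(
                f"n={n:4d} {label:4s}  median={s.median:.3f} iqr={s.iqr:.3f} "
                f"flag={s.billow_flag}"
            )


if __name__ == "__main__":
    np.set_printoptions(precision=5)
    refinement_study()
    registration_study()
    signature_study()
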