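#!/usr/bin/env python
"""Image-quality deep dive: NPS curves and MTF curves per method.

Reconstructs the epoxy rod (three slices) with FBP and with both IR methods
at their MTF-matched strengths, estimates radial noise power spectra from
neighboring-slice subtractions, and writes NPS/MTF curves as two-column CSV
files plus a summary figure.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from cacstudy import iq_metrics, recon_fbp, recon_ir, study_runner
from cacstudy.study_runner import StudyConfig, _StudyEngine, select_lambdas

OUT = Path("results/image_quality")
OUT.mkdir(parents=True, exist_ok=True)

config = StudyConfig()
engine = _StudyEngine(config, seed=1, verbose=True)
grid, geom, mats = engine.grid, engine.geom, engine.materials

mediums = {}
for reg in ("TV", "GAMMA"):
    _, levels, _ = select_lambdas(engine, reg)
    mediums[reg] = levels["medium"]

frames = study_runner.PROTOCOL_FRAMES["CNP"]
epoxy_sinos = [engine.epoxy_sino(frames, seed, slice_tag=s) for s, seed in enumerate((11, 12, 13))]

slices = {"FBP": [recon_fbp.fbp(s, config.kernel, grid, mats).image for s in epoxy_sinos]}
for reg, lam in mediums.items():
    recs, _ = recon_ir.solve_batch(
        epoxy_sinos, geom, grid, mats, [lam] * 3,
        recon_ir.IrConfig(regularizer=reg, n_iterations=config.ir_iterations),
    )
    slices[reg] = [r.image for r in recs]

fig, (ax_nps, ax_mtf) = plt.subplots(1, 2, figsize=(10, 4))
summary = []
cardiac_sinos = engine.cardiac_sinos(15, 21)
for method, imgs in slices.items():
    curve = iq_metrics.radial_nps(
        imgs, (grid.dy, grid.dx), roi_size=32,
        interior_mask=engine.epoxy.interior_mask()[engine.bench_k],
    )
    pd.DataFrame({"frequency_cyc_mm": curve.frequency, "power_hu2_mm2": curve.power}).to_csv(
        OUT / f"nps_{method.lower()}.csv", index=False
    )
    ax_nps.plot(curve.frequency, curve.normalized(), label=method)

    if method == "FBP":
        img = recon_fbp.fbp(cardiac_sinos[engine.bench_k], config.kernel, grid, mats).image
    else:
        recs, _ = recon_ir.solve_batch(
            [cardiac_sinos[engine.bench_k]], geom, grid, mats, [mediums[method]],
            recon_ir.IrConfig(regularizer=method, n_iterations=config.ir_iterations),
        )
        img = recs[0].image
    mtf = iq_metrics.mtf_from_gap(img, engine.cardiac.gap, (grid.dy, grid.dx))
    pd.DataFrame({"frequency_cyc_mm": mtf.frequency, "modulation": mtf.modulation}).to_csv(
        OUT / f"mtf_{method.lower()}.csv", index=False
    )
    sel = mtf.frequency <= 1.2
    ax_mtf.plot(mtf.frequency[sel], mtf.modulation[sel], label=method)
    summary.append(
        {
            "method": method,
            "nps_peak_freq_cyc_mm": float(curve.frequency[np.argmax(curve.power)]),
            "mtf_f50_cyc_mm": round(mtf.f50, 3),
            "mtf_f10_cyc_mm": round(mtf.f10, 3),
        }
    )

ax_nps.set_xlabel("frequency (cycles/mm)")
ax_nps.set_ylabel("normalized NPS")
ax_nps.legend()
ax_mtf.set_xlabel("frequency (cycles/mm)")
ax_mtf.set_ylabel("MTF")
ax_mtf.legend()
fig.tight_layout()
fig.savefig(OUT / "nps_mtf.png", dpi=120)

table = pd.DataFrame(summary)
table.to_csv(OUT / "summary.csv", index=False)
print(table.to_string(index=False))
print(f"\nFBP noise peaks at mid frequency; IR shifts power toward low "
      f"frequency (the 'plastic' texture). Curves under {OUT}/")
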