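#!/usr/bin/env python
"""Select regularization strengths for both IR methods.

Reproduces the two selection policies on the synthetic system: the adaptive
policy (noise matched to the 7.4 HU target per dose level, so lambda grows
as dose falls) and the fixed policy (weak/medium/strong, with medium chosen
by least-squares MTF matching against the reference-dose FBP).  Writes a
lambda table analogous in structure to the published per-frame-average
table; the absolute values are specific to this synthetic system.
"""

from pathlib import Path

import pandas as pd

from cacstudy import reg_select
from cacstudy.study_runner import StudyConfig, _StudyEngine, select_lambdas

OUT = Path("results/regularization")
OUT.mkdir(parents=True, exist_ok=True)

config = StudyConfig(include_adaptive=True)
engine = _StudyEngine(config, seed=1, verbose=True)

rows = []
for reg in ("TV", "GAMMA"):
    lam_grid, levels, adaptive = select_lambdas(engine, reg)
    rows.append({"method": reg, "level": "weak", "lambda": levels["weak"]})
    rows.append({"method": reg, "level": "medium (MTF-matched)", "lambda": levels["medium"]})
    rows.append({"method": reg, "level": "strong", "lambda": levels["strong"]})
    for frames in (15, 2, 1):
        sino = engine.cardiac_sinos(frames, 700 + frames)[engine.bench_k]
        res = reg_select.adaptive_lambda(
            sino, engine.geom, engine.grid, engine.materials, reg, lam_grid,
            config.target_lnp_noise, engine.noise_roi, n_iterations=config.ir_iterations,
        )
        rows.append(
            {"method": reg, "level": f"adaptive @ {frames} frames", "lambda": res.lam,
             "achieved_noise_hu": round(res.noise_sd[res.lam], 2)}
        )

table = pd.DataFrame(rows)
table.to_csv(OUT / "lambda_table.csv", index=False)
print(table.to_string(index=False))
print(
    f"\nAdaptive lambda rises as frames fall over the reduced-dose levels; the"
    f"\n15-frame adaptive row is degenerate on this system (IR noise sits below"
    f"\nthe 7.4 HU target at every candidate -- see docs/methods.md)."
    f"\nTable under {OUT}/"
)
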