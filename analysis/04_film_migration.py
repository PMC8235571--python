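#!/usr/bin/env python
"""Gravity-driven wall-film migration: baseline vs optimized system.

Runs both delivery systems at a 0.1 mL dose in the vertex-to-floor position
with the full 0.2 s Eulerian wall-film stage, and reports the before/after
regional dose table and the olfactory enhancement factor.
"""

from pathlib import Path

import pandas as pd

from nasospray.config import RunConfig, preset_spray
from nasospray.dosimetry import enhancement_factor
from nasospray.film import SurfaceOperators
from nasospray.geometry import build_idealized_nasal_passage
from nasospray.pipeline import run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

mesh = build_idealized_nasal_passage()
ops = SurfaceOperators(mesh)

rows = []
for name in ("baseline", "optimized"):
    cfg = RunConfig(spray=preset_spray(name), seed=1, n_simulated=10_000)
    r = run_pipeline(cfg, mesh=mesh, ops=ops)
    i, f = r.initial_report.df_pct, r.film_fractions
    fold = enhancement_factor(f["OL"], i["OL"])
    rows.append({"system": name,
                 "OL_initial": round(i["OL"], 2),
                 "OL_film": round(f["OL"], 2),
                 "OL_fold": round(fold, 2),
                 "SM_initial": round(i["SM"], 2),
                 "SM_film": round(f["SM"], 2),
                 "VEST_initial": round(i["VEST"], 2),
                 "VEST_film": round(f["VEST"], 2)})
    print(f"{name}: olfactory {i['OL']:.2f}% -> {f['OL']:.2f}% "
          f"({fold:.1f}-fold), vestibule {i['VEST']:.2f}% -> {f['VEST']:.2f}%")

table = pd.DataFrame(rows)
table.to_csv(OUT / "film_migration.csv", index=False)
print("inverting the head aligns gravity with the olfactory roof: the film"
      " drains out of the anterior nose and multiplies the olfactory dose.")
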