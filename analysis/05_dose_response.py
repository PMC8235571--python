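#!/usr/bin/env python
"""Dose-response of film translocation with the optimized system.

Sweeps the applied dose at fixed seed, tabulates per-region doses before and
after migration, and reports the overflow-onset dose below which the film
stays pinned in its deposition footprint.
"""

from pathlib import Path

from dataclasses import replace

from nasospray.config import RunConfig, preset_spray
from nasospray.dosimetry import dose_response_sweep
from nasospray.film import SurfaceOperators
from nasospray.geometry import build_idealized_nasal_passage
from nasospray.pipeline import run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

mesh = build_idealized_nasal_passage()
ops = SurfaceOperators(mesh)
base = RunConfig(spray=preset_spray("optimized"), seed=1, n_simulated=10_000)


def one(dose):
    cfg = replace(base, spray=replace(base.spray, dose_ml=dose))
    r = run_pipeline(cfg, mesh=mesh, ops=ops)
    return r.initial_report, r.film_fractions


doses = [0.0125, 0.025, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8]
table = dose_response_sweep(doses, one)
table.to_csv(OUT / "dose_response.csv", index=False)

ol = table[(table.region == "OL") & (table.phase == "film")]
print("olfactory film dose vs applied dose:")
for _, row in ol.iterrows():
    print(f"  {row.dose_ml:6.4f} mL -> {row.df_pct:6.2f}% "
          f"({row.volume_m3 * 1e9:8.2f} µL absolute)")
onset = table.attrs["overflow_onset_ml"]
print(f"overflow onset: {onset} mL — below this dose the film self-weight"
      " cannot beat the holding capacity and the olfactory dose stays at its"
      " initial deposition value; above it, migration grows the absolute"
      " olfactory dose monotonically.")
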