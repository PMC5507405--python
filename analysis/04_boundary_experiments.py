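"""Boundary and perturbation scenarios: bead sources, BMP erosion, cut edges.

Reproduces, in silico, the study's perturbation experiments: cell
accumulation around an attractant-loaded bead and its modulation by
widespread sensitization or attractant blockade; erosion of pre-formed
condensates under rising BMP; and the mechanism-separating cut-edge
experiment (reaction-diffusion foci align along an inhibitor-sink edge,
chemotactic aggregates keep their distance from a truncated edge).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dermapattern.chemotaxis import exemplar_params
from dermapattern.fields import Grid2D
from dermapattern.scenarios import (
    bead_scenario,
    edge_contrast,
    edge_experiment,
    erosion_scenario,
    preform_condensates,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
grid = Grid2D(64, 64, 0.5, "no_flux")

# bead point sources under three modifiers (5 seeds each)
p = exemplar_params(chi0=0.6)
rows = []
for modifier in ("none", "global_attractant", "attractant_blocked"):
    for seed in range(5):
        r = bead_scenario(p, grid, source_rate=2.0, modifier=modifier, seed=seed, t_end=40.0)
        rows.append({"modifier": modifier, "seed": seed, "aggregate_area": r.aggregate_area,
                     "annulus_density": r.annulus_density, "depleted": r.depleted})
bead = pd.DataFrame(rows)
bead.to_csv(OUT / "bead_scenarios.csv", index=False)
med = bead.groupby("modifier").aggregate_area.median()
print("bead aggregate area (median of 5 seeds):")
print(f"  sensitized (global attractant) {med['global_attractant']:.1f} > "
      f"control {med['none']:.1f} > attractant blocked {med['attractant_blocked']:.1f}")

# BMP erosion of pre-formed condensates
pf = exemplar_params()
erosion_rows = []
for seed in range(3):
    rho0, _ = preform_condensates(pf, grid, t_end=300.0, seed=seed)
    for level in (0.0, 0.5, 1.0, 2.0, 4.0):
        ts = erosion_scenario(pf, grid, rho0, bmp_level=level, t_end=40.0)
        ts["seed"] = seed
        erosion_rows.append(ts)
erosion = pd.concat(erosion_rows, ignore_index=True)
erosion.to_csv(OUT / "bmp_erosion.csv", index=False)
final = erosion[erosion.time_h == erosion.time_h.max()].groupby("bmp_level").mean_focus_area.median()
print("final mean condensate area vs BMP level (median of 3 seeds):")
for level, area in final.items():
    print(f"  bmp={level:<4} area {area:.1f}")

# cut-edge experiment, 10 seeds per mechanism
res_rd = edge_experiment("rd", seeds=list(range(10)))
res_ch = edge_experiment("chemotaxis", seeds=list(range(10)))
edges = pd.DataFrame([vars(r) for r in res_rd + res_ch])
edges.to_csv(OUT / "edge_experiment.csv", index=False)
summary = edge_contrast(res_rd, res_ch)
print(
    f"cut edge: rd median normalized distance {summary['median_rd']:.2f} "
    f"(foci hug the inhibitor-sink edge) vs chemotaxis "
    f"{summary['median_chemotaxis']:.2f} (aggregates stand off the truncation)"
)
print(f"outputs in {OUT}")
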