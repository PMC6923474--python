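#!/usr/bin/env python
"""Ca2+ dependence of IC50 and the composite IC50(Vm, [Ca2+]) surface.

Two computations:
  1. refit of the published condition-mean IC50s with A*exp(-Ca/b) — the
     desk-scale reproduction (A ~ 91 uM, b ~ 0.63 mM), plus the composed
     surface prefactor IC50(0 mV)*A/IC50(0.25 mM) = 220*91/63 ~ 318 uM;
  2. a surface fit to this package's own simulated per-cell IC50 grid.
Writes results/ca_surface.json and a prediction grid for plotting.
"""

import json
from pathlib import Path

import numpy as np

import nmdarblock as nb
from nmdarblock.calibration import (
    REPORTED_IC50_025CA,
    REPORTED_IC50_0MV,
    REPORTED_IC50_BY_CA,
)
from nmdarblock.dependence_models import (
    composed_prefactor,
    fit_ca_exponential,
    fit_surface,
    surface_grid,
)
from nmdarblock.dose_response import extract_staircase, fit_hill
from nmdarblock.fixtures import default_staircase_levels, jittered_rates
from nmdarblock.protocols import staircase_protocol

SEED, N_CELLS = 1, 2
base = nb.RateSet()

# 1 — published means
ca = np.array(sorted(REPORTED_IC50_BY_CA))
fit = fit_ca_exponential(ca, np.array([REPORTED_IC50_BY_CA[c] for c in ca]))
pref = composed_prefactor(REPORTED_IC50_0MV, fit.amplitude, REPORTED_IC50_025CA)
print(f"published means: A = {fit.amplitude:.1f} uM, b = {fit.b_ca:.2f} mM")
print(f"composed surface prefactor: {pref:.1f} uM")

# 2 — simulated grid
vms_t, cas_t, ics = [], [], []
for vi, vm in enumerate((-100.0, -70.0, -30.0)):
    for ci, ca_mm in enumerate((0.25, 1.0, 4.0)):
        levels = default_staircase_levels(base, vm, ca_mm)
        for c in range(N_CELLS):
            r = jittered_rates(base, np.random.default_rng([SEED, vi, ci, c]))
            tr = nb.simulate_trace(
                r,
                staircase_protocol(levels, ca_out=ca_mm, holding_voltage=vm,
                                   sample_rate=100),
                noise_sd=5.0, seed=100 * vi + 10 * ci + c,
            )
            vms_t.append(vm); cas_t.append(ca_mm)
            ics.append(fit_hill(extract_staircase(tr)).ic50)
sf = fit_surface(np.array(vms_t), np.array(cas_t), np.array(ics))
print(f"simulated grid: prefactor = {sf.prefactor:.1f} uM, a = {sf.a:.4f} /mV, "
      f"b = {sf.b:.2f} mM (implied delta = {sf.delta_implied:.2f})")

Path("results").mkdir(exist_ok=True)
with open("results/ca_surface.json", "w") as fh:
    json.dump(
        {
            "published_refit": {"A_uM": fit.amplitude, "b_mM": fit.b_ca},
            "composed_prefactor_uM": pref,
            "simulated_surface": {"prefactor_uM": sf.prefactor, "a_per_mV": sf.a,
                                  "b_mM": sf.b, "delta_implied": sf.delta_implied},
        },
        fh, indent=1,
    )
surface_grid(sf).to_csv("results/surface_grid.csv", index=False)
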