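#!/usr/bin/env python
"""Trapping-protocol analysis for the three candidate block mechanisms.

Simulates the block/AP5-washout/test-pulse protocol across washout durations
for a partial-trapping blocker (the amitriptyline-like default), a full
trapper (no escape) and a sequential (foot-in-the-door) blocker, then
classifies each from tails and the fast-fraction recovery. Found: the
amitriptyline-like scheme classifies as partial trapping with no tail
current, and the escape rate is recovered from the recovery curve.
"""

import json
from pathlib import Path

import nmdarblock as nb
from nmdarblock.calibration import (
    full_trapping_rates,
    sequential_blocker_rates,
    trapping_rates,
)
from nmdarblock.protocols import trapping_protocol
from nmdarblock.trapping import analyze_trapping

SEED = 1
schemes = {
    "atl_like_partial": trapping_rates(),
    "full_trapping": full_trapping_rates(),
    "sequential": sequential_blocker_rates(),
}

out = {}
for si, (name, rates) in enumerate(schemes.items()):
    by = {
        t: [
            nb.simulate_trace(rates, trapping_protocol(t, atl=1000.0),
                              noise_sd=5.0, seed=SEED + 1000 * si + 10 * int(2 * t) + c)
            for c in range(3)
        ]
        for t in (0.5, 1.0, 2.0, 4.0)
    }
    res = analyze_trapping(by)
    out[name] = {
        "mode": res.mode,
        "escape_rate_per_s": res.escape_rate,
        "true_k_escape": rates.k_escape,
        "tail_fraction": res.tail_fraction,
        "tau_s_anova_p": res.tau_s_anova_p,
        "fraction_by_delay": dict(
            zip(res.per_washout["t_AP5"], res.per_washout["fraction_mean"])
        ),
    }
    print(f"{name}: mode = {res.mode}, escape rate = {res.escape_rate:.3f} /s "
          f"(true {rates.k_escape}), tails in {res.tail_fraction:.0%} of traces, "
          f"tau_s ANOVA p = {res.tau_s_anova_p:.2f}")

Path("results").mkdir(exist_ok=True)
with open("results/trapping.json", "w") as fh:
    json.dump(out, fh, indent=1)
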