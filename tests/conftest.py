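"""Shared simulated fixtures (session-scoped: simulation output is reused)."""

from __future__ import annotations

import numpy as np
import pytest

import nmdarblock as nb
from nmdarblock.calibration import (
    full_trapping_rates,
    sequential_blocker_rates,
    trapping_rates,
    two_state_rates,
)
from nmdarblock.protocols import block_step_protocol, trapping_protocol


@pytest.fixture(scope="session")
def two_state():
    """Strict O⇌OB parameter set (gating and trapping off)."""
    return two_state_rates()


@pytest.fixture(scope="session")
def block_step_trace(two_state):
    """Noiseless 100 µM ATL step/unblock trace at −70 mV (two-state rates)."""
    return nb.simulate_trace(two_state, block_step_protocol(100.0, sample_rate=200))


@pytest.fixture(scope="session")
def trapping_traces():
    """Trapping-protocol traces for the three generating schemes.

    dict: scheme -> {t_AP5: [traces]} with modest fixture noise.
    """
    schemes = {
        "partial_trapping": trapping_rates(),
        "full_trapping": full_trapping_rates(),
        "sequential": sequential_blocker_rates(),
    }
    out = {}
    for si, (name, rates) in enumerate(schemes.items()):
        by_delay = {}
        for t_ap5 in (0.5, 1.0, 2.0, 4.0):
            by_delay[t_ap5] = [
                nb.simulate_trace(
                    rates,
                    trapping_protocol(t_ap5, atl=1000.0),
                    noise_sd=5.0,
                    seed=10000 * si + 10 * int(t_ap5 * 2) + c,
                )
                for c in range(2)
            ]
        out[name] = by_delay
    return out


def relaxation_segment(trace, epoch_index, tau_exchange=0.010):
    """Samples of one epoch, starting after the solution-exchange transient."""
    e = trace.protocol.epochs[epoch_index]
    return trace.segment(e.t_start + 3 * tau_exchange, e.t_end)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
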