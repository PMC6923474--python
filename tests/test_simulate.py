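"""Master-equation simulation: conservation, closed forms, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nmdarblock as nb
from nmdarblock.calibration import two_state_rates
from nmdarblock.model import IDX, RateSet
from nmdarblock.protocols import (
    Protocol,
    SolutionEpoch,
    agonist_pulse_protocol,
    block_step_protocol,
)
from nmdarblock.trace_analysis import fit_monoexp, steady_state_measure


def test_no_agonist_no_current():
    proto = Protocol(
        epochs=(SolutionEpoch(0.0, 5.0, ATL=100.0, Ca_out=1.0),), sample_rate=200
    )
    tr = nb.simulate_trace(RateSet(), proto)
    assert np.allclose(tr.current, 0.0, atol=1e-9)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(
    k_des0=st.floats(0.0, 5.0),
    k_escape=st.floats(0.0, 2.0),
    atl=st.floats(0.0, 500.0),
    alpha=st.floats(0.5, 50.0),
)
def test_occupancies_conserved(k_des0, k_escape, atl, alpha):
    """Occupancies stay in [0,1] and sum to 1 within 1e-9 at every sample."""
    r = RateSet(k_des0=k_des0, k_escape=k_escape, alpha_close=alpha)
    proto = Protocol(
        epochs=(
            SolutionEpoch(0.0, 0.5, Ca_out=1.0),
            SolutionEpoch(0.5, 3.0, NMDA=100.0, Gly=30.0, ATL=atl, Ca_out=1.0),
            SolutionEpoch(3.0, 5.0, Ca_out=1.0),
        ),
        sample_rate=200,
    )
    tr = nb.simulate_trace(r, proto)
    assert np.all(tr.states >= -1e-12)
    assert np.all(tr.states <= 1 + 1e-12)
    assert np.allclose(tr.states.sum(axis=1), 1.0, atol=1e-9)


@pytest.mark.parametrize("atl", [1.0, 10.0, 100.0, 1000.0])
@pytest.mark.parametrize("vm", [-70.0, -40.0])
def test_two_state_closed_forms(two_state, atl, vm):
    """Steady-state block equals B/(B+K_d(Vm)) and 1/τ_on = k_on·B + k_off,
    both within 1% (noiseless)."""
    proto = block_step_protocol(atl, holding_voltage=vm, block_s=40.0, sample_rate=100)
    tr = nb.simulate_trace(two_state, proto)
    kd = two_state.kd(vm)
    i_c = steady_state_measure(tr, 1).mean_pa
    i_b = steady_state_measure(tr, 2).mean_pa
    expected_rate = two_state.k_on(vm) * atl + two_state.k_off0
    if 40.0 * expected_rate > 6.0:  # only assert equilibrium when reached
        assert nb.blocked_fraction(i_c, i_b) == pytest.approx(
            atl / (atl + kd), rel=0.01
        )
    on = tr.protocol.epochs[2]
    fit = fit_monoexp(*tr.segment(on.t_start + 0.05, on.t_end))
    assert 1.0 / fit.tau == pytest.approx(expected_rate, rel=0.01)


def test_unblock_rate_independent_of_concentration(two_state):
    """1/τ_off equals k_off regardless of the prior blocker concentration."""
    rates = []
    for atl in (10.0, 100.0):
        tr = nb.simulate_trace(two_state, block_step_protocol(atl, sample_rate=100))
        off = tr.protocol.epochs[3]
        fit = fit_monoexp(*tr.segment(off.t_start + 0.05, off.t_end))
        rates.append(1.0 / fit.tau)
    assert rates[0] == pytest.approx(two_state.k_off0, rel=0.01)
    assert rates[1] == pytest.approx(rates[0], rel=0.02)


def test_noiseless_simulation_bit_reproducible():
    proto = agonist_pulse_protocol(sample_rate=200)
    a = nb.simulate_trace(RateSet(), proto)
    b = nb.simulate_trace(RateSet(), proto)
    assert np.array_equal(a.current, b.current)


def test_noise_seeding():
    proto = agonist_pulse_protocol(sample_rate=200)
    a = nb.simulate_trace(RateSet(), proto, noise_sd=5.0, seed=7)
    b = nb.simulate_trace(RateSet(), proto, noise_sd=5.0, seed=7)
    c = nb.simulate_trace(RateSet(), proto, noise_sd=5.0, seed=8)
    assert np.array_equal(a.current, b.current)
    assert not np.array_equal(a.current, c.current)


def test_pure_block_gating_still_matches_closed_forms():
    """With fast, strongly open-biased gating the macroscopic relaxation still
    reports the binding step within 1% even though closing is enabled."""
    r = nb.RateSet(k_des0=0.0, k_escape=0.0)
    tr = nb.simulate_trace(r, block_step_protocol(100.0, sample_rate=100))
    on = tr.protocol.epochs[2]
    fit = fit_monoexp(*tr.segment(on.t_start + 0.05, on.t_end))
    assert 1.0 / fit.tau == pytest.approx(r.k_on(-70.0) * 100.0 + r.k_off0, rel=0.01)


def test_current_scale_is_conductance_times_driving_force():
    r = RateSet(k_des0=0.0)
    tr = nb.simulate_trace(r, agonist_pulse_protocol(ca_out=0.25, sample_rate=200))
    i_ss = steady_state_measure(tr, 1).mean_pa
    f_nmda = 100.0 / (100.0 + r.ec50_nmda)
    p_open = (r.beta_open_max * f_nmda) / (r.beta_open_max * f_nmda + r.alpha_close)
    assert i_ss == pytest.approx(r.n_channels_gamma * (-70.0) * p_open, rel=1e-3)
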