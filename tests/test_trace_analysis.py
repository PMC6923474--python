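"""Steady-state measurement, relaxation fits, and tail detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nmdarblock as nb
from nmdarblock.calibration import two_state_rates
from nmdarblock.exceptions import ValidationError
from nmdarblock.protocols import block_step_protocol
from nmdarblock.trace_analysis import (
    blocked_fraction,
    detect_tail_current,
    fit_biexp_rise,
    fit_monoexp,
    steady_state_measure,
)


class TestBlockedFraction:
    def test_half_block(self):
        assert blocked_fraction(-100.0, -50.0) == pytest.approx(0.5)

    def test_no_block_identity(self):
        assert blocked_fraction(-240.0, -240.0) == 0.0

    def test_sign_mismatch_warns(self):
        with pytest.warns(UserWarning):
            blocked_fraction(-100.0, 5.0)

    def test_zero_control_rejected(self):
        with pytest.raises(ValidationError):
            blocked_fraction(0.0, -10.0)

    def test_two_state_fixture_at_kd(self, two_state):
        """Blocker applied at its K_d blocks exactly half the current."""
        kd = two_state.kd(-70.0)
        tr = nb.simulate_trace(
            two_state, block_step_protocol(kd, block_s=60.0, sample_rate=50)
        )
        i_c = steady_state_measure(tr, 1).mean_pa
        i_b = steady_state_measure(tr, 2).mean_pa
        assert blocked_fraction(i_c, i_b) == pytest.approx(0.5, abs=0.01)


class TestMonoexp:
    def test_exact_exponential_recovery(self):
        t = np.linspace(0.0, 20.0, 2000)
        y = (-800.0 - (-200.0)) * np.exp(-t / 2.75) + (-200.0)
        fit = fit_monoexp(t, y)
        assert fit.tau == pytest.approx(2.75, rel=1e-6)
        assert fit.I_max == pytest.approx(-800.0, rel=1e-6)
        assert fit.I_min == pytest.approx(-200.0, rel=1e-6)

    def test_onset_rate_matches_binding_relation(self):
        """1/τ_on = k_on·B + k_off = 0.0016·100 + 0.204 = 0.364 s⁻¹ for a
        voltage-independent two-state blocker."""
        r = two_state_rates(voltage_dependent=False)
        tr = nb.simulate_trace(r, block_step_protocol(100.0, sample_rate=100))
        on = tr.protocol.epochs[2]
        fit = fit_monoexp(*tr.segment(on.t_start + 0.05, on.t_end))
        assert 1.0 / fit.tau == pytest.approx(0.364, rel=0.01)

    def test_offset_rate_is_koff(self, block_step_trace, two_state):
        off = block_step_trace.protocol.epochs[3]
        fit = fit_monoexp(*block_step_trace.segment(off.t_start + 0.05, off.t_end))
        assert 1.0 / fit.tau == pytest.approx(0.204, rel=0.01)


class TestBiexp:
    def test_generative_recovery(self):
        """Amplitudes of a two-component rise recovered within 2%."""
        t = np.arange(0.0, 40.0, 0.01)
        i1, i2, ib = 300.0, 500.0, 40.0
        y = i1 * np.exp(-t / 0.05) + i2 * np.exp(-t / 13.0) - (i1 + i2 + ib)
        fit = fit_biexp_rise(t, y, ib)
        assert fit.I_f == pytest.approx(i1, rel=0.02)
        assert fit.I_s == pytest.approx(i2, rel=0.02)
        assert fit.tau_f == pytest.approx(0.05, rel=0.02)
        assert fit.tau_s == pytest.approx(13.0, rel=0.02)
        assert not fit.degenerate

    def test_close_time_constants_flagged_degenerate(self):
        t = np.arange(0.0, 10.0, 0.01)
        y = 300.0 * np.exp(-t / 1.0) + 300.0 * np.exp(-t / 1.5) - 600.0
        assert fit_biexp_rise(t, y, 0.0).degenerate


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    t0=st.floats(0.0, 5.0),
    dur=st.floats(0.5, 20.0),
    tau_ex=st.floats(0.001, 0.05),
)
def test_steady_window_avoids_epoch_edges(t0, dur, tau_ex):
    """The steady-state window never samples within 3·tau_exchange of an edge."""
    from nmdarblock.protocols import Protocol, SolutionEpoch

    e = SolutionEpoch(t0, t0 + dur, NMDA=100.0, Gly=30.0, Ca_out=1.0)
    proto = Protocol(epochs=(e,), sample_rate=1000.0)
    n = int(proto.total_duration * 1000) + 1
    trace = nb.CurrentTrace(
        time=np.arange(n) / 1000.0, current=np.full(n, -100.0), protocol=proto
    )
    try:
        m = steady_state_measure(trace, e, tau_exchange=tau_ex)
    except nb.exceptions.InsufficientDataError:
        return  # epoch legitimately too short for any window
    assert m.t_start >= e.t_start + 3 * tau_ex - 1e-9
    assert m.t_end <= e.t_end - 3 * tau_ex + 1e-9


class TestTailCurrent:
    def test_trapping_blocker_has_no_tail(self, trapping_traces):
        tr = trapping_traces["partial_trapping"][1.0][0]
        detected, _ = detect_tail_current(tr, 3)
        assert not detected

    def test_sequential_blocker_has_tail(self, trapping_traces):
        tr = trapping_traces["sequential"][1.0][0]
        detected, area = detect_tail_current(tr, 3)
        assert detected
        assert area > 0

    def test_no_blocker_no_tail(self):
        from nmdarblock.protocols import trapping_protocol

        proto = trapping_protocol(1.0, atl=0.0)
        tr = nb.simulate_trace(nb.RateSet(k_des0=0.0), proto)
        detected, _ = detect_tail_current(tr, 3)
        assert not detected
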