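"""Staircase extraction and Hill fitting."""

import numpy as np
import pytest

import nmdarblock as nb
from nmdarblock.calibration import pure_block_rates, two_state_rates
from nmdarblock.dose_response import (
    condition_summary,
    extract_staircase,
    fit_hill,
    fit_hill_per_cell,
    hill,
)
from nmdarblock.exceptions import FitError, InsufficientDataError
from nmdarblock.fixtures import jittered_rates
from nmdarblock.protocols import staircase_protocol


class TestExtractStaircase:
    def test_monotone_amplitudes(self):
        tr = nb.simulate_trace(
            two_state_rates(),
            staircase_protocol([1.0, 3.0, 10.0, 30.0, 100.0], ca_out=0.25,
                               sample_rate=50),
        )
        pts = extract_staircase(tr)
        amps = [p.relative_amplitude for p in pts]
        assert len(pts) == 5
        assert all(a >= b - 1e-6 for a, b in zip(amps, amps[1:]))

    def test_two_state_point_at_kd_is_half(self, two_state):
        kd = two_state.kd(-70.0)
        tr = nb.simulate_trace(
            two_state,
            staircase_protocol([kd], ca_out=0.25, level_s=60.0, sample_rate=50),
        )
        (pt,) = extract_staircase(tr)
        assert pt.relative_amplitude == pytest.approx(0.5, abs=0.01)

    def test_requires_pre_blocker_epoch(self):
        from nmdarblock.protocols import Protocol, SolutionEpoch

        proto = Protocol(
            epochs=(
                SolutionEpoch(0.0, 5.0, NMDA=100.0, Gly=30.0, ATL=10.0, Ca_out=1.0),
            ),
            sample_rate=100,
        )
        tr = nb.simulate_trace(nb.RateSet(), proto)
        with pytest.raises(InsufficientDataError):
            extract_staircase(tr)


class TestFitHill:
    def test_exact_recovery(self):
        b = np.logspace(-1, 2, 12)
        fit = fit_hill((b, hill(b, 4.9, 1.2)))
        assert fit.ic50 == pytest.approx(4.9, rel=1e-6)
        assert fit.h == pytest.approx(1.2, rel=1e-6)

    def test_fit_is_fixed_point_of_generated_data(self):
        b = np.logspace(-1.5, 2.5, 9)
        first = fit_hill((b, hill(b, 12.0, 1.7)))
        second = fit_hill((b, hill(b, first.ic50, first.h)))
        assert second.ic50 == pytest.approx(first.ic50, rel=1e-9)
        assert second.h == pytest.approx(first.h, rel=1e-9)

    def test_too_few_concentrations(self):
        with pytest.raises(InsufficientDataError):
            fit_hill((np.array([1.0, 10.0]), np.array([0.9, 0.4])))

    def test_insufficient_inhibition(self):
        b = np.array([1.0, 3.0, 10.0])
        with pytest.raises(FitError):
            fit_hill((b, np.array([0.99, 0.97, 0.95])))

    def test_pure_block_ic50_equals_kd(self):
        """Fitted IC₅₀ of a pure open-channel blocker is its K_d (127.5 µM at
        −70 mV with the anchored rates)."""
        r = pure_block_rates(voltage_dependent=False)
        levels = [10.0, 30.0, 100.0, 300.0, 1000.0]
        tr = nb.simulate_trace(
            r, staircase_protocol(levels, ca_out=0.25, level_s=40.0, sample_rate=50)
        )
        fit = fit_hill(extract_staircase(tr))
        assert fit.ic50 == pytest.approx(127.5, rel=0.02)
        assert fit.h == pytest.approx(1.0, abs=0.05)


class TestNoisyRecovery:
    def test_ic50_unbiased_across_replicates(self):
        """Across 20 jittered, noisy cells the mean recovered IC₅₀ tracks the
        mean true K_d within 10%, and the SEM shrinks with n."""
        base = pure_block_rates(voltage_dependent=False)
        levels = [10.0, 30.0, 100.0, 300.0, 1000.0]
        fits, truths = [], []
        for c in range(20):
            rng = np.random.default_rng([42, c])
            r = jittered_rates(base, rng)
            tr = nb.simulate_trace(
                r,
                staircase_protocol(levels, ca_out=0.25, level_s=40.0, sample_rate=50),
                noise_sd=5.0,
                seed=c,
            )
            fits.append(fit_hill(extract_staircase(tr, cell_id=f"c{c}")))
            truths.append(r.kd(-70.0))
        est = np.array([f.ic50 for f in fits])
        assert est.mean() == pytest.approx(np.mean(truths), rel=0.10)
        sem_small = condition_summary(fits[:5])["ic50_sem"] * np.sqrt(5)
        sem_large = condition_summary(fits)["ic50_sem"] * np.sqrt(20)
        # per-cell scatter (sd) is stable, so SEM scales ~1/sqrt(n)
        assert condition_summary(fits)["ic50_sem"] < condition_summary(fits[:5])[
            "ic50_sem"
        ]
        assert sem_large == pytest.approx(sem_small, rel=0.8)


def test_per_cell_fits_group_by_cell():
    b = np.logspace(-1, 2, 7)
    pts = []
    for cell, ic50 in (("a", 5.0), ("b", 8.0)):
        for conc, amp in zip(b, hill(b, ic50, 1.3)):
            pts.append(
                nb.dose_response.DoseResponsePoint(
                    ATL=conc, relative_amplitude=min(amp, 1.2), cell_id=cell
                )
            )
    fits = fit_hill_per_cell(pts)
    assert sorted(round(f.ic50, 3) for f in fits) == [5.0, 8.0]
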