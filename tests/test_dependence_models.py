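"""Woodhull voltage dependence, Ca²⁺ exponential, and the composite surface."""

import numpy as np
import pytest

from nmdarblock.calibration import (
    REPORTED_CA_AMPLITUDE,
    REPORTED_CA_EFOLD,
    REPORTED_IC50_BY_CA,
)
from nmdarblock.dependence_models import (
    SurfaceFit,
    composed_prefactor,
    fit_ca_exponential,
    fit_surface,
    fit_woodhull,
    predict_ic50,
)
from nmdarblock.exceptions import InsufficientDataError, ValidationError


class TestWoodhull:
    def test_generative_identity(self):
        vm = np.array([-100.0, -70.0, -30.0])
        fit = fit_woodhull(vm, 220.0 * np.exp(vm * 0.021))
        assert fit.ic50_0mv == pytest.approx(220.0, rel=1e-6)
        assert fit.e_fold_mV == pytest.approx(1.0 / 0.021, rel=1e-6)

    def test_delta_from_50mv_efold(self):
        """An e-fold shift per 50 mV with z=1, RT/F=25.7 mV means δ = 0.51."""
        vm = np.array([-100.0, -70.0, -30.0, 0.0])
        fit = fit_woodhull(vm, 220.0 * np.exp(vm / 50.0))
        assert fit.delta == pytest.approx(25.7 / 50.0, rel=1e-9)
        assert round(fit.delta, 2) == 0.51

    def test_voltage_independent_flagged(self):
        vm = np.array([-100.0, -70.0, -30.0])
        fit = fit_woodhull(vm, np.full(3, 50.0))
        assert fit.flagged_voltage_independent
        assert fit.delta == pytest.approx(0.0, abs=1e-9)

    def test_wrong_sign_rejected(self):
        vm = np.array([-100.0, -70.0, -30.0])
        with pytest.raises(ValidationError):
            fit_woodhull(vm, 220.0 * np.exp(-vm * 0.021))

    def test_needs_three_voltages(self):
        with pytest.raises(InsufficientDataError):
            fit_woodhull(np.array([-70.0, -30.0]), np.array([50.0, 120.0]))


class TestCaExponential:
    def test_generative_identity(self):
        ca = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        fit = fit_ca_exponential(ca, 91.0 * np.exp(-ca / 0.63))
        assert fit.amplitude == pytest.approx(91.0, rel=1e-6)
        assert fit.b_ca == pytest.approx(0.63, rel=1e-6)

    def test_refit_of_reported_condition_means(self):
        """The five reported mean IC₅₀s refit to A ≈ 91 µM, b ≈ 0.63 mM."""
        ca = np.array(sorted(REPORTED_IC50_BY_CA))
        ic50 = np.array([REPORTED_IC50_BY_CA[c] for c in ca])
        fit = fit_ca_exponential(ca, ic50)
        assert fit.amplitude == pytest.approx(REPORTED_CA_AMPLITUDE, rel=0.10)
        assert fit.b_ca == pytest.approx(REPORTED_CA_EFOLD, rel=0.10)

    def test_nonmonotone_warns(self):
        ca = np.array([0.25, 0.5, 1.0, 2.0])
        with pytest.warns(UserWarning):
            fit_ca_exponential(ca, np.array([60.0, 20.0, 40.0, 5.0]))

    def test_flat_data_fit_is_flat(self):
        """Ca-independent IC₅₀s (the BAPTA limit) yield an essentially flat
        exponential: predictions vary < 5% across the Ca range."""
        ca = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        fit = fit_ca_exponential(ca, np.full(5, 105.0))
        preds = fit.predict(ca)
        assert preds.max() / preds.min() < 1.05


class TestSurface:
    def test_composed_prefactor(self):
        """220·91/63 ≈ 317.8 µM, the composite surface amplitude."""
        assert composed_prefactor(220.0, 91.0, 63.0) == pytest.approx(
            317.8, abs=0.1
        )

    def test_generative_identity(self):
        vms = np.repeat([-100.0, -70.0, -30.0, 0.0], 5)
        cas = np.tile([0.25, 0.5, 1.0, 2.0, 4.0], 4)
        ics = 317.0 * np.exp(0.018 * vms - cas / 0.69)
        fit = fit_surface(vms, cas, ics)
        assert fit.prefactor == pytest.approx(317.0, rel=1e-6)
        assert fit.a == pytest.approx(0.018, rel=1e-6)
        assert fit.b == pytest.approx(0.69, rel=1e-6)
        assert fit.delta_implied == pytest.approx(0.018 * 25.7, rel=1e-6)

    def test_separability(self):
        """For any product model the exponents are independent of which
        slices of the other variable are included."""
        def table(vm_set, ca_set):
            vms = np.repeat(vm_set, len(ca_set))
            cas = np.tile(ca_set, len(vm_set))
            return vms, cas, 200.0 * np.exp(0.02 * vms) * np.exp(-cas / 0.8)

        full = fit_surface(*table([-100.0, -70.0, -30.0], [0.25, 1.0, 4.0]))
        sub = fit_surface(*table([-100.0, -30.0], [0.5, 2.0]))
        assert sub.a == pytest.approx(full.a, rel=1e-9)
        assert sub.b == pytest.approx(full.b, rel=1e-9)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValidationError):
            fit_surface(
                np.array([-70.0, -70.0, -70.0]),
                np.array([0.25, 1.0, 4.0]),
                np.array([60.0, 20.0, 1.0]),
            )


class TestPredict:
    def test_reference_condition_evaluation(self):
        """With the reported parameters, (0 mV, 0.25 mM) predicts ≈ 220.6 µM —
        consistent with the measured IC₅₀(0 mV)."""
        sf = SurfaceFit(prefactor=317.0, a=0.018, b=0.69)
        assert predict_ic50(sf, 0.0, 0.25) == pytest.approx(220.6, abs=0.5)

    def test_zero_ca_zero_vm_is_prefactor(self):
        sf = SurfaceFit(prefactor=317.0, a=0.018, b=0.69)
        assert predict_ic50(sf, 0.0, 0.0) == pytest.approx(317.0)

    def test_monotone_decreasing_in_ca(self):
        sf = SurfaceFit(prefactor=317.0, a=0.018, b=0.69)
        cas = np.linspace(0.0, 4.0, 9)
        preds = predict_ic50(sf, np.full_like(cas, -70.0), cas)
        assert np.all(np.diff(preds) < 0)
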