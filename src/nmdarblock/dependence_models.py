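"""Voltage, Ca²⁺ and composite dependence of the blocker IC₅₀.

Three related fits:

* Woodhull voltage dependence, IC₅₀(Vm) = IC₅₀(0 mV)·exp(Vm·zδF/RT), fit as a
  straight line in log(IC₅₀) — the model is exactly linear there and
  multiplicative errors become homoscedastic.
* Ca²⁺ dependence, IC₅₀([Ca²⁺]) = A·exp(−[Ca²⁺]/b), fit by unweighted
  nonlinear least squares on the linear IC₅₀ scale (the convention that
  reproduces the published amplitude/e-fold values from the condition means).
* The separable composite surface IC₅₀(Vm, [Ca²⁺]) = pref·exp(a·Vm − Ca/b),
  fit in log space; its prefactor can also be composed from the two component
  fits as IC₅₀(0 mV)·A / IC₅₀(reference Ca).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import FitError, InsufficientDataError, ValidationError

RT_OVER_F_DEFAULT = 25.7  # mV at room temperature


@dataclass(frozen=True)
class WoodhullFit:
    """Voltage dependence of IC₅₀ for a charged open-channel blocker.

    ``delta`` is the fraction of the membrane electric field at the blocking
    site; ``e_fold_mV`` the voltage shift producing an e-fold IC₅₀ change.
    """

    ic50_0mv: float
    delta: float
    z: float = 1.0
    rt_over_f: float = RT_OVER_F_DEFAULT
    ic50_0mv_se: float = float("nan")
    delta_se: float = float("nan")
    flagged_voltage_independent: bool = False

    @property
    def e_fold_mV(self) -> float:
        return self.rt_over_f / (self.z * self.delta)

    @property
    def slope(self) -> float:
        """d log(IC₅₀)/dVm in 1/mV."""
        return self.z * self.delta / self.rt_over_f

    def predict(self, Vm: np.ndarray) -> np.ndarray:
        return self.ic50_0mv * np.exp(np.asarray(Vm) * self.slope)


@dataclass(frozen=True)
class CaExpFit:
    """Single-exponential Ca²⁺ dependence IC₅₀ = A·exp(−[Ca²⁺]/b)."""

    amplitude: float   # µM, extrapolated IC50 at [Ca2+] = 0
    b_ca: float        # mM, e-fold constant
    amplitude_se: float = float("nan")
    b_ca_se: float = float("nan")

    def predict(self, ca: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-np.asarray(ca) / self.b_ca)


@dataclass(frozen=True)
class SurfaceFit:
    """Composite IC₅₀(Vm, [Ca²⁺]) = prefactor·exp(a·Vm − [Ca²⁺]/b)."""

    prefactor: float   # µM
    a: float           # 1/mV
    b: float           # mM
    rt_over_f: float = RT_OVER_F_DEFAULT
    reference_ic50: float | None = None  # IC50 at the reference Ca condition

    def __post_init__(self):
        if self.prefactor <= 0 or self.b <= 0:
            raise ValidationError("surface prefactor and b must be positive")

    @property
    def delta_implied(self) -> float:
        """δ implied by the surface's voltage exponent (z = 1)."""
        return self.a * self.rt_over_f


def fit_woodhull(
    vm: np.ndarray,
    ic50: np.ndarray,
    z: float = 1.0,
    rt_over_f: float = RT_OVER_F_DEFAULT,
    flat_delta: float = 0.05,
) -> WoodhullFit:
    """Least-squares line through log(IC₅₀) versus Vm.

    For a cationic blocker the IC₅₀ must grow with depolarization
    (positive log-slope); a clearly negative slope raises a sign-convention
    error, while |δ| below ``flat_delta`` only flags the fit as
    voltage-independent.
    """
    vm = np.asarray(vm, dtype=float)
    ic50 = np.asarray(ic50, dtype=float)
    if np.unique(vm).size < 3:
        raise InsufficientDataError("need >= 3 distinct voltages")
    if np.any(ic50 <= 0):
        raise ValidationError("IC50 values must be positive")
    (slope, intercept), cov = np.polyfit(vm, np.log(ic50), 1, cov=True)
    delta = slope * rt_over_f / z
    delta_se = float(np.sqrt(cov[0, 0]) * rt_over_f / z)
    if delta < -flat_delta:
        raise ValidationError(
            f"log(IC50) falls with depolarization (delta = {delta:.3f}); "
            "sign convention violated for a cationic blocker"
        )
    ic50_0 = float(np.exp(intercept))
    return WoodhullFit(
        ic50_0mv=ic50_0,
        delta=float(delta),
        z=z,
        rt_over_f=rt_over_f,
        ic50_0mv_se=float(ic50_0 * np.sqrt(cov[1, 1])),
        delta_se=delta_se,
        flagged_voltage_independent=bool(abs(delta) < flat_delta),
    )


def fit_ca_exponential(
    ca: np.ndarray,
    ic50: np.ndarray,
    reversal_tol: float = 0.2,
) -> CaExpFit:
    """Unweighted nonlinear fit of A·exp(−Ca/b) on the linear IC₅₀ scale.

    Warns if the IC₅₀s are non-monotone in Ca beyond ``reversal_tol``
    (fractional reversal) — the model presumes monotone suppression.
    """
    ca = np.asarray(ca, dtype=float)
    ic50 = np.asarray(ic50, dtype=float)
    if np.unique(ca).size < 3:
        raise InsufficientDataError("need >= 3 distinct Ca2+ concentrations")
    levels = np.unique(ca)
    level_means = np.array([ic50[ca == c].mean() for c in levels])
    rises = np.diff(level_means) / np.maximum(level_means[:-1], 1e-12)
    if np.any(rises > reversal_tol):
        warnings.warn(
            "IC50 versus Ca2+ reverses by more than 20%; exponential model "
            "may be inappropriate",
            stacklevel=2,
        )
    # log-linear regression for starting values
    slope, intercept = np.polyfit(ca, np.log(np.maximum(ic50, 1e-12)), 1)
    p0 = (float(np.exp(intercept)), float(-1.0 / min(slope, -1e-6)))

    def model(x, amp, b):
        return amp * np.exp(-x / b)

    try:
        popt, pcov = curve_fit(model, ca, ic50, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Ca-exponential fit did not converge: {exc}", p0) from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return CaExpFit(float(popt[0]), float(popt[1]), float(perr[0]), float(perr[1]))


def composed_prefactor(
    ic50_0mv: float, ca_amplitude: float, reference_ic50: float
) -> float:
    """Surface prefactor composed from component fits:
    IC₅₀(0 mV)·A / IC₅₀(reference [Ca²⁺])."""
    if reference_ic50 <= 0:
        raise ValidationError("reference IC50 must be positive")
    return ic50_0mv * ca_amplitude / reference_ic50


def fit_surface(
    vm: np.ndarray,
    ca: np.ndarray,
    ic50: np.ndarray,
    rt_over_f: float = RT_OVER_F_DEFAULT,
) -> SurfaceFit:
    """Least squares on log(IC₅₀) for the separable exponential surface.

    The design must span at least two voltages and two Ca²⁺ levels;
    otherwise the exponents are not identifiable.
    """
    vm = np.asarray(vm, dtype=float)
    ca = np.asarray(ca, dtype=float)
    ic50 = np.asarray(ic50, dtype=float)
    if np.unique(vm).size < 2 or np.unique(ca).size < 2:
        raise ValidationError(
            "surface fit needs >= 2 distinct voltages and >= 2 Ca2+ levels"
        )
    if np.any(ic50 <= 0):
        raise ValidationError("IC50 values must be positive")
    X = np.column_stack([np.ones_like(vm), vm, -ca])
    coef, *_ = np.linalg.lstsq(X, np.log(ic50), rcond=None)
    log_pref, a, inv_b = coef
    if inv_b <= 0:
        raise FitError("fitted Ca exponent is non-suppressive (b <= 0)", None)
    return SurfaceFit(
        prefactor=float(np.exp(log_pref)),
        a=float(a),
        b=float(1.0 / inv_b),
        rt_over_f=rt_over_f,
    )


def predict_ic50(surface: SurfaceFit, vm, ca) -> np.ndarray | float:
    """Evaluate the composite surface at (Vm, [Ca²⁺])."""
    vm = np.asarray(vm, dtype=float)
    ca = np.asarray(ca, dtype=float)
    out = surface.prefactor * np.exp(surface.a * vm - ca / surface.b)
    return float(out) if out.ndim == 0 else out


def surface_grid(
    surface: SurfaceFit,
    vm_range: tuple[float, float] = (-100.0, 40.0),
    ca_range: tuple[float, float] = (0.25, 4.0),
    n_vm: int = 29,
    n_ca: int = 16,
):
    """A (Vm, Ca, IC₅₀) grid for plotting the predicted surface."""
    import pandas as pd

    vms = np.linspace(*vm_range, n_vm)
    cas = np.linspace(*ca_range, n_ca)
    vg, cg = np.meshgrid(vms, cas, indexing="ij")
    return pd.DataFrame(
        {
            "Vm_mV": vg.ravel(),
            "Ca_mM": cg.ravel(),
            "ic50_uM": predict_ic50(surface, vg.ravel(), cg.ravel()),
        }
    )
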