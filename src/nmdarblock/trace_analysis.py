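"""Per-trace measurements: steady-state amplitudes, blocked fraction, and
mono-/bi-exponential relaxation fits.

Sign convention: NMDAR currents at negative holding voltages are inward
(negative pA).  Fits operate on the raw signed current; derived amplitudes
(I_f, I_s, blocked fraction) are reported as magnitudes or dimensionless
ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import FitError, InsufficientDataError, ValidationError
from .protocols import SolutionEpoch
from .simulate import CurrentTrace


@dataclass(frozen=True)
class SteadyStateMeasure:
    """Mean current over a late-epoch window plus a steadiness diagnostic."""

    mean_pa: float
    t_start: float
    t_end: float
    slope_pa_per_s: float
    steady: bool

    @property
    def window(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class RelaxationFit:
    """Single-exponential relaxation I(t) = (I_max − I_min)·exp(−t/τ) + I_min."""

    I_max: float
    I_min: float
    tau: float
    rms: float
    flagged: bool = False

    @property
    def rate(self) -> float:
        return 1.0 / self.tau


@dataclass(frozen=True)
class BiexpFit:
    """Double-exponential test-pulse rise with amplitude constraint
    C = I₁ + I₂ + I_b (I_b the residual non-blocked amplitude)."""

    I_1: float
    I_2: float
    tau_1: float
    tau_2: float
    C: float
    rms: float
    degenerate: bool = False

    # fast/slow assignment by time-constant ordering, not fit order
    @property
    def tau_f(self) -> float:
        return min(self.tau_1, self.tau_2)

    @property
    def tau_s(self) -> float:
        return max(self.tau_1, self.tau_2)

    @property
    def I_f(self) -> float:
        return self.I_1 if self.tau_1 <= self.tau_2 else self.I_2

    @property
    def I_s(self) -> float:
        return self.I_2 if self.tau_1 <= self.tau_2 else self.I_1

    @property
    def fast_fraction(self) -> float:
        return self.I_f / (self.I_f + self.I_s)


def steady_state_measure(
    trace: CurrentTrace,
    epoch: SolutionEpoch | int,
    frac: float = 0.2,
    tau_exchange: float = 0.010,
    steadiness_tol: float = 0.05,
) -> SteadyStateMeasure:
    """Mean current over the final ``frac`` of an epoch.

    The window excludes samples within 3·tau_exchange of either epoch edge
    and is judged steady when |slope|·window < tol·|mean|.
    """
    if isinstance(epoch, int):
        epoch = trace.protocol.epochs[epoch]
    guard = 3.0 * tau_exchange
    t0 = max(epoch.t_end - frac * epoch.duration, epoch.t_start + guard)
    t1 = epoch.t_end - guard
    if t1 <= t0:
        raise InsufficientDataError(
            f"epoch [{epoch.t_start}, {epoch.t_end}] too short for a steady window"
        )
    t, i = trace.segment(t0, t1)
    if t.size < 3:
        raise InsufficientDataError("fewer than 3 samples in the steady window")
    slope, intercept = np.polyfit(t, i, 1)
    mean = float(i.mean())
    steady = abs(slope) * (t1 - t0) < steadiness_tol * max(abs(mean), 1e-12)
    return SteadyStateMeasure(mean, float(t[0]), float(t[-1]), float(slope), steady)


def blocked_fraction(I_c: float, I_b: float) -> float:
    """Fraction of current blocked, 1 − I_b/I_c (steady-state amplitudes)."""
    if I_c == 0:
        raise ValidationError("control current I_c must be nonzero")
    if I_b * I_c < 0:
        warnings.warn(
            "I_b and I_c have opposite signs; check baseline subtraction",
            stacklevel=2,
        )
    return 1.0 - I_b / I_c


def _monoexp(t, i_max, i_min, tau):
    return (i_max - i_min) * np.exp(-t / tau) + i_min


def fit_monoexp(
    time: np.ndarray,
    current: np.ndarray,
    tau_bounds: tuple[float, float] | None = None,
) -> RelaxationFit:
    """Least-squares single-exponential fit of a relaxation segment.

    ``time`` is shifted to start at 0.  Initial guesses: endpoints for
    I_max/I_min, the 1/e crossing for τ.  Non-convergence raises
    :class:`FitError` carrying the guesses; τ landing on a bound flags the
    fit rather than failing.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(current, dtype=float)
    if t.size < 4:
        raise InsufficientDataError("need at least 4 samples for a relaxation fit")
    t = t - t[0]
    i_max0, i_min0 = float(y[0]), float(y[-1])
    span = float(t[-1])
    # 1/e crossing of the normalized relaxation
    denom = i_max0 - i_min0
    tau0 = span / 3.0
    if denom != 0:
        z = (y - i_min0) / denom
        below = np.nonzero(z < np.exp(-1.0))[0]
        if below.size and t[below[0]] > 0:
            tau0 = float(t[below[0]])
    if tau_bounds is None:
        dt = span / (t.size - 1)
        tau_bounds = (dt / 10.0, 50.0 * span)
    p0 = (i_max0, i_min0, np.clip(tau0, *tau_bounds))
    try:
        popt, _ = curve_fit(
            _monoexp, t, y, p0=p0,
            bounds=([-np.inf, -np.inf, tau_bounds[0]], [np.inf, np.inf, tau_bounds[1]]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"mono-exponential fit did not converge: {exc}", p0) from exc
    i_max, i_min, tau = popt
    rms = float(np.sqrt(np.mean((_monoexp(t, *popt) - y) ** 2)))
    at_bound = tau <= tau_bounds[0] * 1.01 or tau >= tau_bounds[1] * 0.99
    return RelaxationFit(float(i_max), float(i_min), float(tau), rms, flagged=at_bound)


def fit_biexp_rise(
    time: np.ndarray,
    current: np.ndarray,
    I_b: float,
    degenerate_ratio: float = 3.0,
) -> BiexpFit:
    """Constrained double-exponential fit of a test-pulse current rise.

    Model: I(t) = I₁·exp(−t/τ₁) + I₂·exp(−t/τ₂) − C with C = I₁ + I₂ + I_b,
    so I(0) = −I_b and I(∞) = −C.  ``I_b`` is the magnitude of the residual
    non-blocked current.  Components closer than ``degenerate_ratio`` in τ
    are flagged degenerate (a single exponential describes the rise).
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(current, dtype=float)
    if t.size < 6:
        raise InsufficientDataError("need at least 6 samples for a bi-exponential fit")
    t = t - t[0]
    ib = abs(float(I_b))
    c_inf = abs(float(y[-1]))
    amp = max(c_inf - ib, 1e-9)
    span = float(t[-1])

    def model(tt, i1, i2, tau1, tau2):
        return i1 * np.exp(-tt / tau1) + i2 * np.exp(-tt / tau2) - (i1 + i2 + ib)

    p0 = (0.5 * amp, 0.5 * amp, span / 100.0, span / 3.0)
    lo = [0.0, 0.0, 1e-5, 1e-5]
    hi = [5.0 * amp + 1e-9, 5.0 * amp + 1e-9, 10.0 * span, 100.0 * span]
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=(lo, hi), maxfev=40000)
    except RuntimeError as exc:
        raise FitError(f"bi-exponential fit did not converge: {exc}", p0) from exc
    i1, i2, tau1, tau2 = (float(v) for v in popt)
    rms = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    ratio = max(tau1, tau2) / max(min(tau1, tau2), 1e-12)
    return BiexpFit(i1, i2, tau1, tau2, i1 + i2 + ib, rms,
                    degenerate=ratio < degenerate_ratio)


def detect_tail_current(
    trace: CurrentTrace,
    washout_epoch: SolutionEpoch | int,
    threshold: float = 0.05,
    min_duration: float = 0.050,
    pre_window: float = 1.0,
) -> tuple[bool, float]:
    """Detect a 'tail' after simultaneous agonist + blocker removal.

    Returns (detected, area in pA·s).  A tail is a post-removal current whose
    magnitude exceeds the pre-removal steady state by ``threshold`` for at
    least ``min_duration`` — the macroscopic signature of sequential
    (foot-in-the-door) block.  The washout epoch must be drug- and
    agonist-free.
    """
    if isinstance(washout_epoch, int):
        washout_epoch = trace.protocol.epochs[washout_epoch]
    if washout_epoch.NMDA > 0 or washout_epoch.ATL > 0:
        raise ValidationError("washout epoch must contain neither agonist nor blocker")
    t_pre, i_pre = trace.segment(
        washout_epoch.t_start - pre_window, washout_epoch.t_start
    )
    if i_pre.size < 3:
        raise InsufficientDataError("no pre-removal samples for tail detection")
    pre = float(np.abs(i_pre).mean())
    t, i = trace.segment(washout_epoch.t_start, washout_epoch.t_end)
    if t.size < 2:
        return False, 0.0
    exceed = np.abs(i) > pre * (1.0 + threshold)
    dt = trace.dt
    # longest contiguous run of exceeding samples
    run = best = 0
    for flag in exceed:
        run = run + 1 if flag else 0
        best = max(best, run)
    detected = best * dt >= min_duration
    area = float(np.sum((np.abs(i) - pre)[exceed]) * dt)
    return detected, area
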