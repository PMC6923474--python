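"""Concentration–inhibition curves and Hill fits.

Staircase protocols apply rising blocker concentrations within one sustained
agonist application; each level's steady-state amplitude is normalized to the
pre-blocker steady state of the same application (I_b/I_c), and the resulting
points are fit with the Hill equation

    I_b/I_c = 1 / (1 + [B]^h / IC50^h).

Condition-level IC₅₀ is the mean of per-cell fits (not a pooled fit), with
SEM over cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import FitError, InsufficientDataError, ValidationError
from .simulate import CurrentTrace
from .trace_analysis import steady_state_measure


@dataclass(frozen=True)
class DoseResponsePoint:
    """One normalized steady-state amplitude at one blocker concentration."""

    ATL: float
    relative_amplitude: float
    cell_id: str | None = None
    Vm: float = -70.0
    Ca_out: float = 1.0
    bapta: bool = False

    def __post_init__(self):
        if not 0.0 <= self.relative_amplitude <= 1.2:
            raise ValidationError(
                f"relative amplitude {self.relative_amplitude:.3f} outside [0, 1.2]"
            )


@dataclass(frozen=True)
class HillFit:
    """IC₅₀ (µM) and Hill coefficient for one concentration–inhibition curve."""

    ic50: float
    h: float
    ic50_se: float
    h_se: float
    n: int
    Vm: float = -70.0
    Ca_out: float = 1.0
    bapta: bool = False


def hill(b: np.ndarray, ic50: float, h: float) -> np.ndarray:
    """Relative amplitude I_b/I_c at blocker concentration(s) ``b``."""
    b = np.asarray(b, dtype=float)
    return 1.0 / (1.0 + (b / ic50) ** h)


def extract_staircase(
    trace: CurrentTrace,
    tau_exchange: float = 0.010,
    cell_id: str | None = None,
) -> list[DoseResponsePoint]:
    """Per-level normalized amplitudes from a rising-ATL staircase trace.

    Requires an agonist-only epoch immediately before ≥3 ATL levels within
    the same application; amplitudes are baseline-subtracted using the
    pre-agonist epoch mean.
    """
    epochs = trace.protocol.epochs
    pre_idx = None
    atl_idx: list[int] = []
    for k, e in enumerate(epochs):
        if e.NMDA > 0 and e.ATL == 0:
            pre_idx = k
            atl_idx = []
        elif e.NMDA > 0 and e.ATL > 0 and pre_idx is not None:
            atl_idx.append(k)
    if pre_idx is None:
        raise InsufficientDataError("staircase trace lacks a pre-ATL agonist epoch")
    if len(atl_idx) < 1:
        raise InsufficientDataError("staircase trace has no ATL levels")

    baseline_epochs = [e for e in epochs[:pre_idx] if e.NMDA == 0 and e.ATL == 0]
    baseline = 0.0
    if baseline_epochs:
        baseline = steady_state_measure(
            trace, baseline_epochs[-1], tau_exchange=tau_exchange
        ).mean_pa
    i_c = (
        steady_state_measure(trace, epochs[pre_idx], tau_exchange=tau_exchange).mean_pa
        - baseline
    )
    proto = trace.protocol
    points = []
    for k in atl_idx:
        i_b = (
            steady_state_measure(trace, epochs[k], tau_exchange=tau_exchange).mean_pa
            - baseline
        )
        rel = float(np.clip(i_b / i_c, 0.0, 1.2))
        points.append(
            DoseResponsePoint(
                ATL=epochs[k].ATL,
                relative_amplitude=rel,
                cell_id=cell_id,
                Vm=proto.holding_voltage,
                Ca_out=epochs[k].Ca_out,
                bapta=proto.bapta_loaded,
            )
        )
    return points


def fit_hill(
    points: list[DoseResponsePoint] | tuple[np.ndarray, np.ndarray],
    h_bounds: tuple[float, float] = (0.3, 4.0),
) -> HillFit:
    """Nonlinear least-squares Hill fit, parameterized in log10(IC₅₀).

    Accepts DoseResponsePoints or a raw (concentration, relative amplitude)
    pair.  Raises if fewer than 3 distinct concentrations, or if every
    amplitude exceeds 0.9 (IC₅₀ unidentifiable).
    """
    if isinstance(points, tuple):
        conc = np.asarray(points[0], dtype=float)
        amp = np.asarray(points[1], dtype=float)
        vm, ca, bapta = -70.0, 1.0, False
    else:
        conc = np.array([p.ATL for p in points], dtype=float)
        amp = np.array([p.relative_amplitude for p in points], dtype=float)
        vm = points[0].Vm if points else -70.0
        ca = points[0].Ca_out if points else 1.0
        bapta = points[0].bapta if points else False
    if np.unique(conc[conc > 0]).size < 3:
        raise InsufficientDataError("need >= 3 distinct blocker concentrations")
    if np.all(amp > 0.9):
        raise FitError("insufficient inhibition: all amplitudes > 0.9", None)
    mask = conc > 0
    conc, amp = conc[mask], amp[mask]

    def model(b, log_ic50, h):
        return hill(b, 10.0 ** log_ic50, h)

    # initial IC50 guess: concentration bracketing 50% inhibition
    below = amp < 0.5
    guess = conc[below][0] if below.any() else conc[-1]
    p0 = (np.log10(guess), 1.0)
    try:
        popt, pcov = curve_fit(
            model, conc, amp, p0=p0,
            bounds=([np.log10(conc.min()) - 3, h_bounds[0]],
                    [np.log10(conc.max()) + 3, h_bounds[1]]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"Hill fit did not converge: {exc}", p0) from exc
    log_ic50, h = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    ic50 = 10.0 ** log_ic50
    ic50_se = ic50 * np.log(10.0) * perr[0]  # delta method on log10 scale
    return HillFit(
        float(ic50), float(h), float(ic50_se), float(perr[1]),
        n=conc.size, Vm=vm, Ca_out=ca, bapta=bapta,
    )


def fit_hill_per_cell(points: list[DoseResponsePoint]) -> list[HillFit]:
    """One Hill fit per cell id, mirroring per-cell analysis of staircases."""
    by_cell: dict[str | None, list[DoseResponsePoint]] = {}
    for p in points:
        by_cell.setdefault(p.cell_id, []).append(p)
    return [fit_hill(cell_points) for cell_points in by_cell.values()]


def condition_summary(fits: list[HillFit]) -> pd.Series:
    """Condition mean ± SEM of per-cell IC₅₀ and Hill coefficient."""
    if len(fits) < 2:
        raise InsufficientDataError("need >= 2 cells for a condition summary")
    ic50s = np.array([f.ic50 for f in fits])
    hs = np.array([f.h for f in fits])
    n = len(fits)
    return pd.Series(
        {
            "ic50_mean": ic50s.mean(),
            "ic50_sem": ic50s.std(ddof=1) / np.sqrt(n),
            "h_mean": hs.mean(),
            "h_sem": hs.std(ddof=1) / np.sqrt(n),
            "n_cells": n,
            "Vm": fits[0].Vm,
            "Ca_out": fits[0].Ca_out,
            "bapta": fits[0].bapta,
        }
    )
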