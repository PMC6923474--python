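"""Trapping-protocol analysis and block-mode classification.

After steady-state block, agonist and blocker are removed together into an
AP5-containing wash of duration t_AP5, then a test agonist pulse is applied.
Channels that trapped the blocker by closing reopen slowly (unblock-limited,
τ_s), untouched channels reopen fast (τ_f); the fast-amplitude fraction
I_f/(I_f+I_s) versus t_AP5 reports whether — and how fast — the blocker
escapes closed channels.  A 'tail current' upon removal instead indicates a
sequential (foot-in-the-door) blocker that prevents closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy import stats as sps

from .exceptions import FitError, InsufficientDataError
from .simulate import CurrentTrace
from .trace_analysis import (
    BiexpFit,
    detect_tail_current,
    fit_biexp_rise,
    steady_state_measure,
)

MODES = ("sequential", "full_trapping", "partial_trapping", "indeterminate")


@dataclass
class TrappingResult:
    """Aggregated trapping-protocol outcome across washout durations."""

    per_washout: pd.DataFrame
    escape_rate: float
    escape_rate_se: float
    f0: float
    f_inf: float
    recovery_slope: float
    recovery_slope_ci: tuple[float, float]
    tau_s_anova_p: float
    tail_fraction: float
    mode: str
    diagnostics: dict = field(default_factory=dict)


def _find_epochs(trace: CurrentTrace):
    """Locate block, washout and test epochs of one trapping trace."""
    epochs = trace.protocol.epochs
    block = wash = test = None
    for k, e in enumerate(epochs):
        if e.NMDA > 0 and e.ATL > 0:
            block = k
        elif block is not None and e.AP5 > 0 and e.NMDA == 0 and wash is None:
            wash = k
        elif wash is not None and e.NMDA > 0 and e.ATL == 0:
            test = k
            break
    if block is None or wash is None or test is None:
        raise InsufficientDataError(
            "trapping trace must contain block, AP5 washout and test epochs"
        )
    return block, wash, test


def measure_test_pulse(
    trace: CurrentTrace, tau_exchange: float = 0.010
) -> tuple[BiexpFit, float, bool]:
    """Bi-exponential fit of the test-pulse rise of one trapping trace.

    Returns (fit, I_b magnitude, tail detected).  The fit window starts where
    the rising current magnitude first exceeds the residual blocked level
    I_b, making the amplitude constraint C = I₁ + I₂ + I_b consistent with
    the first fitted sample.
    """
    block_k, wash_k, test_k = _find_epochs(trace)
    epochs = trace.protocol.epochs
    baseline = steady_state_measure(trace, 0, tau_exchange=tau_exchange).mean_pa
    i_b = abs(
        steady_state_measure(trace, block_k, tau_exchange=tau_exchange).mean_pa
        - baseline
    )
    tail, _ = detect_tail_current(trace, wash_k)

    test = epochs[test_k]
    t, i = trace.segment(test.t_start, test.t_end - 3 * tau_exchange)
    mag = np.abs(i - baseline)
    above = np.nonzero(mag >= i_b)[0]
    start = above[0] if above.size else 0
    fit = fit_biexp_rise(t[start:], i[start:] - baseline, i_b)
    return fit, i_b, tail


def _recovery(t, f0, f_inf, k):
    return f_inf - (f_inf - f0) * np.exp(-k * t)


def analyze_trapping(
    traces_by_delay: dict[float, list[CurrentTrace]],
    tau_exchange: float = 0.010,
    alpha: float = 0.05,
) -> TrappingResult:
    """Aggregate test-pulse fits across washout durations and classify.

    Fits f(t_AP5) = f∞ − (f∞ − f₀)·exp(−k·t_AP5) to the per-trace fast
    fractions to estimate the escape rate, runs a one-way ANOVA on τ_s
    across washout groups, and classifies the block mode (see
    :func:`classify_block_mode`).
    """
    rows = []
    for t_ap5, traces in sorted(traces_by_delay.items()):
        for trace in traces:
            fit, i_b, tail = measure_test_pulse(trace, tau_exchange)
            rows.append(
                {
                    "t_AP5": t_ap5,
                    "I_f": fit.I_f,
                    "I_s": fit.I_s,
                    "fraction_fast": fit.fast_fraction,
                    "tau_f": fit.tau_f,
                    "tau_s": fit.tau_s,
                    "I_b": i_b,
                    "tail": tail,
                    "degenerate": fit.degenerate,
                }
            )
    table = pd.DataFrame(rows)
    per_washout = (
        table.groupby("t_AP5")
        .agg(
            fraction_mean=("fraction_fast", "mean"),
            fraction_sem=("fraction_fast", "sem"),
            tau_f_mean=("tau_f", "mean"),
            tau_s_mean=("tau_s", "mean"),
            tau_s_sem=("tau_s", "sem"),
            n=("fraction_fast", "size"),
        )
        .reset_index()
    )
    n_delays = per_washout.shape[0]
    tail_fraction = float(table["tail"].mean())

    diagnostics: dict = {"n_traces": len(table)}
    if n_delays < 2:
        return TrappingResult(
            per_washout=per_washout,
            escape_rate=float("nan"), escape_rate_se=float("nan"),
            f0=float("nan"), f_inf=float("nan"),
            recovery_slope=float("nan"), recovery_slope_ci=(np.nan, np.nan),
            tau_s_anova_p=float("nan"),
            tail_fraction=tail_fraction,
            mode="unclassified",
            diagnostics={**diagnostics, "reason": "fewer than 2 washout durations"},
        )

    t = table["t_AP5"].to_numpy(float)
    f = table["fraction_fast"].to_numpy(float)
    # saturating-recovery fit for the escape rate (f_inf bounded at 1)
    p0 = (max(min(f.min(), 1.0), 0.0), min(f.max(), 1.0), 1.0 / t.max())
    try:
        popt, pcov = curve_fit(
            _recovery, t, f, p0=p0,
            bounds=([0.0, 0.0, 0.0], [1.0, 1.0, np.inf]), maxfev=20000,
        )
        f0, f_inf, k = (float(v) for v in popt)
        k_se = float(np.sqrt(max(pcov[2, 2], 0.0)))
    except RuntimeError as exc:
        raise FitError(f"recovery fit did not converge: {exc}", p0) from exc

    # linear trend of fraction vs delay, with 95% CI on the slope
    lin = sps.linregress(t, f)
    df = len(t) - 2
    tcrit = sps.t.ppf(1 - alpha / 2, df) if df > 0 else np.inf
    ci = (lin.slope - tcrit * lin.stderr, lin.slope + tcrit * lin.stderr)

    groups = [g["tau_s"].to_numpy(float) for _, g in table.groupby("t_AP5")]
    if all(len(g) >= 2 for g in groups) and len(groups) >= 2:
        anova_p = float(sps.f_oneway(*groups).pvalue)
    else:
        anova_p = float("nan")

    # a degenerate (single-exponential) rise has no resolved slow component,
    # so its fast fraction carries no trapping information
    first = table[table["t_AP5"] == per_washout["t_AP5"].iloc[0]]
    informative = first[~first["degenerate"]]
    short_frac = (
        float(informative["fraction_fast"].mean()) if len(informative) else 1.0
    )
    mode = classify_block_mode(
        tail_detected=tail_fraction > 0.5,
        slope_ci=ci,
        short_delay_fraction=short_frac,
    )
    return TrappingResult(
        per_washout=per_washout,
        escape_rate=k, escape_rate_se=k_se, f0=f0, f_inf=f_inf,
        recovery_slope=float(lin.slope), recovery_slope_ci=ci,
        tau_s_anova_p=anova_p,
        tail_fraction=tail_fraction,
        mode=mode,
        diagnostics={**diagnostics, "table": table},
    )


def classify_block_mode(
    tail_detected: bool,
    slope_ci: tuple[float, float],
    short_delay_fraction: float = 1.0,
    deep_trapping_threshold: float = 0.7,
) -> str:
    """Rule-based block-mode call.

    sequential if a tail current was seen; otherwise full trapping when the
    fast-fraction trend is flat (slope CI includes 0) and partial trapping
    when it rises.  A tail together with a deeply trapped short-delay
    fraction is contradictory → indeterminate.
    """
    lo, hi = slope_ci
    if tail_detected:
        if short_delay_fraction < deep_trapping_threshold:
            return "indeterminate"
        return "sequential"
    if lo <= 0.0 <= hi:
        return "full_trapping"
    if lo > 0.0:
        return "partial_trapping"
    return "indeterminate"
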