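"""Deterministic master-equation simulation of macroscopic NMDAR currents.

The five-state occupancy vector evolves as dP/dt = Qᵀ(t)·P, where Q depends on
the effective (exchange-lagged) solution composition.  Nominal bath targets
are piecewise constant between epoch boundaries; each species relaxes toward
its target with the first-order lag ``tau_exchange``, giving closed-form
concentration trajectories within each segment.  Macroscopic current is
N·γ·(Vm − E_rev)·P(O) plus optional white Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import IntegrationError, ValidationError
from .model import IDX, RateSet, build_rate_matrix
from .protocols import CONCENTRATION_FIELDS, Protocol


@dataclass
class CurrentTrace:
    """A sampled whole-cell current with its recording conditions.

    ``time`` is a uniform grid in seconds; ``current`` in pA (inward
    negative).  ``states`` (optional, not serialized) holds the simulated
    occupancy matrix, one row per sample, columns ordered as model.STATES.
    """

    time: np.ndarray
    current: np.ndarray
    protocol: Protocol
    seed: int | None = None
    noise_sd: float = 0.0
    states: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape:
            raise ValidationError("time and current must have equal length")
        if self.time.size < 2:
            raise ValidationError("trace needs at least two samples")
        dt = np.diff(self.time)
        if dt.min() <= 0:
            raise ValidationError("time must be strictly increasing")
        if (dt.max() - dt.min()) > 1e-6 * dt.mean():
            raise ValidationError("time grid must be uniform to 1 part in 1e6")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def segment(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        """Time/current samples with t0 <= t < t1."""
        m = (self.time >= t0) & (self.time < t1)
        return self.time[m], self.current[m]


def _sample_grid(protocol: Protocol) -> np.ndarray:
    n = int(np.floor(protocol.total_duration * protocol.sample_rate)) + 1
    return np.arange(n) / protocol.sample_rate


def simulate_trace(
    rates: RateSet,
    protocol: Protocol,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> CurrentTrace:
    """Integrate the kinetic scheme through a protocol and sample the current.

    Deterministic given ``seed``; with ``noise_sd=0`` the output is
    bit-for-bit reproducible.  Raises :class:`IntegrationError` naming the
    time point if occupancies become non-finite.
    """
    Vm = protocol.holding_voltage
    bapta = protocol.bapta_loaded
    tau = rates.tau_exchange
    tgrid = _sample_grid(protocol)
    bounds = protocol.boundaries()

    P = np.zeros(5)
    P[IDX["C"]] = 1.0
    out = np.empty((tgrid.size, 5))
    # effective concentrations at the current segment start
    ceff = {k: 0.0 for k in CONCENTRATION_FIELDS}
    ceff["Ca_out"] = protocol.epochs[0].Ca_out

    filled = 0
    for t0, t1 in zip(bounds, bounds[1:]):
        if t1 <= t0:
            continue
        target = protocol.target_concentrations(0.5 * (t0 + t1))
        c0 = dict(ceff)

        def conc(t: float) -> dict[str, float]:
            if tau <= 0:
                return target
            lag = np.exp(-(t - t0) / tau)
            return {
                k: target[k] + (c0[k] - target[k]) * lag
                for k in CONCENTRATION_FIELDS
            }

        def rhs(t, p):
            Q = build_rate_matrix(rates, conc(t), Vm, bapta)
            return Q.T @ p

        def jac(t, p):
            return build_rate_matrix(rates, conc(t), Vm, bapta).T

        mask = (tgrid >= t0) & (tgrid < t1) if t1 < bounds[-1] else (tgrid >= t0)
        t_eval = tgrid[mask]
        # always integrate through to t1 so the segment-end state is available
        eval_pts = t_eval
        if not eval_pts.size or eval_pts[-1] < t1:
            eval_pts = np.append(eval_pts, t1)
        sol = solve_ivp(
            rhs, (t0, t1), P, method="LSODA", jac=jac, t_eval=eval_pts,
            rtol=rtol, atol=atol,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            bad_t = t0 if not sol.t.size else float(sol.t[-1])
            raise IntegrationError(
                f"master-equation integration failed near t={bad_t:.6g} s", t=bad_t
            )
        ys = sol.y.T
        if t_eval.size:
            out[filled : filled + t_eval.size] = ys[: t_eval.size]
            filled += t_eval.size
        P = np.clip(ys[-1], 0.0, None)
        P /= P.sum()
        ceff = conc(t1)

    # remove solver-tolerance-level negatives and renormalize each sample
    states = np.clip(out[:filled], 0.0, None)
    states /= states.sum(axis=1, keepdims=True)
    tgrid = tgrid[:filled]
    current = rates.n_channels_gamma * (Vm - rates.e_rev) * states[:, IDX["O"]]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd, size=current.size)
    return CurrentTrace(
        time=tgrid,
        current=current,
        protocol=protocol,
        seed=seed,
        noise_sd=noise_sd,
        states=states,
    )
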