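"""Five-state kinetic scheme of NMDAR gating, Ca²⁺-dependent desensitization,
and voltage-dependent open-channel block with trapping.

States::

    C  (closed)            O  (open)             D  (desensitized)
    OB (open, blocked)     CB (closed, blocked = trapped)

Transitions::

    C  -> O   beta_open_max · [NMDA]/([NMDA]+EC50)      (0 while AP5 present)
    O  -> C   alpha_close
    O  -> D   k_des0 · ca_coupling · Ca_influx · (1 + ε·[ATL]/([ATL]+K_ATL))
              × bapta_factor when the cell is BAPTA-loaded
    D  -> O   k_rec
    O  -> OB  k_on0 · [ATL] · exp(−δ·z·Vm / (RT/F))     (Woodhull on-rate)
    OB -> O   k_off0                                     (voltage-independent)
    OB -> CB  alpha_blocked (defaults to alpha_close)    (closure traps blocker)
    CB -> OB  the C→O opening rate
    CB -> C   k_escape                                   (partial trapping)

The blocker's entire voltage dependence sits on the on-rate so that the
equilibrium dissociation constant follows the Woodhull form
K_d(Vm) = (k_off0/k_on0)·exp(δ·z·Vm·F/RT) exactly.  The Ca²⁺-influx surrogate
is the driving-force-scaled bath concentration, normalized to 1·Ca_out at
−70 mV:  Ca_influx = Ca_out·max(0, E_rev − Vm)/(E_rev + 70).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, fields, replace

import numpy as np

from .exceptions import ValidationError

#: state ordering used by every rate matrix and state vector in the package
STATES = ("C", "O", "D", "OB", "CB")
IDX = {s: i for i, s in enumerate(STATES)}

#: effective AP5 (µM) above which activation is fully suppressed; applied
#: AP5 is 50 µM, so 0.5 µM marks the tail end of the exchange transient
AP5_PRESENT_THRESHOLD = 0.5

_NONNEG_RATES = (
    "alpha_close", "beta_open_max", "ec50_nmda", "k_des0", "k_rec",
    "atl_des_gain", "atl_des_k", "ca_coupling", "k_on0", "k_off0", "k_escape",
)


@dataclass(frozen=True)
class RateSet:
    """Rate parameters of the kinetic scheme.

    Units: first-order rates 1/s; ``k_on0`` 1/(s·µM) at 0 mV; ``ec50_nmda``
    and ``atl_des_k`` µM; ``ca_coupling`` 1/mM; ``n_channels_gamma`` the
    lumped N·γ conductance in pA/mV; voltages mV.
    """

    alpha_close: float = 10.0
    beta_open_max: float = 2400.0
    ec50_nmda: float = 20.0
    k_des0: float = 1.0
    k_rec: float = 0.5
    atl_des_gain: float = 2.0        # ε, saturable ATL enhancement of desensitization
    atl_des_k: float = 0.5           # µM, half-max ATL of that enhancement
    ca_coupling: float = 1.0         # 1/mM
    bapta_factor: float = 0.1        # residual desensitization in BAPTA-loaded cells
    k_on0: float = 0.0016 / math.exp(0.51 * 70.0 / 25.7)  # anchored to −70 mV estimate
    k_off0: float = 0.204
    delta_block: float = 0.51        # δ, electrical depth of the blocking site
    z_block: float = 1.0             # blocker valence
    k_escape: float = 0.25           # 1/s, escape from the trapped (CB) state
    n_channels_gamma: float = 20.0   # pA/mV
    e_rev: float = 0.0               # mV
    tau_exchange: float = 0.010      # s, solution-exchange lag
    rt_over_f: float = 25.7          # mV
    alpha_blocked: float | None = None  # OB→CB rate; None → alpha_close

    def __post_init__(self):
        for name in _NONNEG_RATES:
            if getattr(self, name) < 0:
                raise ValidationError(f"rate {name} must be >= 0")
        if not 0.0 <= self.delta_block <= 1.0:
            raise ValidationError("delta_block must lie in [0, 1]")
        if not 0.0 <= self.bapta_factor <= 1.0:
            raise ValidationError("bapta_factor must lie in [0, 1]")
        if self.tau_exchange < 0 or self.rt_over_f <= 0:
            raise ValidationError("tau_exchange >= 0 and rt_over_f > 0 required")
        if self.alpha_blocked is not None and self.alpha_blocked < 0:
            raise ValidationError("alpha_blocked must be >= 0")

    # -- derived quantities -------------------------------------------------

    def k_on(self, Vm: float) -> float:
        """Blocker on-rate (1/(s·µM)) at membrane voltage ``Vm`` (mV)."""
        return self.k_on0 * math.exp(
            -self.delta_block * self.z_block * Vm / self.rt_over_f
        )

    def kd(self, Vm: float) -> float:
        """Equilibrium dissociation constant (µM) at ``Vm``: k_off0/k_on(Vm)."""
        return self.k_off0 / self.k_on(Vm)

    def opening_rate(self, nmda: float, ap5: float = 0.0) -> float:
        """C→O rate; AP5 shuts activation off completely (competitive).

        'Present' means above AP5_PRESENT_THRESHOLD, so a lagged washout
        transient clears in finite time.
        """
        if ap5 > AP5_PRESENT_THRESHOLD or nmda <= 0:
            return 0.0
        return self.beta_open_max * nmda / (nmda + self.ec50_nmda)

    def ca_influx(self, ca_out: float, Vm: float) -> float:
        """Driving-force-scaled Ca²⁺ influx surrogate (mM-equivalents).

        Equals ``ca_out`` at −70 mV and 0 at/above the reversal potential.
        """
        return ca_out * max(0.0, self.e_rev - Vm) / (self.e_rev + 70.0)

    def replace(self, **kw) -> "RateSet":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def build_rate_matrix(
    rates: RateSet,
    solution: dict[str, float],
    Vm: float,
    bapta: bool = False,
) -> np.ndarray:
    """Transition-rate matrix Q over (C, O, D, OB, CB).

    ``Q[i, j]`` is the rate from state i to state j (1/s); diagonals are the
    negated row sums, so dP/dt = Qᵀ·P conserves probability.  ``solution``
    holds the effective concentrations NMDA, ATL, AP5 (µM) and Ca_out (mM).
    """
    if not math.isfinite(Vm):
        raise ValidationError("Vm must be finite")
    nmda = solution.get("NMDA", 0.0)
    atl = solution.get("ATL", 0.0)
    ap5 = solution.get("AP5", 0.0)
    ca = solution.get("Ca_out", 0.0)
    for name, v in (("NMDA", nmda), ("ATL", atl), ("AP5", ap5), ("Ca_out", ca)):
        if v < 0:
            raise ValidationError(f"negative concentration {name}")

    opening = rates.opening_rate(nmda, ap5)
    des = (
        rates.k_des0
        * rates.ca_coupling
        * rates.ca_influx(ca, Vm)
        * (1.0 + rates.atl_des_gain * atl / (atl + rates.atl_des_k) if atl > 0 else 1.0)
    )
    if bapta:
        des *= rates.bapta_factor
    alpha_b = (
        rates.alpha_close if rates.alpha_blocked is None else rates.alpha_blocked
    )

    Q = np.zeros((5, 5))
    Q[IDX["C"], IDX["O"]] = opening
    Q[IDX["O"], IDX["C"]] = rates.alpha_close
    Q[IDX["O"], IDX["D"]] = des
    Q[IDX["D"], IDX["O"]] = rates.k_rec
    Q[IDX["O"], IDX["OB"]] = rates.k_on(Vm) * atl
    Q[IDX["OB"], IDX["O"]] = rates.k_off0
    Q[IDX["OB"], IDX["CB"]] = alpha_b
    Q[IDX["CB"], IDX["OB"]] = opening
    Q[IDX["CB"], IDX["C"]] = rates.k_escape
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def steady_state(Q: np.ndarray) -> np.ndarray:
    """Stationary occupancy vector of Q (solves πᵀQ = 0, Σπ = 1)."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()
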