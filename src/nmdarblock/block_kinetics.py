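"""Blocker rate constants from macroscopic relaxation time constants.

For a bimolecular open-channel block, the relaxation rate onto a blocker step
is 1/τ_on = k_on·[B] + k_off, so two concentrations give

    k_on  = (1/τ_on(C₂) − 1/τ_on(C₁)) / (C₂ − C₁)
    k_off = 1/τ_off
    K_d   = k_off / k_on
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InsufficientDataError, ValidationError


@dataclass(frozen=True)
class BlockKinetics:
    """k_on (1/(s·µM)), k_off (1/s) and K_d (µM) at one holding voltage."""

    k_on: float
    k_off: float
    Vm: float = -70.0
    C1: float | None = None
    C2: float | None = None

    def __post_init__(self):
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValidationError("k_on and k_off must be positive")

    @property
    def Kd(self) -> float:
        return self.k_off / self.k_on

    def to_dict(self) -> dict:
        return {
            "k_on_per_s_uM": self.k_on,
            "k_off_per_s": self.k_off,
            "Kd_uM": self.Kd,
            "Vm_mV": self.Vm,
            "concentrations_uM": [self.C1, self.C2],
        }


def estimate_kon(
    tau_on_c1: float, tau_on_c2: float, c1: float, c2: float,
    min_ratio: float = 3.0,
) -> float:
    """k_on from block-onset time constants at two concentrations.

    Requires C₂ ≥ ``min_ratio``·C₁ to keep the difference well conditioned.
    τ_on must shorten with concentration; a non-positive slope raises.
    """
    if not (c2 > c1 > 0):
        raise ValidationError("need C2 > C1 > 0")
    if c2 < min_ratio * c1:
        raise ValidationError(
            f"C2/C1 = {c2 / c1:.2f} < {min_ratio}: concentrations too close"
        )
    if tau_on_c1 <= 0 or tau_on_c2 <= 0:
        raise ValidationError("time constants must be positive")
    kon = (1.0 / tau_on_c2 - 1.0 / tau_on_c1) / (c2 - c1)
    if kon <= 0:
        raise InsufficientDataError(
            "no concentration dependence: tau_on did not shorten with [B]"
        )
    return kon


def estimate_koff(tau_off: float) -> float:
    """k_off = 1/τ_off from an unblock relaxation."""
    if tau_off <= 0:
        raise ValidationError("tau_off must be positive")
    return 1.0 / tau_off


def equilibrium_kd(k_on: float, k_off: float) -> float:
    """Equilibrium dissociation constant K_d = k_off/k_on (µM)."""
    if k_on <= 0:
        raise ValidationError("k_on must be positive")
    return k_off / k_on


def from_relaxations(
    tau_on_c1: float, tau_on_c2: float, tau_off: float,
    c1: float, c2: float, Vm: float = -70.0,
) -> BlockKinetics:
    """Assemble a BlockKinetics record from the three fitted time constants."""
    return BlockKinetics(
        k_on=estimate_kon(tau_on_c1, tau_on_c2, c1, c2),
        k_off=estimate_koff(tau_off),
        Vm=Vm, C1=c1, C2=c2,
    )
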