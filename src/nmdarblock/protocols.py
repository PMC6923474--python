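"""Solution-application protocols for whole-cell recordings.

A protocol is an ordered, non-overlapping list of solution epochs applied to a
voltage-clamped cell.  Each epoch states the concentrations present in the bath
during that interval; the simulator smooths transitions between epochs with a
first-order exchange lag.  Units are fixed package-wide: time in seconds,
voltage in mV, NMDA/Gly/ATL/AP5 in µM, Ca²⁺ in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Sequence

from .exceptions import ValidationError

#: concentration fields of an epoch, in declaration order
CONCENTRATION_FIELDS = ("NMDA", "Gly", "ATL", "AP5", "Ca_out")


@dataclass(frozen=True)
class SolutionEpoch:
    """One timed application of a bath solution.

    Concentrations: NMDA, Gly, ATL, AP5 in µM; Ca_out in mM.
    """

    t_start: float
    t_end: float
    NMDA: float = 0.0
    Gly: float = 0.0
    ATL: float = 0.0
    AP5: float = 0.0
    Ca_out: float = 1.0

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise ValidationError(
                f"epoch t_end ({self.t_end}) must exceed t_start ({self.t_start})"
            )
        for name in CONCENTRATION_FIELDS:
            if getattr(self, name) < 0:
                raise ValidationError(f"negative concentration {name}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def concentrations(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in CONCENTRATION_FIELDS}


@dataclass(frozen=True)
class Protocol:
    """A full recording protocol: epochs + holding conditions.

    ``bapta_loaded`` marks cells pre-loaded with the fast Ca²⁺ chelator BAPTA,
    which suppresses Ca²⁺-dependent desensitization.
    """

    epochs: tuple[SolutionEpoch, ...]
    holding_voltage: float = -70.0
    bapta_loaded: bool = False
    total_duration: float | None = None
    sample_rate: float = 1000.0

    def __post_init__(self):
        epochs = tuple(self.epochs)
        object.__setattr__(self, "epochs", epochs)
        if not epochs:
            raise ValidationError("protocol needs at least one epoch")
        for a, b in zip(epochs, epochs[1:]):
            if b.t_start < a.t_end:
                raise ValidationError(
                    f"epochs overlap or are out of order at t={b.t_start}"
                )
        if self.total_duration is None:
            object.__setattr__(self, "total_duration", epochs[-1].t_end)
        if self.total_duration < max(e.t_end for e in epochs):
            raise ValidationError("total_duration shorter than the last epoch")
        if not self.sample_rate > 0:
            raise ValidationError("sample_rate must be positive")

    def target_concentrations(self, t: float) -> dict[str, float]:
        """Nominal (pre-lag) bath composition at time ``t``.

        Gaps between epochs are drug-free wash in the bathing solution: the
        Ca²⁺ of the most recent epoch is carried over, everything else is 0.
        """
        ca = self.epochs[0].Ca_out
        for e in self.epochs:
            if t < e.t_start:
                break
            if t < e.t_end:
                return e.concentrations()
            ca = e.Ca_out
        return {"NMDA": 0.0, "Gly": 0.0, "ATL": 0.0, "AP5": 0.0, "Ca_out": ca}

    def boundaries(self) -> list[float]:
        """Sorted unique solution-change times within [0, total_duration]."""
        ts = {0.0, float(self.total_duration)}
        for e in self.epochs:
            ts.update((e.t_start, e.t_end))
        return sorted(t for t in ts if 0.0 <= t <= self.total_duration)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epochs"] = [asdict(e) for e in self.epochs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        epochs = tuple(SolutionEpoch(**e) for e in d["epochs"])
        rest = {k: v for k, v in d.items() if k != "epochs"}
        return cls(epochs=epochs, **rest)


# ---------------------------------------------------------------------------
# Protocol builders emulating the study's recording designs
# ---------------------------------------------------------------------------

_AGONIST = dict(NMDA=100.0, Gly=30.0)  # standard activating solution (µM)


def staircase_protocol(
    atl_levels: Sequence[float],
    ca_out: float = 1.0,
    holding_voltage: float = -70.0,
    bapta_loaded: bool = False,
    pre_s: float = 20.0,
    level_s: float = 25.0,
    baseline_s: float = 2.0,
    sample_rate: float = 200.0,
) -> Protocol:
    """Rising-ATL staircase within one sustained agonist application.

    Baseline (no agonist), then agonist alone for ``pre_s`` to reach steady
    state, then each ATL level for ``level_s`` without interrupting the
    agonist.
    """
    epochs = [SolutionEpoch(0.0, baseline_s, Ca_out=ca_out)]
    t = baseline_s
    epochs.append(SolutionEpoch(t, t + pre_s, Ca_out=ca_out, **_AGONIST))
    t += pre_s
    for atl in atl_levels:
        epochs.append(SolutionEpoch(t, t + level_s, ATL=atl, Ca_out=ca_out, **_AGONIST))
        t += level_s
    return Protocol(
        epochs=tuple(epochs),
        holding_voltage=holding_voltage,
        bapta_loaded=bapta_loaded,
        sample_rate=sample_rate,
    )


def block_step_protocol(
    atl: float,
    ca_out: float = 0.25,
    holding_voltage: float = -70.0,
    pre_s: float = 20.0,
    block_s: float = 30.0,
    wash_s: float = 30.0,
    baseline_s: float = 2.0,
    sample_rate: float = 200.0,
) -> Protocol:
    """Single ATL step at steady state, then unblock in agonist alone.

    Yields the block-onset and -offset relaxations used for k_on/k_off
    estimation.
    """
    e = [
        SolutionEpoch(0.0, baseline_s, Ca_out=ca_out),
        SolutionEpoch(baseline_s, baseline_s + pre_s, Ca_out=ca_out, **_AGONIST),
        SolutionEpoch(
            baseline_s + pre_s, baseline_s + pre_s + block_s,
            ATL=atl, Ca_out=ca_out, **_AGONIST,
        ),
        SolutionEpoch(
            baseline_s + pre_s + block_s, baseline_s + pre_s + block_s + wash_s,
            Ca_out=ca_out, **_AGONIST,
        ),
    ]
    return Protocol(
        epochs=tuple(e), holding_voltage=holding_voltage, sample_rate=sample_rate
    )


def trapping_protocol(
    t_ap5: float,
    atl: float = 200.0,
    ca_out: float = 0.25,
    holding_voltage: float = -70.0,
    control_s: float = 15.0,
    block_s: float = 10.0,
    test_s: float = 30.0,
    gap_s: float = 0.2,
    baseline_s: float = 2.0,
    ap5: float = 50.0,
    sample_rate: float = 500.0,
) -> Protocol:
    """Trapping-block protocol: block, washout under AP5, test pulse.

    Agonist application to steady state, co-application of ATL, simultaneous
    removal of agonist and blocker into AP5-containing wash of duration
    ``t_ap5``, then a test agonist application whose rise time reports the
    trapped fraction.
    """
    if t_ap5 <= 0:
        raise ValidationError("t_ap5 must be positive")
    t0 = baseline_s
    t1 = t0 + control_s
    t2 = t1 + block_s
    t3 = t2 + t_ap5
    e = [
        SolutionEpoch(0.0, t0, Ca_out=ca_out),
        SolutionEpoch(t0, t1, Ca_out=ca_out, **_AGONIST),
        SolutionEpoch(t1, t2, ATL=atl, Ca_out=ca_out, **_AGONIST),
        SolutionEpoch(t2, t3, AP5=ap5, Ca_out=ca_out),
        SolutionEpoch(t3, t3 + test_s, Ca_out=ca_out, **_AGONIST),
    ]
    return Protocol(
        epochs=tuple(e), holding_voltage=holding_voltage, sample_rate=sample_rate
    )


def agonist_pulse_protocol(
    ca_out: float = 1.0,
    holding_voltage: float = -70.0,
    pulse_s: float = 20.0,
    baseline_s: float = 2.0,
    wash_s: float = 5.0,
    bapta_loaded: bool = False,
    sample_rate: float = 200.0,
) -> Protocol:
    """A single agonist application (control current, no blocker)."""
    e = [
        SolutionEpoch(0.0, baseline_s, Ca_out=ca_out),
        SolutionEpoch(baseline_s, baseline_s + pulse_s, Ca_out=ca_out, **_AGONIST),
        SolutionEpoch(
            baseline_s + pulse_s, baseline_s + pulse_s + wash_s, Ca_out=ca_out
        ),
    ]
    return Protocol(
        epochs=tuple(e),
        holding_voltage=holding_voltage,
        bapta_loaded=bapta_loaded,
        sample_rate=sample_rate,
    )
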