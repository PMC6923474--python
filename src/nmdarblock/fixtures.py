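"""Study-fixture generation: simulated 'cells' under the study's conditions.

The generator emulates the recording designs the analysis consumes —
rising-ATL staircases across bath [Ca²⁺] and holding voltage, single ATL
steps for relaxation kinetics, the trapping protocol across washout
durations, and BAPTA-loaded cells — with cell-to-cell lognormal jitter on
conductance and rate parameters, plus a machine-readable ground-truth record
of every cell's true parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .exceptions import ValidationError
from .model import IDX, RateSet, build_rate_matrix, steady_state
from .protocols import (
    Protocol,
    block_step_protocol,
    staircase_protocol,
    trapping_protocol,
)
from .simulate import CurrentTrace, simulate_trace
from . import trace_io

_AGONIST_SOLUTION = dict(NMDA=100.0, Gly=30.0, AP5=0.0)


def steady_state_po_ratio(
    rates: RateSet, atl: float, ca: float, Vm: float, bapta: bool = False
) -> float:
    """Stationary I_b/I_c: open-state occupancy with blocker over without."""
    base = dict(_AGONIST_SOLUTION, ATL=0.0, Ca_out=ca)
    blocked = dict(_AGONIST_SOLUTION, ATL=atl, Ca_out=ca)
    po0 = steady_state(build_rate_matrix(rates, base, Vm, bapta))[IDX["O"]]
    pob = steady_state(build_rate_matrix(rates, blocked, Vm, bapta))[IDX["O"]]
    return float(pob / po0)


def steady_state_ic50(
    rates: RateSet, Vm: float = -70.0, ca: float = 1.0, bapta: bool = False,
    bracket: tuple[float, float] = (1e-4, 1e5),
) -> float:
    """Ground-truth IC₅₀ (µM): the ATL level halving the stationary current."""
    f = lambda b: steady_state_po_ratio(rates, b, ca, Vm, bapta) - 0.5
    return float(brentq(f, *bracket, xtol=1e-10, rtol=1e-12))


def default_staircase_levels(
    rates: RateSet, Vm: float, ca: float, bapta: bool = False,
    factors: tuple[float, ...] = (1 / 9, 1 / 3, 1.0, 3.0, 9.0),
) -> list[float]:
    """Five log-spaced ATL levels bracketing the condition's expected IC₅₀
    (the concentrations a pilot experiment would have chosen)."""
    ic50 = steady_state_ic50(rates, Vm, ca, bapta)
    return [round(ic50 * f, 4) for f in factors]


def jittered_rates(
    base: RateSet,
    rng: np.random.Generator,
    sigma_conductance: float = 0.2,
    sigma_rates: float = 0.05,
) -> RateSet:
    """Cell-to-cell variability: lognormal jitter on conductance and rates."""
    jit = lambda s: float(np.exp(rng.normal(0.0, s)))
    return base.replace(
        n_channels_gamma=base.n_channels_gamma * jit(sigma_conductance),
        k_on0=base.k_on0 * jit(sigma_rates),
        k_off0=base.k_off0 * jit(sigma_rates),
        k_des0=base.k_des0 * jit(sigma_rates),
        k_escape=base.k_escape * jit(sigma_rates) if base.k_escape > 0 else 0.0,
    )


@dataclass
class FixtureRecord:
    """One simulated recording plus its condition metadata and true rates."""

    trace: CurrentTrace
    meta: dict
    rates: RateSet


@dataclass
class StudyFixtures:
    records: list[FixtureRecord] = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)

    def select(self, **conditions) -> list[FixtureRecord]:
        out = []
        for r in self.records:
            if all(r.meta.get(k) == v for k, v in conditions.items()):
                out.append(r)
        return out

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for k, r in enumerate(self.records):
            trace_io.write_trace(r.trace, directory / f"trace_{k:04d}.tsv", meta=r.meta)
        with open(directory / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1)


@dataclass(frozen=True)
class StudyConfig:
    """Which study conditions to emulate and at what size/noise."""

    ca_levels: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    voltages: tuple[float, ...] = (-100.0, -70.0, -30.0)
    voltage_ca: float = 0.25
    t_ap5: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    trapping_atl: float = 1000.0
    bapta_ca: float = 1.0
    kinetics_concs: tuple[float, float] = (10.0, 100.0)
    n_cells: int = 5
    noise_sd: float = 5.0
    sigma_conductance: float = 0.2
    sigma_rates: float = 0.05
    include: tuple[str, ...] = (
        "dose_response", "voltage", "kinetics", "trapping", "bapta",
    )
    sample_rate: float = 100.0

    def __post_init__(self):
        if self.n_cells < 2:
            raise ValidationError(
                "need >= 2 cells per condition (SEM undefined otherwise)"
            )
        unknown = set(self.include) - {
            "dose_response", "voltage", "kinetics", "trapping", "bapta",
        }
        if unknown:
            raise ValidationError(f"unknown fixture families: {sorted(unknown)}")


def _cell_rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng([seed, *stream])


def make_study_fixtures(
    config: StudyConfig,
    seed: int,
    rates: RateSet | None = None,
) -> StudyFixtures:
    """Simulate per-cell traces for every requested condition family.

    Deterministic given ``seed``: each cell draws its jittered parameters and
    recording noise from a stream derived by fixed offsets.  The returned
    ground truth maps cell ids to their true rates and stationary IC₅₀s.
    """
    base = rates if rates is not None else RateSet()
    out = StudyFixtures()
    truth: dict[str, dict] = {}

    def run(protocol: Protocol, cell_rates: RateSet, cell_id: str, **meta):
        trace = simulate_trace(
            cell_rates, protocol,
            noise_sd=config.noise_sd,
            seed=int(_cell_rng(seed, 999, len(out.records)).integers(2**31)),
        )
        rec = FixtureRecord(
            trace=trace, meta={"cell_id": cell_id, **meta}, rates=cell_rates
        )
        out.records.append(rec)
        return rec

    def cell_truth(cell_id: str, cell_rates: RateSet, Vm: float, ca: float, bapta: bool):
        truth.setdefault(
            cell_id,
            {
                "rates": cell_rates.to_dict(),
                "conditions": [],
            },
        )["conditions"].append(
            {
                "Vm": Vm, "Ca_out": ca, "bapta": bapta,
                "ic50_true": steady_state_ic50(cell_rates, Vm, ca, bapta),
                "kd_true": cell_rates.kd(Vm),
            }
        )

    stream = 0
    if "dose_response" in config.include:
        for ca in config.ca_levels:
            levels = default_staircase_levels(base, -70.0, ca)
            for c in range(config.n_cells):
                cell_id = f"dr_ca{ca}_c{c}"
                cr = jittered_rates(
                    base, _cell_rng(seed, stream, c),
                    config.sigma_conductance, config.sigma_rates,
                )
                proto = staircase_protocol(
                    levels, ca_out=ca, sample_rate=config.sample_rate
                )
                run(proto, cr, cell_id, kind="dose_response", Ca_out=ca,
                    Vm=-70.0, bapta=False)
                cell_truth(cell_id, cr, -70.0, ca, False)
            stream += 1

    if "voltage" in config.include:
        for vm in config.voltages:
            levels = default_staircase_levels(base, vm, config.voltage_ca)
            for c in range(config.n_cells):
                cell_id = f"volt_vm{int(vm)}_c{c}"
                cr = jittered_rates(
                    base, _cell_rng(seed, stream, c),
                    config.sigma_conductance, config.sigma_rates,
                )
                proto = staircase_protocol(
                    levels, ca_out=config.voltage_ca, holding_voltage=vm,
                    sample_rate=config.sample_rate,
                )
                run(proto, cr, cell_id, kind="voltage", Ca_out=config.voltage_ca,
                    Vm=vm, bapta=False)
                cell_truth(cell_id, cr, vm, config.voltage_ca, False)
            stream += 1

    if "kinetics" in config.include:
        # relaxation kinetics are measured where block is the only slow
        # process (the low-Ca design): desensitization-free parameter set
        kin_base = base.replace(k_des0=0.0)
        for atl in config.kinetics_concs:
            for c in range(config.n_cells):
                cell_id = f"kin_atl{int(atl)}_c{c}"
                cr = jittered_rates(
                    kin_base, _cell_rng(seed, stream, c),
                    config.sigma_conductance, config.sigma_rates,
                )
                proto = block_step_protocol(
                    atl, ca_out=0.25, sample_rate=config.sample_rate
                )
                run(proto, cr, cell_id, kind="kinetics", ATL=atl, Ca_out=0.25,
                    Vm=-70.0, bapta=False)
                cell_truth(cell_id, cr, -70.0, 0.25, False)
            stream += 1

    if "trapping" in config.include:
        # the trapping protocol isolates block from desensitization (the
        # low-Ca design of the original recordings); the fixture family
        # therefore runs the desensitization-free variant, at an ATL well
        # above K_d so the trapped pool dominates the test-pulse rise
        trap_base = base.replace(k_des0=0.0)
        for t_ap5 in config.t_ap5:
            for c in range(config.n_cells):
                cell_id = f"trap_t{t_ap5}_c{c}"
                cr = jittered_rates(
                    trap_base, _cell_rng(seed, stream, c),
                    config.sigma_conductance, config.sigma_rates,
                )
                proto = trapping_protocol(
                    t_ap5, atl=config.trapping_atl, ca_out=0.25,
                    sample_rate=max(config.sample_rate, 500.0),
                )
                run(proto, cr, cell_id, kind="trapping", t_AP5=t_ap5,
                    Ca_out=0.25, Vm=-70.0, bapta=False)
                cell_truth(cell_id, cr, -70.0, 0.25, False)
            stream += 1

    if "bapta" in config.include:
        levels = default_staircase_levels(base, -70.0, config.bapta_ca, bapta=True)
        for c in range(config.n_cells):
            cell_id = f"bapta_c{c}"
            cr = jittered_rates(
                base, _cell_rng(seed, stream, c),
                config.sigma_conductance, config.sigma_rates,
            )
            proto = staircase_protocol(
                levels, ca_out=config.bapta_ca, bapta_loaded=True,
                sample_rate=config.sample_rate,
            )
            run(proto, cr, cell_id, kind="bapta", Ca_out=config.bapta_ca,
                Vm=-70.0, bapta=True)
            cell_truth(cell_id, cr, -70.0, config.bapta_ca, True)
        stream += 1

    out.ground_truth = {
        "seed": seed,
        "base_rates": base.to_dict(),
        "config": asdict(config),
        "cells": truth,
    }
    return out
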