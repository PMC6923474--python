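"""Reading and writing of trace files and their protocol sidecars.

One trace is stored as a two-column tab-delimited text file (``time_s``,
``current_pA``) plus a JSON sidecar (same path + ``.json``) holding the
protocol, units, seed/noise provenance and optional condition metadata.  The
unit contract is fixed: seconds, pA, mV, µM (ATL/NMDA/Gly/AP5), mM (Ca²⁺);
files declaring anything else are rejected at parse time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import UnitError, ValidationError
from .protocols import Protocol
from .simulate import CurrentTrace

_UNITS = {"time": "s", "current": "pA"}


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_trace(trace: CurrentTrace, path: str | Path, meta: dict | None = None) -> None:
    """Write a trace and its sidecar; 64-bit lossless via 17-digit text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("time_s\tcurrent_pA\n")
        for t, c in zip(trace.time, trace.current):
            fh.write(f"{t:.17g}\t{c:.17g}\n")
    sidecar = {
        "units": dict(_UNITS),
        "protocol": trace.protocol.to_dict(),
        "seed": trace.seed,
        "noise_sd": trace.noise_sd,
        "meta": meta or {},
    }
    with open(sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_trace(path: str | Path) -> CurrentTrace:
    """Read and validate a trace; raises typed errors naming the file."""
    path = Path(path)
    sc = sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace data file missing: {path}")
    if not sc.exists():
        raise FileNotFoundError(f"trace sidecar missing: {sc}")
    with open(sc) as fh:
        sidecar = json.load(fh)
    units = sidecar.get("units", {})
    if units != _UNITS:
        raise UnitError(f"{sc}: units {units!r} != required {_UNITS!r}")
    try:
        protocol = Protocol.from_dict(sidecar["protocol"])
    except (KeyError, TypeError, ValidationError) as exc:
        raise ValidationError(f"{sc}: invalid protocol ({exc})") from exc
    data = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(data.columns) != ["time_s", "current_pA"]:
        raise ValidationError(f"{path}: expected columns time_s, current_pA")
    try:
        trace = CurrentTrace(
            time=data["time_s"].to_numpy(),
            current=data["current_pA"].to_numpy(),
            protocol=protocol,
            seed=sidecar.get("seed"),
            noise_sd=sidecar.get("noise_sd", 0.0),
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    trace.meta = sidecar.get("meta", {})  # type: ignore[attr-defined]
    return trace


@dataclass
class TraceBundle:
    """A set of traces plus a per-trace condition manifest."""

    traces: list[CurrentTrace] = field(default_factory=list)
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.traces)


_MANIFEST_COLS = ["path", "cell_id", "Vm", "Ca_out", "bapta", "kind"]


def read_bundle(directory: str | Path) -> TraceBundle:
    """Load every trace in ``directory`` and assemble the condition manifest.

    One manifest record per sidecar; manifest keys (paths) are unique by
    construction.
    """
    directory = Path(directory)
    rows, traces = [], []
    for sc in sorted(directory.glob("*.tsv.json")):
        data_path = Path(str(sc)[: -len(".json")])
        trace = read_trace(data_path)
        meta = getattr(trace, "meta", {})
        rows.append(
            {
                "path": str(data_path),
                "cell_id": meta.get("cell_id"),
                "Vm": trace.protocol.holding_voltage,
                "Ca_out": trace.protocol.epochs[-1].Ca_out,
                "bapta": trace.protocol.bapta_loaded,
                "kind": meta.get("kind"),
                **{
                    k: v
                    for k, v in meta.items()
                    if k not in {"cell_id", "kind"} and np.isscalar(v)
                },
            }
        )
        traces.append(trace)
    manifest = pd.DataFrame(rows)
    return TraceBundle(traces=traces, manifest=manifest)


def validate_directory(directory: str | Path) -> list[str]:
    """Lint a fixture directory; returns a list of problems (empty if clean)."""
    directory = Path(directory)
    problems = []
    for sc in sorted(directory.glob("*.tsv.json")):
        data_path = Path(str(sc)[: -len(".json")])
        try:
            read_trace(data_path)
        except (ValidationError, FileNotFoundError, UnitError) as exc:
            problems.append(str(exc))
    for tsv in sorted(directory.glob("*.tsv")):
        if not sidecar_path(tsv).exists():
            problems.append(f"trace sidecar missing: {sidecar_path(tsv)}")
    return problems
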