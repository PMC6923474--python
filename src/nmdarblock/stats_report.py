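"""Group statistics (two-tailed t, one-way ANOVA with Bonferroni) and the
end-to-end study pipeline.

Summary convention: mean ± SEM over cells (SEM = sd/√n); significance stars
follow the study's caption convention (*** p<0.001, **** p<0.0001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InsufficientDataError, ValidationError

log = logging.getLogger("nmdarblock")


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    return ""


def mean_sem(values) -> tuple[float, float, int]:
    v = np.asarray(values, dtype=float)
    n = v.size
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(n)), n


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of one statistical comparison between groups of cells."""

    labels: tuple
    test: str
    statistic: float
    p: float
    n_per_group: tuple[int, ...]
    stars: str = ""
    pairwise: pd.DataFrame | None = field(default=None, compare=False)


def compare_groups(values_a, values_b, labels=("a", "b")) -> GroupComparison:
    """Unpaired two-tailed Student's t-test (pooled variance)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return GroupComparison(
                tuple(labels), "t_two_tailed", 0.0, 1.0, (a.size, b.size)
            )
        raise ValidationError("zero variance in both groups: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        tuple(labels), "t_two_tailed", float(t), float(p),
        (a.size, b.size), significance_stars(float(p)),
    )


def anova_bonferroni(groups: dict, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA plus all pairwise t-tests at Bonferroni-adjusted alpha."""
    if len(groups) < 3:
        raise InsufficientDataError("ANOVA needs >= 3 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise InsufficientDataError(f"group {k!r} has n < 2")
    F, p = sps.f_oneway(*arrays.values())
    m = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for (ka, va), (kb, vb) in combinations(arrays.items(), 2):
        t, pp = sps.ttest_ind(va, vb, equal_var=True)
        rows.append(
            {
                "group_a": ka, "group_b": kb, "t": float(t), "p": float(pp),
                "p_bonferroni": min(float(pp) * m, 1.0),
                "significant": float(pp) < alpha / m,
            }
        )
    return GroupComparison(
        tuple(arrays), "anova_bonferroni", float(F), float(p),
        tuple(v.size for v in arrays.values()),
        significance_stars(float(p)), pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def run_pipeline(config: dict | None = None, seed: int = 0) -> dict:
    """Simulate → measure → fit → classify → test: the full study in one call.

    ``config`` may override StudyConfig fields under key ``"study"`` and the
    simulator rates under ``"rates"``.  Stages run independently: a failing
    stage is recorded as failed and the rest continue.  Returns a
    JSON-serializable report; deterministic given ``seed``.
    """
    from .calibration import REPORTED_IC50_025CA
    from .dose_response import condition_summary, extract_staircase, fit_hill_per_cell
    from .dependence_models import (
        composed_prefactor, fit_ca_exponential, fit_surface, fit_woodhull,
    )
    from .fixtures import StudyConfig, make_study_fixtures
    from .model import RateSet
    from .trace_analysis import fit_monoexp, steady_state_measure
    from .block_kinetics import from_relaxations
    from .trapping import analyze_trapping

    config = config or {}
    study = StudyConfig(**config.get("study", {}))
    rates = RateSet.from_dict(config["rates"]) if "rates" in config else RateSet()
    report: dict = {"seed": seed, "stages": {}}

    def stage(name, fn):
        try:
            out = fn()
            report["stages"][name] = {"status": "ok", "result": _jsonable(out)}
            log.info("stage %s ok", name)
            return out
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            log.warning("stage %s failed: %s", name, exc)
            return None

    fixtures = stage(
        "simulate", lambda: None or make_study_fixtures(study, seed, rates)
    )
    if fixtures is None:
        return report
    report["stages"]["simulate"]["result"] = {
        "n_traces": len(fixtures.records),
        "families": sorted({r.meta["kind"] for r in fixtures.records}),
    }

    def hill_by(kind: str, group_key: str):
        rows = {}
        for rec in fixtures.select(kind=kind):
            pts = extract_staircase(
                rec.trace, tau_exchange=rates.tau_exchange,
                cell_id=rec.meta["cell_id"],
            )
            rows.setdefault(rec.meta[group_key], []).extend(pts)
        fits = {k: fit_hill_per_cell(v) for k, v in rows.items()}
        summaries = {k: condition_summary(v) for k, v in fits.items()}
        return fits, summaries

    dose = stage("dose_response", lambda: hill_by("dose_response", "Ca_out"))
    volt = stage("voltage", lambda: hill_by("voltage", "Vm"))
    if dose is not None:
        report["stages"]["dose_response"]["result"] = {
            str(ca): s.to_dict() for ca, s in dose[1].items()
        }
    if volt is not None:
        report["stages"]["voltage"]["result"] = {
            str(vm): s.to_dict() for vm, s in volt[1].items()
        }

    def kinetics():
        taus: dict[float, list[float]] = {}
        koffs: list[float] = []
        for rec in fixtures.select(kind="kinetics"):
            tr, atl = rec.trace, rec.meta["ATL"]
            epochs = tr.protocol.epochs
            block = next(k for k, e in enumerate(epochs) if e.ATL > 0)
            on_e, off_e = epochs[block], epochs[block + 1]
            lag = 3 * rates.tau_exchange
            fit_on = fit_monoexp(*tr.segment(on_e.t_start + lag, on_e.t_end))
            fit_off = fit_monoexp(*tr.segment(off_e.t_start + lag, off_e.t_end))
            taus.setdefault(atl, []).append(fit_on.tau)
            koffs.append(1.0 / fit_off.tau)
        (c1, t1), (c2, t2) = sorted(taus.items())
        bk = from_relaxations(
            float(np.mean(t1)), float(np.mean(t2)),
            1.0 / float(np.mean(koffs)), c1, c2,
        )
        return bk.to_dict()

    kin = stage("kinetics", kinetics)

    ca_fit = None
    if dose is not None:
        def ca_exp():
            cas = sorted(dose[1])
            means = [dose[1][ca]["ic50_mean"] for ca in cas]
            f = fit_ca_exponential(np.array(cas), np.array(means))
            return f
        ca_fit = stage("ca_dependence", ca_exp)
        if ca_fit is not None:
            report["stages"]["ca_dependence"]["result"] = {
                "amplitude_uM": ca_fit.amplitude, "b_mM": ca_fit.b_ca,
            }

    wh = None
    if volt is not None:
        def woodhull():
            vms, ics = [], []
            for vm, fits in volt[0].items():
                for f in fits:
                    vms.append(vm)
                    ics.append(f.ic50)
            return fit_woodhull(np.array(vms), np.array(ics))
        wh = stage("woodhull", woodhull)
        if wh is not None:
            report["stages"]["woodhull"]["result"] = {
                "ic50_0mv_uM": wh.ic50_0mv, "delta": wh.delta,
                "e_fold_mV": wh.e_fold_mV,
            }

    if dose is not None and volt is not None:
        def surface():
            vms, cas, ics = [], [], []
            for ca, fits in dose[0].items():
                for f in fits:
                    vms.append(f.Vm); cas.append(ca); ics.append(f.ic50)
            for vm, fits in volt[0].items():
                for f in fits:
                    vms.append(vm); cas.append(f.Ca_out); ics.append(f.ic50)
            sf = fit_surface(np.array(vms), np.array(cas), np.array(ics))
            out = {"prefactor_uM": sf.prefactor, "a_per_mV": sf.a, "b_mM": sf.b,
                   "delta_implied": sf.delta_implied}
            if wh is not None and ca_fit is not None:
                ref = dose[1].get(0.25, {"ic50_mean": REPORTED_IC50_025CA})["ic50_mean"]
                out["composed_prefactor_uM"] = composed_prefactor(
                    wh.ic50_0mv, ca_fit.amplitude, float(ref)
                )
            return out
        stage("surface", surface)

    def trapping_stage():
        by_delay: dict[float, list] = {}
        for rec in fixtures.select(kind="trapping"):
            by_delay.setdefault(rec.meta["t_AP5"], []).append(rec.trace)
        if not by_delay:
            raise InsufficientDataError("no trapping fixtures generated")
        res = analyze_trapping(by_delay, tau_exchange=rates.tau_exchange)
        return {
            "mode": res.mode,
            "escape_rate_per_s": res.escape_rate,
            "tau_s_anova_p": res.tau_s_anova_p,
            "tail_fraction": res.tail_fraction,
            "per_washout": res.per_washout,
        }

    stage("trapping", trapping_stage)

    if dose is not None:
        def stats_stage():
            out = {}
            bapta = fixtures.select(kind="bapta")
            if bapta:
                b_fits = fit_hill_per_cell(
                    [
                        p
                        for rec in bapta
                        for p in extract_staircase(
                            rec.trace, tau_exchange=rates.tau_exchange,
                            cell_id=rec.meta["cell_id"],
                        )
                    ]
                )
                ca_key = bapta[0].meta["Ca_out"]
                if ca_key in dose[0]:
                    cmp = compare_groups(
                        [f.ic50 for f in dose[0][ca_key]],
                        [f.ic50 for f in b_fits],
                        labels=("control", "bapta"),
                    )
                    out["bapta_vs_control"] = {
                        "t": cmp.statistic, "p": cmp.p, "stars": cmp.stars,
                        "control_ic50": mean_sem([f.ic50 for f in dose[0][ca_key]])[0],
                        "bapta_ic50": mean_sem([f.ic50 for f in b_fits])[0],
                    }
            ordered = [dose[1][ca]["ic50_mean"] for ca in sorted(dose[1])]
            out["ic50_strictly_decreasing_in_ca"] = bool(
                np.all(np.diff(ordered) < 0)
            )
            return out

        stage("stats", stats_stage)

    if kin is not None:
        report["stages"]["kinetics"]["result"] = kin
    return _jsonable(report)
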