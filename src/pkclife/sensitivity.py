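"""Local one-at-a-time parameter sensitivity of total PKC.

Each parameter is perturbed individually (5-fold increase and 90%
reduction) while all others stay at baseline, under a low-intensity
(0.0005 nM) and a high-intensity (0.5 nM) stimulation protocol.  The
effect metric is the maximum over time of |total PKC (perturbed) − total
PKC (baseline)| normalized by the baseline maximum, and parameters are
classed high / moderate / insensitive by fixed effect thresholds.  The
thresholds are heuristics for ranking, not physical constants, and are
exposed as arguments.

No global (Sobol/Morris) analysis is attempted; the procedure is strictly
one-at-a-time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .defaults import default_parameterization
from .network import Parameterization, build_default_network
from .protocols import Protocol, Pulse
from .scenarios import (
    ACTIVATOR_DURATION,
    ACTIVATOR_ONSET,
    SYNTHESIS_PULSE,
    ScenarioResult,
    _final_total,
)
from .simulate import SimulationError, simulate, species_series, total_pkc_series

__all__ = [
    "SENSITIVITY_PARAMETERS",
    "UNLISTED_PARAMETERS",
    "CLASS_THRESHOLDS",
    "SensitivityRecord",
    "classify",
    "sensitivity_map",
    "parameter_classes",
    "pdk1_expression_sweep",
]

# parameters swept by default: every rate constant, the degradation rates,
# the polyribosome level T and the PDK1 level
SENSITIVITY_PARAMETERS: tuple[str, ...] = tuple(
    [f"k{i}" for i in range(1, 21)] + ["lam1", "lam2", "lam3", "lam4",
                                       "T", "PDK1"]
)

# swept for completeness although absent from the reference qualitative
# classification; reported separately in the summary
UNLISTED_PARAMETERS: frozenset[str] = frozenset({"k3", "k20", "lam4"})

CLASS_THRESHOLDS: dict[str, float] = {"high": 0.5, "moderate": 0.05}

SCENARIO_AMPLITUDES: dict[str, float] = {"low": 0.0005, "high": 0.5}
PERTURBATION_FACTORS: tuple[float, ...] = (5.0, 0.1)


@dataclass(frozen=True)
class SensitivityRecord:
    parameter: str
    scenario: str
    factor: float
    effect: float
    klass: str
    failed: bool = False


def classify(effect: float,
             thresholds: dict[str, float] | None = None) -> str:
    th = CLASS_THRESHOLDS if thresholds is None else thresholds
    if not np.isfinite(effect):
        return "failed"
    if effect >= th["high"]:
        return "high"
    if effect >= th["moderate"]:
        return "moderate"
    return "insensitive"


def _stimulation_protocol(amplitude: float) -> Protocol:
    return Protocol(
        t_end=ACTIVATOR_ONSET + ACTIVATOR_DURATION + 120.0,
        synthesis_pulses=(SYNTHESIS_PULSE,),
        activator_pulses=(
            Pulse(ACTIVATOR_ONSET, ACTIVATOR_DURATION, amplitude),),
    )


def _total(params: Parameterization, protocol: Protocol) -> np.ndarray:
    net = build_default_network()
    return total_pkc_series(simulate(net, params, protocol)).to_numpy()


def sensitivity_map(
    params: Parameterization | None = None,
    parameter_ids: tuple[str, ...] | None = None,
    scenarios: tuple[str, ...] = ("low", "high"),
    factors: tuple[float, ...] = PERTURBATION_FACTORS,
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Long-format table of SensitivityRecords: one row per
    (parameter, scenario, factor).

    Integrator failures under a perturbation are flagged (effect NaN,
    failed True), never silently dropped.
    """
    p = default_parameterization() if params is None else params
    ids = SENSITIVITY_PARAMETERS if parameter_ids is None else parameter_ids
    baselines = {
        sc: _total(p, _stimulation_protocol(SCENARIO_AMPLITUDES[sc]))
        for sc in scenarios
    }
    rows = []
    for pid in ids:
        for sc in scenarios:
            base = baselines[sc]
            norm = float(np.max(base))
            proto = _stimulation_protocol(SCENARIO_AMPLITUDES[sc])
            for factor in factors:
                failed = False
                try:
                    pert = _total(p.with_(**{pid: p.get(pid) * factor}), proto)
                    effect = float(np.max(np.abs(pert - base)) / norm)
                except SimulationError:
                    effect, failed = float("nan"), True
                rows.append(SensitivityRecord(
                    parameter=pid, scenario=sc, factor=factor,
                    effect=effect, klass=classify(effect, thresholds),
                    failed=failed))
    return pd.DataFrame([r.__dict__ for r in rows])


def parameter_classes(
    table: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
) -> pd.Series:
    """Per-parameter class: the maximum class over the four perturbation
    runs (ranked insensitive < moderate < high; failed runs excluded)."""
    effects = table.dropna(subset=["effect"]).groupby("parameter")["effect"]
    return effects.max().map(lambda e: classify(e, thresholds))


def pdk1_expression_sweep(
    levels: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0),
    params: Parameterization | None = None,
) -> ScenarioResult:
    """Totals and the mature / membrane-active / dephosphorylated-active
    state series across clamped PDK1 expression levels, under the low- and
    high-intensity stimulation protocols."""
    p = default_parameterization() if params is None else params
    net = build_default_network()
    conditions = []
    trajs = {}
    for sc, amp in SCENARIO_AMPLITUDES.items():
        proto = _stimulation_protocol(amp)
        for level in levels:
            pl = p.with_(PDK1=level)
            tr = simulate(net, pl, proto)
            key = f"{sc}_pdk1_{level:g}"
            trajs[key] = tr
            tot = total_pkc_series(tr)
            conditions.append({
                "condition": key,
                "scenario": sc,
                "pdk1_level": level,
                "final_total": _final_total(tr),
                "plateau_total": float(
                    tot[(tot.index >= 40.0) & (tot.index <= 50.0)].mean()),
                "peak_mature": float(
                    species_series(tr, "CPKC_PAPHPT").max()),
                "peak_active_membrane": float(
                    species_series(tr, "PKC_PAPHPT_act").max()),
                "peak_active_dephos": float(
                    species_series(tr, "PKC_A").max()),
            })
    metrics = {
        "levels": list(levels),
        "plateau_totals_low": [c["plateau_total"] for c in conditions
                               if c["scenario"] == "low"],
        "plateau_totals_high": [c["plateau_total"] for c in conditions
                                if c["scenario"] == "high"],
    }
    return ScenarioResult("pdk1_expression", conditions, trajs, metrics)
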