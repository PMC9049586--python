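"""Named, pre-built simulation experiments.

Each ``run_*`` function reproduces one published-figure experiment of the
life-cycle study: the activator dose-response, the pulse-duration sweep,
dephosphorylation blocking, sequential intermediate-strength pulses, HSP70
overexpression, PHLPP blocking, the rescue-by-second-synthesis experiment
and the dual-degradation variant.  All run from the shipped default
parameterization unless one is passed explicitly.

Down-regulation metrics
-----------------------
"Down-regulation" is the activator-induced loss of total PKC.  Because the
mature pool also turns over slowly (rate lam4) regardless of stimulation,
loss and retention are measured against a time-matched synthesis-only
control run: retention = final total (stimulated) / final total (control).
The absolute pre-pulse plateau and final totals are reported alongside.
"Final" totals are means over the last 10 minutes of the run.

Measurement windows
-------------------
The pre-activation plateau is read over 40-50 min (between the end of
maturation and the 50-min activator pulse).  Sequential-pulse drops use a
10-min pre-window ending at pulse onset and a 10-min post-window starting
50 min after pulse end, by which time the transient active species have
resolved.  A slope guard of 0.05 ng/ml/min accommodates the slow basal
turnover of the mature pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .defaults import default_parameterization
from .network import Parameterization, build_default_network
from .protocols import Protocol, Pulse
from .simulate import (
    Trajectory,
    drop_after_pulse,
    half_time,
    plateau_value,
    simulate,
    species_series,
    total_pkc_series,
)

__all__ = [
    "ScenarioResult",
    "SCENARIOS",
    "run_scenario",
    "run_dose_response",
    "run_duration_sweep",
    "run_block_dephosphorylation",
    "run_sequential_pulses",
    "run_hsp70_sweep",
    "run_phlpp_block_sweep",
    "run_second_synthesis_pulse",
    "run_dual_degradation_variant",
]

SYNTHESIS_PULSE = Pulse(0.0, 10.0)          # 10-min protein-synthesis pulse
ACTIVATOR_ONSET = 50.0                      # min
ACTIVATOR_DURATION = 15.0                   # min
DOSE_AMPLITUDES = (0.0005, 0.005, 0.05, 0.5)   # nM
PLATEAU_WINDOW = (40.0, 50.0)
PLATEAU_SLOPE_TOL = 0.02                    # ng/ml per minute
DROP_SLOPE_TOL = 0.05
DROP_SETTLE_DELAY = 50.0                    # min after pulse end
FINAL_WINDOW_MIN = 10.0


@dataclass
class ScenarioResult:
    """Per-condition trajectories plus scalar summary metrics."""

    scenario: str
    conditions: list[dict]
    trajectories: dict[str, Trajectory]
    metrics: dict

    def condition_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.conditions)


def _final_total(traj: Trajectory) -> float:
    tot = total_pkc_series(traj)
    t_end = traj.protocol.t_end
    return float(tot[tot.index >= t_end - FINAL_WINDOW_MIN].mean())


def _peak(traj: Trajectory, name: str) -> float:
    return float(species_series(traj, name).max())


def _persistence(traj: Trajectory, name: str, frac: float = 0.5) -> float:
    """Time (min) a species spends above frac x its own peak."""
    s = species_series(traj, name)
    peak = s.max()
    if peak <= 0:
        return 0.0
    above = s.to_numpy() >= frac * peak
    t = s.index.to_numpy(dtype=float)
    return float(np.trapezoid(above.astype(float), t))


def _control(params: Parameterization, t_end: float,
             synthesis: Sequence[Pulse] = (SYNTHESIS_PULSE,),
             hsp70_multiplier: float = 1.0,
             variant: bool = False) -> Trajectory:
    proto = Protocol(t_end=t_end, synthesis_pulses=tuple(synthesis),
                     hsp70_multiplier=hsp70_multiplier)
    net = build_default_network(variant=variant)
    return simulate(net, params, proto)


def _params(params: Parameterization | None) -> Parameterization:
    return default_parameterization() if params is None else params


def run_dose_response(params: Parameterization | None = None) -> ScenarioResult:
    """Four activator intensities (0.0005-0.5 nM), 15-min pulse at 50 min,
    after the standard 10-min synthesis pulse."""
    p = _params(params)
    t_end = ACTIVATOR_ONSET + ACTIVATOR_DURATION + 120.0
    net = build_default_network()
    ctrl = _control(p, t_end)
    ctrl_final = _final_total(ctrl)
    plateau = plateau_value(total_pkc_series(ctrl), PLATEAU_WINDOW,
                            PLATEAU_SLOPE_TOL)
    trajs: dict[str, Trajectory] = {"control": ctrl}
    conditions = []
    for a in DOSE_AMPLITUDES:
        proto = Protocol(
            t_end=t_end,
            synthesis_pulses=(SYNTHESIS_PULSE,),
            activator_pulses=(Pulse(ACTIVATOR_ONSET, ACTIVATOR_DURATION, a),),
        )
        tr = simulate(net, p, proto)
        key = f"amp_{a:g}"
        trajs[key] = tr
        final = _final_total(tr)
        conditions.append({
            "condition": key,
            "amplitude_nM": a,
            "final_total": final,
            "retention": final / ctrl_final,
            "loss_fraction": 1.0 - final / ctrl_final,
            "peak_active_membrane": _peak(tr, "PKC_PAPHPT_act"),
            "peak_active_dephos": _peak(tr, "PKC_A"),
        })
    metrics = {
        "pre_pulse_plateau": plateau,
        "control_final": ctrl_final,
        "final_totals": [c["final_total"] for c in conditions],
        "retentions": [c["retention"] for c in conditions],
        "loss_lowest": conditions[0]["loss_fraction"],
        "loss_highest": conditions[-1]["loss_fraction"],
    }
    return ScenarioResult("fig2_dose", conditions, trajs, metrics)


def run_duration_sweep(params: Parameterization | None = None) -> ScenarioResult:
    """Low-intensity (0.0005 nM) activator pulses of increasing duration
    (15 to 316.66 min)."""
    p = _params(params)
    durations = (15.0, 100.0, 150.0, 200.0, 316.66)
    net = build_default_network()
    conditions = []
    trajs: dict[str, Trajectory] = {}
    for d in durations:
        t_end = ACTIVATOR_ONSET + d + 120.0
        proto = Protocol(
            t_end=t_end,
            synthesis_pulses=(SYNTHESIS_PULSE,),
            activator_pulses=(Pulse(ACTIVATOR_ONSET, d, 0.0005),),
        )
        tr = simulate(net, p, proto)
        ctrl = _control(p, t_end)
        key = f"dur_{d:g}"
        trajs[key] = tr
        final = _final_total(tr)
        ctrl_final = _final_total(ctrl)
        conditions.append({
            "condition": key,
            "duration_min": d,
            "final_total": final,
            "retention": final / ctrl_final,
            "loss_fraction": 1.0 - final / ctrl_final,
        })
    metrics = {
        "durations": list(durations),
        "retentions": [c["retention"] for c in conditions],
        "loss_shortest": conditions[0]["loss_fraction"],
        "loss_longest": conditions[-1]["loss_fraction"],
    }
    return ScenarioResult("fig3_duration", conditions, trajs, metrics)


def _fig4_pulses() -> tuple[Pulse, ...]:
    # three identical 0.5 nM pulses at 4,000 / 12,000 / 20,000 s
    return tuple(
        Pulse(t_s / 60.0, ACTIVATOR_DURATION, 0.5)
        for t_s in (4000.0, 12000.0, 20000.0)
    )


def run_block_dephosphorylation(
    params: Parameterization | None = None,
) -> ScenarioResult:
    """Three high-intensity pulses with the dephosphorylation rate k17
    completely blocked during each pulse, plus the unblocked contrast."""
    p = _params(params)
    pulses = _fig4_pulses()
    t_end = pulses[-1].t_off + 120.0
    net = build_default_network()
    blocked = simulate(net, p, Protocol(
        t_end=t_end,
        synthesis_pulses=(SYNTHESIS_PULSE,),
        activator_pulses=pulses,
        k17_block_windows=tuple((pu.t_on, pu.duration) for pu in pulses),
    ))
    unblocked = simulate(net, p, Protocol(
        t_end=t_end,
        synthesis_pulses=(SYNTHESIS_PULSE,),
        activator_pulses=pulses,
    ))
    ctrl = _control(p, t_end)
    ctrl_final = _final_total(ctrl)
    plateau = plateau_value(total_pkc_series(ctrl), PLATEAU_WINDOW,
                            PLATEAU_SLOPE_TOL)
    mature = species_series(blocked, "CPKC_PAPHPT")
    dips, recoveries = [], []
    for pu in pulses:
        pre = plateau_value(mature, (pu.t_on - 10.0, pu.t_on), DROP_SLOPE_TOL)
        dip = float(mature[(mature.index >= pu.t_on)
                           & (mature.index <= pu.t_off)].min())
        rec = float(mature[(mature.index >= pu.t_off + 20.0)
                           & (mature.index <= pu.t_off + 30.0)].mean())
        dips.append(pre - dip)
        recoveries.append(rec / pre)
    conditions = [
        {"condition": "blocked", "final_total": _final_total(blocked),
         "retention": _final_total(blocked) / ctrl_final},
        {"condition": "unblocked", "final_total": _final_total(unblocked),
         "retention": _final_total(unblocked) / ctrl_final},
    ]
    metrics = {
        "pre_pulse_plateau": plateau,
        "control_final": ctrl_final,
        "retention_blocked": conditions[0]["retention"],
        "retention_unblocked": conditions[1]["retention"],
        "mature_dips": dips,
        "mature_recovery_ratios": recoveries,
    }
    return ScenarioResult(
        "fig4_block_k17", conditions,
        {"blocked": blocked, "unblocked": unblocked, "control": ctrl},
        metrics)


def _fig5_pulses() -> tuple[Pulse, ...]:
    return tuple(
        Pulse(t_on, ACTIVATOR_DURATION, 0.005) for t_on in (50.0, 220.0, 360.0)
    )


def run_sequential_pulses(
    params: Parameterization | None = None,
) -> ScenarioResult:
    """Three sequential intermediate-strength (0.005 nM) pulses at 50, 220
    and 360 min; reports the stabilized-level drop caused by each pulse."""
    p = _params(params)
    pulses = _fig5_pulses()
    t_end = pulses[-1].t_off + 120.0
    net = build_default_network()
    tr = simulate(net, p, Protocol(
        t_end=t_end,
        synthesis_pulses=(SYNTHESIS_PULSE,),
        activator_pulses=pulses,
    ))
    tot = total_pkc_series(tr)
    drops = [
        drop_after_pulse(tot, pu, slope_tol=DROP_SLOPE_TOL,
                         settle_delay=DROP_SETTLE_DELAY)
        for pu in pulses
    ]
    conditions = [
        {"condition": f"pulse_{i + 1}", "t_on_min": pu.t_on, "drop": d}
        for i, (pu, d) in enumerate(zip(pulses, drops))
    ]
    metrics = {
        "drops": drops,
        "drop_pulse1": drops[0],
        "drop_pulse3": drops[2],
        "strictly_decreasing": bool(np.all(np.diff(drops) < 0)),
    }
    return ScenarioResult("fig5_sequential", conditions, {"stimulated": tr},
                          metrics)


def run_hsp70_sweep(params: Parameterization | None = None) -> ScenarioResult:
    """High-intensity (0.5 nM) stimulation under 1x to 200x HSP70
    overexpression."""
    p = _params(params)
    multipliers = (1.0, 10.0, 40.0, 100.0, 200.0)
    t_end = ACTIVATOR_ONSET + ACTIVATOR_DURATION + 120.0
    net = build_default_network()
    ctrl = _control(p, t_end)
    ctrl_final = _final_total(ctrl)
    conditions = []
    trajs: dict[str, Trajectory] = {"control": ctrl}
    for m in multipliers:
        proto = Protocol(
            t_end=t_end,
            synthesis_pulses=(SYNTHESIS_PULSE,),
            activator_pulses=(Pulse(ACTIVATOR_ONSET, ACTIVATOR_DURATION, 0.5),),
            hsp70_multiplier=m,
        )
        tr = simulate(net, p, proto)
        key = f"hsp70_{m:g}x"
        trajs[key] = tr
        final = _final_total(tr)
        conditions.append({
            "condition": key,
            "hsp70_multiplier": m,
            "final_total": final,
            "retention": final / ctrl_final,
            "peak_active_dephos": _peak(tr, "PKC_A"),
            "persistence_active_dephos": _persistence(tr, "PKC_A"),
        })
    metrics = {
        "multipliers": list(multipliers),
        "final_totals": [c["final_total"] for c in conditions],
        "retentions": [c["retention"] for c in conditions],
        "pkc_a_peaks": [c["peak_active_dephos"] for c in conditions],
        "pkc_a_persistence": [c["persistence_active_dephos"]
                              for c in conditions],
    }
    return ScenarioResult("fig6_hsp70", conditions, trajs, metrics)


def run_phlpp_block_sweep(
    params: Parameterization | None = None,
) -> ScenarioResult:
    """High-intensity stimulation with 0-100% blocking of the
    PHLPP-mediated dephosphorylation rate."""
    p = _params(params)
    fractions = (0.0, 0.5, 0.9, 0.95, 1.0)
    t_end = ACTIVATOR_ONSET + ACTIVATOR_DURATION + 120.0
    net = build_default_network()
    ctrl = _control(p, t_end)
    ctrl_final = _final_total(ctrl)
    conditions = []
    trajs: dict[str, Trajectory] = {"control": ctrl}
    for b in fractions:
        proto = Protocol(
            t_end=t_end,
            synthesis_pulses=(SYNTHESIS_PULSE,),
            activator_pulses=(Pulse(ACTIVATOR_ONSET, ACTIVATOR_DURATION, 0.5),),
            phlpp_block_fraction=b,
        )
        tr = simulate(net, p, proto)
        key = f"block_{b:g}"
        trajs[key] = tr
        final = _final_total(tr)
        conditions.append({
            "condition": key,
            "block_fraction": b,
            "final_total": final,
            "retention": final / ctrl_final,
            "persistence_active_membrane": _persistence(tr, "PKC_PAPHPT_act"),
        })
    metrics = {
        "fractions": list(fractions),
        "final_totals": [c["final_total"] for c in conditions],
        "retentions": [c["retention"] for c in conditions],
    }
    return ScenarioResult("fig7_phlpp", conditions, trajs, metrics)


def run_second_synthesis_pulse(
    params: Parameterization | None = None,
) -> ScenarioResult:
    """Dose-response protocol plus a second 10-min synthesis pulse at
    83.33 min, testing reversal of down-regulation by new synthesis.

    The degree of reversal is the restoration completeness: final total
    with the second pulse divided by the final total of a double-synthesis
    control that received no activator.
    """
    p = _params(params)
    second = Pulse(83.33, 10.0)
    t_end = second.t_off + 120.0
    net = build_default_network()
    ctrl2 = _control(p, t_end, synthesis=(SYNTHESIS_PULSE, second))
    ctrl2_final = _final_total(ctrl2)
    conditions = []
    trajs: dict[str, Trajectory] = {"control_double_synthesis": ctrl2}
    for a in DOSE_AMPLITUDES:
        act = (Pulse(ACTIVATOR_ONSET, ACTIVATOR_DURATION, a),)
        with2 = simulate(net, p, Protocol(
            t_end=t_end, synthesis_pulses=(SYNTHESIS_PULSE, second),
            activator_pulses=act))
        without = simulate(net, p, Protocol(
            t_end=t_end, synthesis_pulses=(SYNTHESIS_PULSE,),
            activator_pulses=act))
        key = f"amp_{a:g}"
        trajs[key] = with2
        f2, f1 = _final_total(with2), _final_total(without)
        conditions.append({
            "condition": key,
            "amplitude_nM": a,
            "final_with_second_pulse": f2,
            "final_without_second_pulse": f1,
            "reversal_gain": f2 - f1,
            "degree_of_reversal": f2 / ctrl2_final,
        })
    metrics = {
        "amplitudes": list(DOSE_AMPLITUDES),
        "degrees_of_reversal": [c["degree_of_reversal"] for c in conditions],
        "reversal_gains": [c["reversal_gain"] for c in conditions],
    }
    return ScenarioResult("s7_second_synthesis", conditions, trajs, metrics)


def run_dual_degradation_variant(
    params: Parameterization | None = None,
    lam5: float = 2.0e-4,
) -> ScenarioResult:
    """Dose-response under the dual-degradation variant, where the
    membrane-active phospho form is also degraded directly (rate lam5)."""
    p = _params(params).with_(lam5=lam5)
    base = run_dose_response(_params(params))
    t_end = ACTIVATOR_ONSET + ACTIVATOR_DURATION + 120.0
    net = build_default_network(variant=True)
    ctrl = _control(p, t_end, variant=True)
    ctrl_final = _final_total(ctrl)
    conditions = []
    trajs: dict[str, Trajectory] = {"control": ctrl}
    for a, base_cond in zip(DOSE_AMPLITUDES, base.conditions):
        proto = Protocol(
            t_end=t_end,
            synthesis_pulses=(SYNTHESIS_PULSE,),
            activator_pulses=(Pulse(ACTIVATOR_ONSET, ACTIVATOR_DURATION, a),),
        )
        tr = simulate(net, p, proto)
        key = f"amp_{a:g}"
        trajs[key] = tr
        final = _final_total(tr)
        conditions.append({
            "condition": key,
            "amplitude_nM": a,
            "final_total": final,
            "retention": final / ctrl_final,
            "base_final_total": base_cond["final_total"],
        })
    metrics = {
        "lam5": lam5,
        "final_totals": [c["final_total"] for c in conditions],
        "base_final_totals": [c["base_final_total"] for c in conditions],
        "retentions": [c["retention"] for c in conditions],
    }
    return ScenarioResult("s8_dual_degradation", conditions, trajs, metrics)


SCENARIOS: dict[str, Callable[..., ScenarioResult]] = {
    "fig2_dose": run_dose_response,
    "fig3_duration": run_duration_sweep,
    "fig4_block_k17": run_block_dephosphorylation,
    "fig5_sequential": run_sequential_pulses,
    "fig6_hsp70": run_hsp70_sweep,
    "fig7_phlpp": run_phlpp_block_sweep,
    "s7_second_synthesis": run_second_synthesis_pulse,
    "s8_dual_degradation": run_dual_degradation_variant,
}


def run_scenario(name: str,
                 params: Parameterization | None = None) -> ScenarioResult:
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    return SCENARIOS[name](params)
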