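"""Reduced-system assays: isolated-subsystem measurements on the model.

These run the same integrator as the full scenarios but on stripped-down
parameterizations (single reactions or the autophosphorylation pair alone),
providing end-to-end checks that the shipped rate constants act as
declared: first-order decay rates recovered from log-linear fits, the
isolated autophosphorylation conversion half-time, and the maturation
half-time of the full constitutive cascade.
"""

from __future__ import annotations

import numpy as np

from .network import Parameterization, build_default_network, SPECIES_NAMES
from .protocols import Protocol, Pulse
from .simulate import half_time, simulate, species_series, total_pkc_series

__all__ = [
    "isolated_decay_rate",
    "isolated_autophosphorylation_half_time",
    "maturation_half_time",
]

_ZERO_RATES = dict(
    k1=0.0, k2=0.0, k3=0.0, k4=0.0, k5=0.0, k6=0.0, k7=0.0, k8=0.0,
    k9=0.0, k10=0.0, k11=0.0, k12=0.0, k13=0.0, k14=0.0, k15=0.0,
    k16=0.0, k17=0.0, k18=0.0, k19=0.0, k20=0.0,
    lam1=0.0, lam2=0.0, lam3=0.0, lam4=0.0, lam5=0.0,
)

_DECAY_SPECIES = {"naive": ("PKC", "lam1"), "mature": ("CPKC_PAPHPT", "lam4")}


def _only(params: Parameterization, **keep: float) -> Parameterization:
    d = params.to_dict()
    d.update(_ZERO_RATES)
    d.update(keep)
    return Parameterization.from_dict(d)


def isolated_decay_rate(
    params: Parameterization,
    which: str = "naive",
    p0: float = 10.0,
    n_half_lives: float = 3.0,
) -> float:
    """Simulate isolated first-order decay of the naive or the mature
    species and recover the rate (s^-1) as the log-linear slope.

    Runs the full simulator with every other reaction switched off, so the
    result verifies the shipped degradation constant end-to-end.
    """
    species, rate_id = _DECAY_SPECIES[which]
    rate = params.get(rate_id)
    p = _only(params, **{rate_id: rate})
    t_end_min = n_half_lives * np.log(2.0) / rate / 60.0
    y0 = np.zeros(len(SPECIES_NAMES))
    y0[SPECIES_NAMES.index(species)] = p0
    traj = simulate(build_default_network(), p,
                    Protocol(t_end=t_end_min), y0=y0,
                    output_dt=t_end_min / 200.0)
    s = species_series(traj, species)
    t_s = s.index.to_numpy(dtype=float) * 60.0
    slope = np.polyfit(t_s, np.log(s.to_numpy(dtype=float)), 1)[0]
    return float(-slope)


def isolated_autophosphorylation_half_time(
    params: Parameterization,
    pool: float = 73.0,
) -> float:
    """Half-conversion time (min) of the isolated autophosphorylation
    subsystem: the full pool initialized as the mTORC2-bound
    activation-loop-phosphorylated form, with only the seeding (R7) and
    mature-catalysed (R8) steps active."""
    p = _only(
        params,
        k9=params.k9, k10=params.k10, k11=params.k11,
        k12=params.k12, k13=params.k13, k14=params.k14,
    )
    y0 = np.zeros(len(SPECIES_NAMES))
    y0[SPECIES_NAMES.index("CPKC_PA")] = pool
    traj = simulate(build_default_network(), p, Protocol(t_end=60.0),
                    y0=y0, output_dt=0.05)
    mature = species_series(traj, "CPKC_PAPHPT")
    return half_time(mature, 0.5, plateau=pool)


def maturation_half_time(params: Parameterization) -> float:
    """Time (min) from synthesis-pulse onset for the mature pool to reach
    half of its level at the end of the constitutive phase (50 min)."""
    traj = simulate(build_default_network(), params,
                    Protocol(t_end=50.0, synthesis_pulses=(Pulse(0.0, 10.0),)))
    mature = species_series(traj, "CPKC_PAPHPT")
    return half_time(mature, 0.5, plateau=float(mature.iloc[-1]))
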