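"""Stimulation and intervention schedules.

A Protocol is a timeline of square pulses and constant interventions:

* synthesis pulses gate the translation signal k3 (a 10-min pulse mimics
  the upstream protein-synthesis cascade; the transcript itself is not
  modelled beyond its loading cycle),
* activator pulses set the clamped second-messenger level (Ca2+/DAG or
  PMA; agonist identity is encoded purely by the pulse amplitude in nM),
* k17 block windows switch the PHLPP-mediated dephosphorylation rate to
  zero inside the window (active-site protection experiments),
* phlpp_block_fraction scales k17 down for the whole run (phosphatase
  knock-down), and
* hsp70_multiplier scales the chemostatted HSP70 level (overexpression).

All protocol times are minutes; pulse membership uses the half-open
convention [t_on, t_on + duration).  Resolution is piecewise-constant, so
the integrator restarts at every pulse/window edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pulse",
    "Protocol",
    "ProtocolError",
    "k3_at",
    "activator_at",
    "k17_eff_at",
    "hsp70_at",
]


class ProtocolError(ValueError):
    """Invalid protocol definition."""


@dataclass(frozen=True)
class Pulse:
    """A square pulse: onset time and duration in minutes, amplitude in the
    target quantity's unit (nM for the activator; the synthesis pulse uses
    amplitude 1.0 as an on/off gate for k3)."""

    t_on: float
    duration: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ProtocolError("pulse duration must be > 0")
        if self.t_on < 0:
            raise ProtocolError("pulse onset must be >= 0")
        if self.amplitude < 0:
            raise ProtocolError("pulse amplitude must be >= 0")

    @property
    def t_off(self) -> float:
        return self.t_on + self.duration

    def covers(self, t: float) -> bool:
        return self.t_on <= t < self.t_off


@dataclass(frozen=True)
class Protocol:
    """Timeline of pulses and interventions over [0, t_end] minutes."""

    t_end: float
    synthesis_pulses: tuple[Pulse, ...] = ()
    activator_pulses: tuple[Pulse, ...] = ()
    k17_block_windows: tuple[tuple[float, float], ...] = ()
    phlpp_block_fraction: float = 0.0
    hsp70_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ProtocolError("t_end must be > 0")
        object.__setattr__(
            self, "synthesis_pulses",
            tuple(sorted(self.synthesis_pulses, key=lambda p: p.t_on)))
        object.__setattr__(
            self, "activator_pulses",
            tuple(sorted(self.activator_pulses, key=lambda p: p.t_on)))
        object.__setattr__(
            self, "k17_block_windows",
            tuple(sorted((float(a), float(b))
                         for a, b in self.k17_block_windows)))
        for a, b in self.k17_block_windows:
            if b <= 0 or a < 0 or a + b > self.t_end:
                raise ProtocolError(
                    "k17 block windows must lie within [0, t_end]")
        for prev, nxt in zip(self.activator_pulses, self.activator_pulses[1:]):
            if nxt.t_on < prev.t_off:
                raise ProtocolError(
                    f"overlapping activator pulses at t={nxt.t_on} min")
        if not 0.0 <= self.phlpp_block_fraction <= 1.0:
            raise ProtocolError("phlpp_block_fraction must be in [0, 1]")
        if self.hsp70_multiplier < 0:
            raise ProtocolError("hsp70_multiplier must be >= 0")

    def discontinuity_times(self) -> np.ndarray:
        """Sorted unique pulse/window edges in (0, t_end), minutes."""
        edges: set[float] = set()
        for p in self.synthesis_pulses + self.activator_pulses:
            edges.update((p.t_on, p.t_off))
        for a, b in self.k17_block_windows:
            edges.update((a, a + b))
        return np.array(sorted(e for e in edges if 0.0 < e < self.t_end))


def k3_at(t: float, protocol: Protocol, params) -> float:
    """Effective translation signal (s^-1): k3 inside a synthesis pulse,
    0 outside."""
    for p in protocol.synthesis_pulses:
        if p.covers(t):
            return params.k3
    return 0.0


def activator_at(t: float, protocol: Protocol) -> float:
    """Clamped second-messenger level (nM) at time t (minutes)."""
    for p in protocol.activator_pulses:
        if p.covers(t):
            return p.amplitude
    return 0.0


def k17_eff_at(t: float, protocol: Protocol, params) -> float:
    """Effective dephosphorylation rate (s^-1).

    The PHLPP level is folded into the pseudo-first-order constant k17;
    fractional PHLPP blocking and the transient full-block windows both act
    here: k17 * (1 - block_fraction) * gate(t).
    """
    for a, b in protocol.k17_block_windows:
        if a <= t < a + b:
            return 0.0
    return params.k17 * (1.0 - protocol.phlpp_block_fraction)


def hsp70_at(protocol: Protocol, params) -> float:
    """Chemostatted HSP70 level, constant over the run."""
    return params.HSP70 * protocol.hsp70_multiplier
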