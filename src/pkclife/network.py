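"""Reaction network for the PKC life-cycle model.

The model tracks a single pool of conventional/novel protein kinase C (PKC)
through its life cycle: de-novo synthesis from a polyribosome-loaded
transcript, PDK1-mediated activation-loop phosphorylation, mTORC2 binding,
autophosphorylation of the turn and hydrophobic motifs, second-messenger
(Ca2+/DAG or PMA) activation at the membrane, PHLPP-mediated
dephosphorylation, degradation of the dephosphorylated-but-active form, and
HSP70-mediated rescue back into the mature pool.

Twelve dynamical species are integrated; six partner species (polyribosome
T, PDK1, mTORC2, the activator, PHLPP and HSP70) are chemostatted: they
enter rate laws at protocol-defined levels but are never integrated, so the
maturation and rescue reactions do not deplete their partners.

All rates follow the law of mass action.  Time is integrated in seconds;
protein species are expressed in ng/ml and the activator in nM, with
bimolecular constants carrying the reciprocal unit of their partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "ElementaryStep",
    "Reaction",
    "Parameterization",
    "ReactionNetwork",
    "build_default_network",
    "mass_action_flux",
    "rhs",
    "conserved_moiety_total",
    "SPECIES_NAMES",
    "CLAMPED_NAMES",
    "MOIETY_COUNTS",
]

# Dynamical state ordering (StateVector layout).
SPECIES_NAMES: tuple[str, ...] = (
    "PKC_mRNA",       # transcript
    "C1",             # polyribosome-loaded transcript
    "PKC",            # naive, unphosphorylated enzyme
    "C2",             # PKC:PDK1 encounter complex
    "PKC_PA",         # phosphorylated at the activation loop
    "CPKC_PA",        # mTORC2-bound, activation-loop phosphorylated
    "C3",             # autophosphorylation seeding dimer
    "C4",             # mature-catalysed autophosphorylation complex
    "CPKC_PAPHPT",    # mature: P_A + P_H + P_T, stored in cytosol
    "PKC_PAPHPT_act", # activator-bound, fully phosphorylated, at membrane
    "PKC_A",          # dephosphorylated but active, degradation-prone
    "C5",             # HSP70 rescue complex (PKC_A : CPKC_PAPHPT : HSP70)
)

# Number of PKC protein moieties carried by each dynamical species.
MOIETY_COUNTS: np.ndarray = np.array(
    [0, 0, 1, 1, 1, 1, 2, 2, 1, 1, 1, 2], dtype=float
)

CLAMPED_NAMES: tuple[str, ...] = ("T", "PDK1", "MTORC2", "ACT", "PHLPP", "HSP70")

_IDX = {name: i for i, name in enumerate(SPECIES_NAMES)}


@dataclass(frozen=True)
class Species:
    """A chemical species of the network.

    kind is "dynamical" (integrated) or "clamped" (chemostatted level that
    enters rate laws only).  pkc_moiety_count is the number of PKC protein
    moieties the species carries (0, 1 or 2).
    """

    name: str
    kind: str
    unit: str
    pkc_moiety_count: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("dynamical", "clamped"):
            raise ValueError(f"unknown species kind {self.kind!r}")
        if self.pkc_moiety_count not in (0, 1, 2):
            raise ValueError("pkc_moiety_count must be 0, 1 or 2")


@dataclass(frozen=True)
class ElementaryStep:
    """One irreversible mass-action step.

    reactants / products map dynamical species names to positive integer
    stoichiometric coefficients; modifiers lists clamped species whose
    (protocol-resolved) levels multiply the rate law.
    """

    id: str
    rate_constant_id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    modifiers: tuple[str, ...] = ()


@dataclass(frozen=True)
class Reaction:
    """A reaction of the printed scheme (R1..R12, RM), grouping its
    elementary forward / reverse / catalytic-release steps."""

    id: str
    steps: tuple[ElementaryStep, ...]

    @property
    def rate_constant_ids(self) -> tuple[str, ...]:
        return tuple(s.rate_constant_id for s in self.steps)


# Rate-constant ids, in declaration order of Parameterization.
_SECOND_ORDER = {"k1", "k4", "k7", "k9", "k12", "k15", "k18"}


@dataclass(frozen=True)
class Parameterization:
    """Numeric parameter set of the life-cycle model.

    First-order constants are s^-1; second-order constants (k1, k4, k7, k9,
    k12, k15, k18) are per concentration-unit of the partner per second
    (k15 per nM of activator, the others per ng/ml).  T, PDK1, MTORC2,
    PHLPP and HSP70 are chemostatted levels; mRNA0 is the initial
    transcript concentration.  lam5 is the optional direct degradation of
    the membrane-active phospho form (dual-degradation variant; 0 in the
    base model).
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    k9: float
    k10: float
    k11: float
    k12: float
    k13: float
    k14: float
    k15: float
    k16: float
    k17: float
    k18: float
    k19: float
    k20: float
    lam1: float
    lam2: float
    lam3: float
    lam4: float
    lam5: float = 0.0
    T: float = 1.0
    PDK1: float = 1.0
    MTORC2: float = 1.0
    PHLPP: float = 1.0
    HSP70: float = 1.0
    mRNA0: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"parameter {f.name} must be finite and >= 0, got {v!r}"
                )

    def get(self, pid: str) -> float:
        if not hasattr(self, pid):
            raise KeyError(f"unknown rate constant or level {pid!r}")
        return float(getattr(self, pid))

    def with_(self, **kwargs: float) -> "Parameterization":
        return replace(self, **kwargs)

    def clamped_levels(self) -> dict[str, float]:
        return {
            "T": self.T,
            "PDK1": self.PDK1,
            "MTORC2": self.MTORC2,
            "PHLPP": self.PHLPP,
            "HSP70": self.HSP70,
        }

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "Parameterization":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


def _step(
    sid: str,
    k: str,
    reac: Sequence[tuple[str, int]],
    prod: Sequence[tuple[str, int]],
    mods: Sequence[str] = (),
) -> ElementaryStep:
    return ElementaryStep(sid, k, tuple(reac), tuple(prod), tuple(mods))


def _default_reactions(variant: bool) -> tuple[Reaction, ...]:
    R = [
        Reaction("R1", (
            _step("R1f", "k1", [("PKC_mRNA", 1)], [("C1", 1)], ["T"]),
            _step("R1r", "k2", [("C1", 1)], [("PKC_mRNA", 1)]),
        )),
        # translation: loaded transcript releases polyribosome and transcript
        Reaction("R2", (
            _step("R2", "k3", [("C1", 1)], [("PKC", 1), ("PKC_mRNA", 1)]),
        )),
        Reaction("R3", (
            _step("R3", "lam1", [("PKC", 1)], []),
        )),
        Reaction("R4", (
            _step("R4f", "k4", [("PKC", 1)], [("C2", 1)], ["PDK1"]),
            _step("R4r", "k5", [("C2", 1)], [("PKC", 1)]),
            _step("R4c", "k6", [("C2", 1)], [("PKC_PA", 1)]),
        )),
        Reaction("R5", (
            _step("R5f", "k7", [("PKC_PA", 1)], [("CPKC_PA", 1)], ["MTORC2"]),
            _step("R5r", "k8", [("CPKC_PA", 1)], [("PKC_PA", 1)]),
        )),
        Reaction("R6", (
            _step("R6", "lam2", [("PKC_PA", 1)], []),
        )),
        Reaction("R7", (
            _step("R7f", "k9", [("CPKC_PA", 2)], [("C3", 1)]),
            _step("R7r", "k10", [("C3", 1)], [("CPKC_PA", 2)]),
            _step("R7c", "k11", [("C3", 1)],
                  [("CPKC_PAPHPT", 1), ("CPKC_PA", 1)]),
        )),
        Reaction("R8", (
            _step("R8f", "k12", [("CPKC_PAPHPT", 1), ("CPKC_PA", 1)],
                  [("C4", 1)]),
            _step("R8r", "k13", [("C4", 1)],
                  [("CPKC_PAPHPT", 1), ("CPKC_PA", 1)]),
            _step("R8c", "k14", [("C4", 1)], [("CPKC_PAPHPT", 2)]),
        )),
        Reaction("R9", (
            _step("R9f", "k15", [("CPKC_PAPHPT", 1)],
                  [("PKC_PAPHPT_act", 1)], ["ACT"]),
            _step("R9r", "k16", [("PKC_PAPHPT_act", 1)],
                  [("CPKC_PAPHPT", 1)]),
        )),
        Reaction("R10", (
            _step("R10", "k17", [("PKC_PAPHPT_act", 1)], [("PKC_A", 1)]),
        )),
        Reaction("R11", (
            _step("R11", "lam3", [("PKC_A", 1)], []),
        )),
        Reaction("R12", (
            _step("R12f", "k18", [("CPKC_PAPHPT", 1), ("PKC_A", 1)],
                  [("C5", 1)], ["HSP70"]),
            _step("R12r", "k19", [("C5", 1)],
                  [("CPKC_PAPHPT", 1), ("PKC_A", 1)]),
            _step("R12c", "k20", [("C5", 1)], [("CPKC_PAPHPT", 2)]),
        )),
        Reaction("RM", (
            _step("RM", "lam4", [("CPKC_PAPHPT", 1)], []),
        )),
    ]
    if variant:
        # dual-degradation variant: the membrane-active phospho form is a
        # second, competing degradation route
        R.append(Reaction("RMA", (
            _step("RMA", "lam5", [("PKC_PAPHPT_act", 1)], []),
        )))
    return tuple(R)


class ReactionNetwork:
    """Species registry + reaction list + precompiled stoichiometry.

    The right-hand side is assembled generically as S @ v(y) from the
    per-step reactant orders and the stoichiometry matrix; clamped species
    contribute constant factors folded into an effective rate vector per
    protocol segment (see :func:`pkclife.simulate.simulate`).
    """

    def __init__(self, reactions: Sequence[Reaction], variant: bool = False):
        self.variant = bool(variant)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.species: tuple[Species, ...] = tuple(
            Species(n, "dynamical",
                    "nM" if n == "ACT" else "ng/ml",
                    int(MOIETY_COUNTS[i]))
            for i, n in enumerate(SPECIES_NAMES)
        ) + tuple(
            Species(n, "clamped", "nM" if n == "ACT" else "ng/ml", 0)
            for n in CLAMPED_NAMES
        )
        self.steps: tuple[ElementaryStep, ...] = tuple(
            s for r in self.reactions for s in r.steps
        )
        n_sp, n_st = len(SPECIES_NAMES), len(self.steps)
        self.reactant_orders = np.zeros((n_st, n_sp))
        self.stoichiometry_matrix = np.zeros((n_sp, n_st))
        for j, st in enumerate(self.steps):
            for name, coef in st.reactants:
                self.reactant_orders[j, _IDX[name]] += coef
                self.stoichiometry_matrix[_IDX[name], j] -= coef
            for name, coef in st.products:
                self.stoichiometry_matrix[_IDX[name], j] += coef
        self.rate_constant_ids: tuple[str, ...] = tuple(
            s.rate_constant_id for s in self.steps
        )
        self.step_index = {s.id: j for j, s in enumerate(self.steps)}

    @property
    def n_species(self) -> int:
        return len(SPECIES_NAMES)

    @property
    def dynamical_species(self) -> tuple[Species, ...]:
        return self.species[: self.n_species]

    @property
    def clamped_species(self) -> tuple[Species, ...]:
        return self.species[self.n_species:]

    def step(self, sid: str) -> ElementaryStep:
        return self.steps[self.step_index[sid]]

    def moiety_delta(self, reaction: Reaction | str) -> int:
        """Net change in PKC protein moieties per firing of the reaction's
        defining (forward/catalytic) direction; 0 for any balanced group."""
        if isinstance(reaction, str):
            reaction = next(r for r in self.reactions if r.id == reaction)
        deltas = set()
        for st in reaction.steps:
            d = sum(c * MOIETY_COUNTS[_IDX[n]] for n, c in st.products) - sum(
                c * MOIETY_COUNTS[_IDX[n]] for n, c in st.reactants
            )
            deltas.add(int(d))
        # reverse steps mirror their forward step; report the extreme
        return max(deltas, key=abs)

    def rate_vector(
        self,
        params: Parameterization,
        *,
        k3_eff: float | None = None,
        k17_eff: float | None = None,
        act: float = 0.0,
        hsp70: float | None = None,
    ) -> np.ndarray:
        """Effective per-step rate constants with clamped levels and
        time-dependent controls folded in.

        k3_eff / k17_eff default to the bare constants; act is the activator
        level (nM); hsp70 defaults to the baseline level.
        """
        clamped = params.clamped_levels()
        clamped["ACT"] = float(act)
        if hsp70 is not None:
            clamped["HSP70"] = float(hsp70)
        rates = np.empty(len(self.steps))
        for j, st in enumerate(self.steps):
            pid = st.rate_constant_id
            if pid == "k3" and k3_eff is not None:
                k = k3_eff
            elif pid == "k17" and k17_eff is not None:
                k = k17_eff
            else:
                k = params.get(pid)
            for m in st.modifiers:
                k *= clamped[m]
            rates[j] = k
        return rates

    def flux_vector(self, rates: np.ndarray, y: np.ndarray) -> np.ndarray:
        v = rates.copy()
        for j in range(len(self.steps)):
            for i in np.nonzero(self.reactant_orders[j])[0]:
                v[j] *= y[i] ** self.reactant_orders[j, i]
        return v

    def rhs_from_rates(self, rates: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.stoichiometry_matrix @ self.flux_vector(rates, y)

    def jacobian_from_rates(self, rates: np.ndarray, y: np.ndarray) -> np.ndarray:
        n_st, n_sp = self.reactant_orders.shape
        dv = np.zeros((n_st, n_sp))
        for j in range(n_st):
            nz = np.nonzero(self.reactant_orders[j])[0]
            for i in nz:
                d = rates[j] * self.reactant_orders[j, i]
                for i2 in nz:
                    o = self.reactant_orders[j, i2] - (1.0 if i2 == i else 0.0)
                    if o:
                        d *= y[i2] ** o
                dv[j, i] = d
        return self.stoichiometry_matrix @ dv

    def to_dict(self) -> dict:
        """Structured-text serialization of the network definition."""
        return {
            "variant": self.variant,
            "species": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "unit": s.unit,
                    "pkc_moiety_count": s.pkc_moiety_count,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "id": r.id,
                    "steps": [
                        {
                            "id": st.id,
                            "rate_constant": st.rate_constant_id,
                            "reactants": [list(t) for t in st.reactants],
                            "products": [list(t) for t in st.products],
                            "modifiers": list(st.modifiers),
                        }
                        for st in r.steps
                    ],
                }
                for r in self.reactions
            ],
        }


def build_default_network(variant: bool = False) -> ReactionNetwork:
    """The 13-reaction PKC life-cycle network (R1-R12 plus the mature-form
    degradation RM); variant=True appends the competing degradation of the
    membrane-active phospho form (rate lam5)."""
    return ReactionNetwork(_default_reactions(variant), variant=variant)


def mass_action_flux(
    step: ElementaryStep,
    state: np.ndarray | Mapping[str, float],
    params: Parameterization,
    clamped_levels: Mapping[str, float] | None = None,
) -> float:
    """Mass-action flux of one elementary step (concentration per second):
    rate constant x product of reactant concentrations raised to their
    stoichiometric coefficients x clamped modifier levels."""
    levels = dict(params.clamped_levels())
    levels.setdefault("ACT", 0.0)
    if clamped_levels:
        levels.update(clamped_levels)
    k = params.get(step.rate_constant_id)
    for m in step.modifiers:
        k *= levels[m]
    if isinstance(state, Mapping):
        y = np.array([state.get(n, 0.0) for n in SPECIES_NAMES])
    else:
        y = np.asarray(state, dtype=float)
    for name, coef in step.reactants:
        k *= y[_IDX[name]] ** coef
    return float(k)


def rhs(t, state, params, protocol, network: ReactionNetwork | None = None):
    """ODE right-hand side at time t (seconds) under a protocol.

    Derivative of each dynamical species = sum over reactions of
    stoichiometry x flux, with the protocol supplying the time-dependent
    effective parameters (synthesis gate k3(t), activator level ACT(t),
    dephosphorylation rate k17_eff(t), HSP70 level).
    """
    from .protocols import activator_at, hsp70_at, k3_at, k17_eff_at

    if network is None:
        network = build_default_network(variant=params.lam5 > 0)
    t_min = t / 60.0
    rates = network.rate_vector(
        params,
        k3_eff=k3_at(t_min, protocol, params),
        k17_eff=k17_eff_at(t_min, protocol, params),
        act=activator_at(t_min, protocol),
        hsp70=hsp70_at(protocol, params),
    )
    return network.rhs_from_rates(rates, np.asarray(state, dtype=float))


def conserved_moiety_total(state: np.ndarray) -> float | np.ndarray:
    """Total PKC enzyme (ng/ml): moiety-weighted sum over dynamical species.

    This is the quantity plotted as "Total PKC" in all scenarios; it is
    conserved by every reaction except synthesis (R2) and the degradation
    reactions (R3, R6, R11, RM, variant RMA).
    """
    state = np.asarray(state, dtype=float)
    return state @ MOIETY_COUNTS


def initial_state(params: Parameterization) -> np.ndarray:
    """Basal state: transcript at mRNA0, every protein species at zero."""
    y0 = np.zeros(len(SPECIES_NAMES))
    y0[_IDX["PKC_mRNA"]] = params.mRNA0
    return y0
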