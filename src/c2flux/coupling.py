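"""Coupling of the mechanistic state to the stoichiometric model.

The mechanistic model fixes net CO2 uptake, Rubisco carboxylation and
oxygenation in both cells, bundle-sheath CO2 leakage, mesophyll PEPC and
bundle-sheath NADP-ME activity as (tightly banded) equality constraints,
and imposes the photorespiratory-pump lower bounds

    v_min,Gly = ξ·V_om,  v_min,Ser = 0.5·ξ·V_om,  v_min,GDC = 0.5·ξ·V_om

on glycine diffusion (M→BS), serine diffusion (BS→M) and the
bundle-sheath GDC reaction.  A scenario additionally closes selected
plasmodesmatal transports and sets the MTF weight on the remaining ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from .mechanistic import MechanisticState, photorespiratory_bounds
from .model import BIG, StoichiometricModel
from .network import DEFAULT_PLASMODESMATAL_WEIGHT, transport_id

#: half-width of the equality band used for mechanistic constraints
EQUALITY_BAND = 1e-6

#: friendly metabolite names accepted in scenario definitions
SPECIES_ALIASES = {
    "2-oxoglutarate": "og", "alpha-ketoglutarate": "og", "2-og": "og",
    "glutamate": "glu", "glutamine": "gln", "asparagine": "asn",
    "aspartate": "asp", "alanine": "ala", "threonine": "thr",
    "pyruvate": "pyr", "malate": "mal", "serine": "ser", "glycine": "gly",
    "3-pga": "pga", "3-phosphoglycerate": "pga", "sucrose": "suc",
    "triose-phosphate": "tp", "phosphate": "pi", "water": "h2o",
}


def canonical_species(name: str) -> str:
    key = name.strip().lower()
    return SPECIES_ALIASES.get(key, key)


@dataclass(frozen=True)
class ScenarioSpec:
    """Which transports are blocked, the C4 activity, and the MTF weight."""

    name: str
    blocked_transports: FrozenSet[str] = frozenset()
    c4_activity: float = 0.0
    plasmodesmatal_weight: float = DEFAULT_PLASMODESMATAL_WEIGHT

    def __post_init__(self) -> None:
        blocked = frozenset(canonical_species(s) for s in self.blocked_transports)
        object.__setattr__(self, "blocked_transports", blocked)
        if blocked & {"gly", "ser"}:
            raise ValueError(
                "glycine and serine transport cannot be blocked: "
                "they carry the C2 cycle itself"
            )
        if self.c4_activity < 0:
            raise ValueError("C4 activity must be non-negative")
        if self.plasmodesmatal_weight < 0:
            raise ValueError("plasmodesmatal weight must be non-negative")

    def with_weight(self, weight: float) -> "ScenarioSpec":
        return ScenarioSpec(self.name, self.blocked_transports, self.c4_activity, weight)

    def with_c4_activity(self, vp: float) -> "ScenarioSpec":
        return ScenarioSpec(self.name, self.blocked_transports, vp, self.plasmodesmatal_weight)


#: progressive blocking of N-return carriers: B closes the Glu/2-OG pair,
#: C additionally Ala/Pyr, D additionally every remaining N carrier other
#: than glycine/serine (nested sets A ⊂ B ⊂ C ⊂ D)
_SCENARIO_BLOCKS: Dict[str, FrozenSet[str]] = {
    "A": frozenset(),
    "B": frozenset({"og", "glu"}),
    "C": frozenset({"og", "glu", "ala", "pyr"}),
    "D": frozenset({"og", "glu", "ala", "pyr", "gln", "asn", "thr", "asp"}),
}

DEFAULT_C4_ACTIVITY = 2.0


def make_scenario(name: str) -> ScenarioSpec:
    """Named setups: the four C2 transport scenarios plus the C4 variant."""
    key = name.strip().upper()
    if key in _SCENARIO_BLOCKS:
        return ScenarioSpec(name=key, blocked_transports=_SCENARIO_BLOCKS[key])
    if key == "C4":
        return ScenarioSpec(name="C4", c4_activity=DEFAULT_C4_ACTIVITY)
    raise ValueError(f"unknown scenario {name!r} (expected A, B, C, D or C4)")


@dataclass
class ConstraintAssignment:
    reaction_id: str
    lower: float
    upper: float
    provenance: str


@dataclass
class ConstraintSet:
    assignments: List[ConstraintAssignment] = field(default_factory=list)

    def add(self, rid: str, lower: float, upper: float, provenance: str) -> None:
        if lower > upper:
            raise ValueError(f"{rid}: lower {lower} exceeds upper {upper}")
        self.assignments.append(ConstraintAssignment(rid, lower, upper, provenance))

    def tsv(self) -> str:
        lines = ["reaction\tlower\tupper\tprovenance"]
        for a in self.assignments:
            lines.append(f"{a.reaction_id}\t{a.lower:.10g}\t{a.upper:.10g}\t{a.provenance}")
        return "\n".join(lines) + "\n"


#: reaction ids the coupler needs to find in the target model
REQUIRED_REACTIONS = (
    "ex_co2_m", "rbc_m", "rbo_m", "rbc_bs", "rbo_bs",
    "pepc_m", "me_bs", "gdc_bs",
    transport_id("co2"), transport_id("gly"), transport_id("ser"),
)


def build_constraint_set(state: MechanisticState, scenario: ScenarioSpec) -> ConstraintSet:
    """Translate a mechanistic state + scenario into bound assignments."""
    cs = ConstraintSet()
    b = EQUALITY_BAND

    def eq(rid: str, value: float, source: str) -> None:
        cs.add(rid, value - b, value + b, source)

    eq("ex_co2_m", state.A_net, "A_net (net CO2 uptake)")
    eq("rbc_m", state.V_cm, "V_cm (mesophyll carboxylation)")
    eq("rbo_m", state.V_om, "V_om (mesophyll oxygenation)")
    eq("rbc_bs", state.V_cbs, "V_cbs (bundle-sheath carboxylation)")
    eq("rbo_bs", state.V_obs, "V_obs (bundle-sheath oxygenation)")
    # positive plasmodesmatal flux is M->BS; leakage L > 0 leaves the BS
    eq(transport_id("co2"), -state.L, "L (bundle-sheath CO2 leakage)")
    eq("pepc_m", state.V_p, "V_p (mesophyll PEPC)")
    eq("me_bs", state.V_me, "V_me (bundle-sheath NADP-ME)")

    pr = photorespiratory_bounds(state.V_om, state.xi)
    cs.add(transport_id("gly"), pr["v_min_gly"], BIG, "v_min,Gly = xi*V_om (M->BS)")
    cs.add(transport_id("ser"), -BIG, -pr["v_min_ser"], "v_min,Ser = 0.5*xi*V_om (BS->M)")
    cs.add("gdc_bs", pr["v_min_gdc"], BIG, "v_min,GDC = 0.5*xi*V_om")

    for sp in sorted(scenario.blocked_transports):
        cs.add(transport_id(sp), 0.0, 0.0, f"scenario {scenario.name}: blocked transport")
    return cs


def apply_constraints(
    model: StoichiometricModel,
    state: MechanisticState,
    scenario: ScenarioSpec,
) -> StoichiometricModel:
    """Return a constrained copy of the model (idempotent)."""
    cs = build_constraint_set(state, scenario)
    missing = [rid for rid in REQUIRED_REACTIONS if not model.has_reaction(rid)]
    missing += [
        a.reaction_id for a in cs.assignments if not model.has_reaction(a.reaction_id)
    ]
    if missing:
        raise KeyError(f"model lacks required reaction(s): {sorted(set(missing))}")
    out = model.copy()
    for a in cs.assignments:
        out.set_bounds(a.reaction_id, a.lower, a.upper)
    out.set_plasmodesmatal_weight(scenario.plasmodesmatal_weight)
    return out
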