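"""Core containers for the two-cell stoichiometric model.

The leaf is represented as two metabolite pools (mesophyll and bundle
sheath) joined by plasmodesmatal transport reactions, plus a small shared
pool for phloem-export species consumed by the biomass drain.  Reactions
carry their own bounds (fluxes in µmol s⁻¹ m⁻²) and a weight used by the
weighted minimization of total flux; the stoichiometric matrix ``S`` is
assembled on demand from the reaction stoichiometries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
from scipy import sparse

#: elements tracked in metabolite formulas (hydrogen is deliberately not
#: balanced: protons are not modelled explicitly)
ELEMENTS = ("C", "H", "N", "O", "P", "S")
BALANCED_ELEMENTS = ("C", "N", "O", "P", "S")

CELLS = ("mesophyll", "bundle_sheath", "shared")
REACTION_CELLS = ("mesophyll", "bundle_sheath", "inter_cell", "boundary")
COMPARTMENTS = ("cytosol", "chloroplast", "mitochondrion", "peroxisome", "apoplast")

#: default flux cap, large relative to any leaf-scale flux
BIG = 1000.0


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    cell: str
    compartment: str = "cytosol"
    formula: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        if self.cell not in CELLS:
            raise ValueError(f"unknown cell domain {self.cell!r} for {self.id}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r} for {self.id}")
        for el, n in self.formula.items():
            if el not in ELEMENTS:
                raise ValueError(f"unknown element {el!r} in formula of {self.id}")
            if n < 0:
                raise ValueError(f"negative {el} count in formula of {self.id}")

    def atoms(self, element: str) -> int:
        return int(self.formula.get(element, 0))


@dataclass
class Reaction:
    id: str
    name: str
    stoichiometry: Dict[str, float]
    cell: str
    lower_bound: float = 0.0
    upper_bound: float = BIG
    mtf_weight: float = 1.0
    is_plasmodesmatal: bool = False
    reversible: bool = False
    is_boundary: bool = False
    is_biomass: bool = False

    def __post_init__(self) -> None:
        if self.cell not in REACTION_CELLS:
            raise ValueError(f"unknown reaction cell {self.cell!r} for {self.id}")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"{self.id}: lower bound {self.lower_bound} exceeds upper {self.upper_bound}"
            )
        if self.mtf_weight < 0:
            raise ValueError(f"{self.id}: negative MTF weight")
        if self.is_plasmodesmatal != (self.cell == "inter_cell"):
            raise ValueError(
                f"{self.id}: is_plasmodesmatal must hold exactly for inter_cell reactions"
            )

    def copy(self) -> "Reaction":
        r = replace(self)
        r.stoichiometry = dict(self.stoichiometry)
        return r


class StoichiometricModel:
    """Metabolites, reactions and the matrix ``S`` they induce.

    Column order of ``S`` follows the (stable, insertion-ordered) reaction
    list; the builder inserts reactions in sorted-id order so that the
    matrix layout is reproducible across runs and serializations.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective: Optional[Mapping[str, float]] = None,
        name: str = "model",
    ) -> None:
        self.name = name
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        self.objective: Dict[str, float] = dict(objective or {})
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite id")
        if len(self._rxn_index) != len(self.reactions):
            raise ValueError("duplicate reaction id")
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in self._met_index:
                    raise ValueError(f"reaction {r.id} references unknown metabolite {mid}")
        for rid in self.objective:
            if rid not in self._rxn_index:
                raise ValueError(f"objective references unknown reaction {rid}")

    # -- accessors ---------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def plasmodesmatal_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_plasmodesmatal]

    # -- matrix ------------------------------------------------------------
    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        rows, cols, data = [], [], []
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                rows.append(self._met_index[mid])
                cols.append(j)
                data.append(float(coef))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n_metabolites, self.n_reactions)
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([r.lower_bound for r in self.reactions])
        hi = np.array([r.upper_bound for r in self.reactions])
        return lo, hi

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(self.n_reactions)
        for rid, coef in self.objective.items():
            c[self._rxn_index[rid]] = coef
        return c

    def weight_vector(self) -> np.ndarray:
        return np.array([r.mtf_weight for r in self.reactions])

    # -- editing -----------------------------------------------------------
    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            self.metabolites,
            [r.copy() for r in self.reactions],
            dict(self.objective),
            name=self.name,
        )

    def set_bounds(self, rid: str, lower: float, upper: float) -> None:
        r = self.reaction(rid)
        if lower > upper:
            raise ValueError(f"{rid}: lower bound {lower} exceeds upper {upper}")
        r.lower_bound = float(lower)
        r.upper_bound = float(upper)

    def set_plasmodesmatal_weight(self, weight: float) -> None:
        if weight < 0:
            raise ValueError("negative plasmodesmatal weight")
        for r in self.reactions:
            if r.is_plasmodesmatal:
                r.mtf_weight = float(weight)

    # -- element bookkeeping ----------------------------------------------
    def reaction_element_balance(self, rid: str) -> Dict[str, float]:
        """Net atoms produced per unit flux, for the balanced elements."""
        r = self.reaction(rid)
        net = {el: 0.0 for el in BALANCED_ELEMENTS}
        for mid, coef in r.stoichiometry.items():
            m = self.metabolite(mid)
            for el in BALANCED_ELEMENTS:
                net[el] += coef * m.atoms(el)
        return net

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<StoichiometricModel {self.name}: {self.n_metabolites} metabolites, "
            f"{self.n_reactions} reactions>"
        )


@dataclass
class ImbalanceRecord:
    reaction_id: str
    element: str
    net: float


def check_balances(model: StoichiometricModel, tol: float = 1e-9) -> List[ImbalanceRecord]:
    """Element-balance audit over C, N, O, P, S.

    Boundary and biomass reactions are exempt (they exchange matter with
    the environment by construction).  A missing formula on a metabolite
    used by an internal reaction is an error.
    """
    records: List[ImbalanceRecord] = []
    for r in model.reactions:
        if r.is_boundary or r.is_biomass:
            continue
        for mid in r.stoichiometry:
            m = model.metabolite(mid)
            if not m.formula:
                raise ValueError(
                    f"metabolite {mid} used by internal reaction {r.id} has no formula"
                )
        net = model.reaction_element_balance(r.id)
        for el, val in net.items():
            if abs(val) > tol:
                records.append(ImbalanceRecord(r.id, el, val))
    return records


def balance_report_tsv(records: List[ImbalanceRecord]) -> str:
    lines = ["reaction\telement\tnet"]
    for rec in records:
        lines.append(f"{rec.reaction_id}\t{rec.element}\t{rec.net:g}")
    return "\n".join(lines) + "\n"
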