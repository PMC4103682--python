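"""Model serialization: native JSON and SBML Level 3 + FBC.

The native format is a plain JSON document with ``metabolites``,
``reactions`` and ``objective`` blocks, written with sorted keys so that a
read→write round trip is byte-identical.  SBML I/O goes through cobrapy
(python-libsbml underneath); on import, FBC bounds and objective are
mapped onto :class:`~c2flux.model.Reaction` fields and inter-cell
transport reactions are tagged by a configurable compartment-pair rule.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from .model import BIG, Metabolite, Reaction, StoichiometricModel
from .network import DEFAULT_PLASMODESMATAL_WEIGHT

NATIVE_FORMAT_VERSION = 1

#: compartment pairs whose spanning reactions are tagged plasmodesmatal on
#: SBML import: (mesophyll-side, bundle-sheath-side) compartment ids
DEFAULT_INTERCELL_RULE: Tuple[Tuple[str, str], ...] = (("m", "bs"),)

_CELL_FROM_COMPARTMENT = {"m": "mesophyll", "bs": "bundle_sheath", "sh": "shared"}
_COMPARTMENT_FROM_CELL = {"mesophyll": "m", "bundle_sheath": "bs", "shared": "sh"}


# ---------------------------------------------------------------------------
# native JSON
# ---------------------------------------------------------------------------

def model_to_dict(model: StoichiometricModel) -> dict:
    return {
        "format_version": NATIVE_FORMAT_VERSION,
        "name": model.name,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "cell": m.cell,
                "compartment": m.compartment,
                "formula": {k: v for k, v in sorted(m.formula.items())},
                "charge": m.charge,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: float(v) for k, v in sorted(r.stoichiometry.items())},
                "cell": r.cell,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "mtf_weight": r.mtf_weight,
                "is_plasmodesmatal": r.is_plasmodesmatal,
                "reversible": r.reversible,
                "is_boundary": r.is_boundary,
                "is_biomass": r.is_biomass,
            }
            for r in model.reactions
        ],
        "objective": {k: v for k, v in sorted(model.objective.items())},
    }


def model_from_dict(data: dict) -> StoichiometricModel:
    mets = [
        Metabolite(
            id=m["id"],
            name=m["name"],
            cell=m["cell"],
            compartment=m["compartment"],
            formula=dict(m.get("formula", {})),
            charge=int(m.get("charge", 0)),
        )
        for m in data["metabolites"]
    ]
    rxns = [
        Reaction(
            id=r["id"],
            name=r["name"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            cell=r["cell"],
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            mtf_weight=float(r.get("mtf_weight", 1.0)),
            is_plasmodesmatal=bool(r.get("is_plasmodesmatal", False)),
            reversible=bool(r.get("reversible", False)),
            is_boundary=bool(r.get("is_boundary", False)),
            is_biomass=bool(r.get("is_biomass", False)),
        )
        for r in data["reactions"]
    ]
    return StoichiometricModel(
        mets, rxns, dict(data.get("objective", {})), name=data.get("name", "model")
    )


def write_native(model: StoichiometricModel, path) -> None:
    Path(path).write_text(
        json.dumps(model_to_dict(model), indent=1, sort_keys=True) + "\n"
    )


def read_native(path) -> StoichiometricModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse native model file {path}: {exc}") from exc
    return model_from_dict(data)


# ---------------------------------------------------------------------------
# SBML L3 + FBC (through cobrapy / python-libsbml)
# ---------------------------------------------------------------------------

def _to_cobra(model: StoichiometricModel):
    import cobra

    cm = cobra.Model(model.name)
    cm.compartments = {"m": "mesophyll", "bs": "bundle_sheath", "sh": "shared"}
    cobra_mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id,
            name=m.name,
            compartment=_COMPARTMENT_FROM_CELL[m.cell],
            charge=m.charge,
        )
        parts = [f"{el}{n}" for el, n in sorted(m.formula.items()) if n > 0]
        cmet.formula = "".join(parts)
        cobra_mets[m.id] = cmet
    cm.add_metabolites(list(cobra_mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(
            r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
        )
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({cobra_mets[k]: v for k, v in r.stoichiometry.items()})
        cr.notes["mtf_weight"] = r.mtf_weight
        cr.notes["cell"] = r.cell
        if r.id in model.objective:
            cr.objective_coefficient = model.objective[r.id]
    return cm


def _spans_intercell(compartments: set, rule: Iterable[Tuple[str, str]]) -> bool:
    return any(a in compartments and b in compartments for a, b in rule)


def _check_fbc_bounds(path) -> None:
    """Reject SBML models whose reactions lack FBC flux bounds.

    cobra silently substitutes configuration defaults for missing bounds,
    so the check runs on the raw document via libsbml.
    """
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ValueError(
            f"cannot parse SBML file {path}: "
            f"{doc.getErrorLog().toString().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"cannot parse SBML file {path}: no model element")
    missing = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        fbc = rxn.getPlugin("fbc")
        if fbc is None or not (
            fbc.isSetLowerFluxBound() and fbc.isSetUpperFluxBound()
        ):
            missing.append(rxn.getId())
    if missing:
        raise ValueError(
            f"SBML reaction(s) lacking FBC bounds: {sorted(missing)}"
        )


def write_sbml(model: StoichiometricModel, path) -> None:
    from cobra.io import write_sbml_model

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        write_sbml_model(_to_cobra(model), str(path))


def read_sbml(
    path,
    intercell_rule: Iterable[Tuple[str, str]] = DEFAULT_INTERCELL_RULE,
    plasmodesmatal_weight: float = DEFAULT_PLASMODESMATAL_WEIGHT,
) -> StoichiometricModel:
    """Import an SBML L3+FBC model (e.g. a genuine C4GEM export).

    Reactions spanning a compartment pair named by ``intercell_rule`` are
    tagged as plasmodesmatal and receive ``plasmodesmatal_weight``; other
    reactions keep weight 1.  Reactions without FBC bounds are rejected;
    transport reactions that span compartments not covered by the rule are
    collected into a warning.
    """
    from cobra.io import read_sbml_model

    _check_fbc_bounds(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cm = read_sbml_model(str(path))
        except Exception as exc:  # cobra raises various parse errors
            raise ValueError(f"cannot parse SBML file {path}: {exc}") from exc

    rule = tuple(intercell_rule)
    mets = []
    for m in cm.metabolites:
        cell = _CELL_FROM_COMPARTMENT.get(m.compartment, "shared")
        formula: Dict[str, int] = {}
        if m.formula:
            import re

            for el, n in re.findall(r"([A-Z][a-z]?)(\d*)", m.formula):
                if el:
                    formula[el] = formula.get(el, 0) + (int(n) if n else 1)
            formula = {k: v for k, v in formula.items() if k in "CHNOPS"}
        mets.append(
            Metabolite(
                id=m.id,
                name=m.name or m.id,
                cell=cell,
                compartment="cytosol",
                formula=formula,
                charge=int(m.charge or 0),
            )
        )

    objective = {}
    untagged: List[str] = []
    rxns = []
    for r in cm.reactions:
        if r.lower_bound is None or r.upper_bound is None or (
            math.isnan(r.lower_bound) or math.isnan(r.upper_bound)
        ):
            raise ValueError(f"SBML reaction {r.id} lacks FBC bounds")
        comps = {m.compartment for m in r.metabolites}
        is_pd = _spans_intercell(comps, rule)
        cell = r.notes.get("cell")
        if len(comps) > 1 and not is_pd and not r.boundary and cell is None:
            untagged.append(r.id)
        if cell is None:
            if r.boundary:
                cell = "boundary"
            elif is_pd:
                cell = "inter_cell"
            else:
                only = comps.pop() if len(comps) == 1 else "m"
                cell = _CELL_FROM_COMPARTMENT.get(only, "mesophyll")
        weight = float(r.notes.get("mtf_weight", plasmodesmatal_weight if is_pd else 1.0))
        lb = max(r.lower_bound, -BIG) if math.isinf(r.lower_bound) else r.lower_bound
        ub = min(r.upper_bound, BIG) if math.isinf(r.upper_bound) else r.upper_bound
        coef = r.objective_coefficient
        if coef:
            objective[r.id] = coef
        rxns.append(
            Reaction(
                id=r.id,
                name=r.name or r.id,
                stoichiometry={m.id: c for m, c in r.metabolites.items()},
                cell=cell,
                lower_bound=lb,
                upper_bound=ub,
                mtf_weight=weight,
                is_plasmodesmatal=cell == "inter_cell",
                reversible=lb < 0 < ub,
                is_boundary=cell == "boundary",
                is_biomass=bool(coef),
            )
        )
    if untagged:
        warnings.warn(
            "transport reactions spanning unrecognized compartment pairs "
            f"left untagged: {sorted(untagged)}"
        )
    return StoichiometricModel(mets, rxns, objective, name=cm.id or "sbml_model")


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def write_model(model: StoichiometricModel, path, fmt: Optional[str] = None) -> None:
    fmt = fmt or _guess_format(path)
    if fmt == "native-json":
        write_native(model, path)
    elif fmt == "sbml":
        write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def read_model(path, fmt: Optional[str] = None) -> StoichiometricModel:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    fmt = fmt or _guess_format(path)
    if fmt == "native-json":
        return read_native(path)
    if fmt == "sbml":
        return read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}")


def _guess_format(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".json",):
        return "native-json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot guess model format from {path}")
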