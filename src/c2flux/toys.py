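"""Small hand-checkable networks for validating the LP cascade.

Each toy has ≤ 8 reactions so that FBA/MTF/FVA can be cross-checked
against exhaustive vertex enumeration.  Metabolite formulas are omitted
(these networks exist to exercise the solver, not element bookkeeping).
"""

from __future__ import annotations

from typing import Dict

from .model import Metabolite, Reaction, StoichiometricModel


def _met(mid: str, cell: str = "mesophyll") -> Metabolite:
    return Metabolite(id=mid, name=mid, cell=cell, compartment="cytosol")


def chain_toy() -> StoichiometricModel:
    """EX→A, A→B (capacity 5), B→biomass: single-path bottleneck."""
    mets = [_met("A"), _met("B")]
    rxns = [
        Reaction("ex_a", "A uptake", {"A": 1}, "boundary", 0, 10, is_boundary=True),
        Reaction("a_to_b", "A->B", {"A": -1, "B": 1}, "mesophyll", 0, 5),
        Reaction("bm", "biomass", {"B": -1}, "boundary", 0, 10,
                 is_boundary=True, is_biomass=True),
    ]
    return StoichiometricModel(mets, rxns, {"bm": 1.0}, name="chain_toy")


def parallel_toy() -> StoichiometricModel:
    """Two parallel A→B routes with capacity 3 each; biomass cap 10."""
    mets = [_met("A"), _met("B")]
    rxns = [
        Reaction("ex_a", "A uptake", {"A": 1}, "boundary", 0, 100, is_boundary=True),
        Reaction("r1", "route 1", {"A": -1, "B": 1}, "mesophyll", 0, 3),
        Reaction("r2", "route 2", {"A": -1, "B": 1}, "mesophyll", 0, 3),
        Reaction("bm", "biomass", {"B": -1}, "boundary", 0, 10,
                 is_boundary=True, is_biomass=True),
    ]
    return StoichiometricModel(mets, rxns, {"bm": 1.0}, name="parallel_toy")


def detour_toy() -> StoichiometricModel:
    """Direct A→B vs a 3-step detour A→X→Y→B of equal capacity."""
    mets = [_met("A"), _met("B"), _met("X"), _met("Y")]
    rxns = [
        Reaction("ex_a", "A uptake", {"A": 1}, "boundary", 0, 4, is_boundary=True),
        Reaction("direct", "A->B", {"A": -1, "B": 1}, "mesophyll", 0, 4),
        Reaction("d1", "A->X", {"A": -1, "X": 1}, "mesophyll", 0, 4),
        Reaction("d2", "X->Y", {"X": -1, "Y": 1}, "mesophyll", 0, 4),
        Reaction("d3", "Y->B", {"Y": -1, "B": 1}, "mesophyll", 0, 4),
        Reaction("bm", "biomass", {"B": -1}, "boundary", 0, 4,
                 is_boundary=True, is_biomass=True),
    ]
    return StoichiometricModel(mets, rxns, {"bm": 1.0}, name="detour_toy")


def loop_toy() -> StoichiometricModel:
    """A productive path plus an internal 2-cycle detached from biomass."""
    mets = [_met("A"), _met("B"), _met("C")]
    rxns = [
        Reaction("ex_a", "A uptake", {"A": 1}, "boundary", 0, 2, is_boundary=True),
        Reaction("a_to_b", "A->B", {"A": -1, "B": 1}, "mesophyll", 0, 5),
        Reaction("b_to_c", "B->C", {"B": -1, "C": 1}, "mesophyll", -5, 5,
                 reversible=True),
        Reaction("c_to_b", "C->B", {"C": -1, "B": 1}, "mesophyll", 0, 5),
        Reaction("bm", "biomass", {"B": -1}, "boundary", 0, 5,
                 is_boundary=True, is_biomass=True),
    ]
    return StoichiometricModel(mets, rxns, {"bm": 1.0}, name="loop_toy")


def weighted_transport_toy() -> StoichiometricModel:
    """Two equivalent inter-cell return routes: one crossing vs two.

    Nitrogen-return caricature: the single-crossing route (`tx_direct`)
    must win under plasmodesmatal weighting even though both routes move
    the same material.
    """
    mets = [_met("N_m", "mesophyll"), _met("N_bs", "bundle_sheath"),
            _met("X_m", "mesophyll"), _met("X_bs", "bundle_sheath")]
    rxns = [
        Reaction("src", "N source (bs)", {"N_bs": 1}, "boundary", 2, 2,
                 is_boundary=True),
        Reaction("tx_direct", "direct N crossing", {"N_bs": -1, "N_m": 1},
                 "inter_cell", -10, 10, mtf_weight=1.1, is_plasmodesmatal=True,
                 reversible=True),
        Reaction("load", "package N into X (bs)", {"N_bs": -1, "X_bs": 1},
                 "bundle_sheath", 0, 10),
        Reaction("tx_x", "X crossing", {"X_bs": -1, "X_m": 1},
                 "inter_cell", -10, 10, mtf_weight=1.1, is_plasmodesmatal=True,
                 reversible=True),
        Reaction("unload", "unpack X into N (m)", {"X_m": -1, "N_m": 1},
                 "mesophyll", 0, 10),
        Reaction("bm", "N sink (m)", {"N_m": -1}, "boundary", 0, 10,
                 is_boundary=True, is_biomass=True),
    ]
    return StoichiometricModel(mets, rxns, {"bm": 1.0}, name="weighted_transport_toy")


ALL_TOYS: Dict[str, StoichiometricModel] = {}


def all_toys() -> Dict[str, StoichiometricModel]:
    return {
        "chain": chain_toy(),
        "parallel": parallel_toy(),
        "detour": detour_toy(),
        "loop": loop_toy(),
        "weighted_transport": weighted_transport_toy(),
    }
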