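"""Structure of the curated two-cell core network."""

import pytest

from c2flux.model import BIG, check_balances
from c2flux.network import (
    CCM_REACTION_IDS,
    PHOSPHOSERINE_REACTION_IDS,
    PLASMODESMATAL_SPECIES,
    BiomassSpec,
    build_core_model,
    transport_id,
)
from c2flux.solver import fba
from c2flux.coupling import apply_constraints, make_scenario

EXPECTED_TRANSPORT_SPECIES = {
    # original reconstruction list
    "mal", "pyr", "pga", "tp", "pi", "suc", "asp", "ala", "pep", "co2", "o2",
    # added transports
    "ser", "gly", "glu", "gln", "asn", "thr", "og", "h2o",
}


def test_exactly_19_plasmodesmatal_species(core_model):
    pd = core_model.plasmodesmatal_reactions()
    assert len(pd) == 19
    species = {r.id.removeprefix("tx_") for r in pd}
    assert species == EXPECTED_TRANSPORT_SPECIES
    assert set(PLASMODESMATAL_SPECIES) == EXPECTED_TRANSPORT_SPECIES


def test_no_ammonia_crosses_between_cells(core_model):
    """Free diffusion of ammonia between the cell types is not allowed."""
    for r in core_model.reactions:
        touches_m = any(m.endswith("_m") and m.startswith("nh3") for m in r.stoichiometry)
        touches_bs = any(m.endswith("_bs") and m.startswith("nh3") for m in r.stoichiometry)
        assert not (touches_m and touches_bs), r.id


def test_every_internal_reaction_element_balanced(core_model):
    assert check_balances(core_model) == []


def test_gs_gogat_irreversible(core_model):
    for rid in ("gsgogat_m", "gsgogat_bs", "gs1_m", "gs1_bs"):
        r = core_model.reaction(rid)
        assert not r.reversible
        assert r.lower_bound == 0.0


def test_nitrogen_enters_as_nitrate_only(core_model):
    n_sources = [
        r.id
        for r in core_model.reactions
        if r.is_boundary and not r.is_biomass
        and any(
            core_model.metabolite(m).atoms("N") * c > 0
            for m, c in r.stoichiometry.items()
        )
    ]
    assert sorted(n_sources) == ["ex_no3_bs", "ex_no3_m"]


def test_bundle_sheath_pepc_and_electron_transport_present(core_model):
    pepc_bs = core_model.reaction("pepc_bs")
    assert pepc_bs.upper_bound == BIG  # unconstrained
    assert core_model.has_reaction("let_bs")  # linear electron transport added
    assert core_model.has_reaction("mdh_bs")  # plastidic NADP-MDH added


def test_no_fixed_starch_or_fatty_acid_drains(core_model):
    names = " ".join(r.name.lower() for r in core_model.reactions)
    assert "starch" not in names
    assert "fatty" not in names


def test_biomass_enforces_sucrose_amino_acid_ratio(core_model):
    bm = core_model.reaction("biomass")
    suc = -bm.stoichiometry["suc_sh"]
    aa = sum(-c for m, c in bm.stoichiometry.items() if m != "suc_sh")
    assert suc / aa == pytest.approx(5.0)


def test_unknown_pathway_block_rejected():
    with pytest.raises(ValueError, match="unknown pathway block"):
        build_core_model(blocks=["calvin", "warp_drive"])


def test_biomass_spec_validation():
    with pytest.raises(ValueError, match="ratio"):
        BiomassSpec(sucrose_to_amino_acid_ratio=0.0)
    with pytest.raises(ValueError, match="sum to 1"):
        BiomassSpec(amino_acid_mix={"ala": 0.5})


def test_c3_operation_feasible_without_ccm_and_phosphoserine(core_model, params, c3_state):
    """Blocking the C4 pump and phosphoserine pathway leaves positive biomass."""
    constrained = apply_constraints(core_model, c3_state, make_scenario("A"))
    for rid in CCM_REACTION_IDS + PHOSPHOSERINE_REACTION_IDS:
        # pepc_m / me_bs are already pinned to 0 by the C3-state coupling
        lo = constrained.reaction(rid).lower_bound
        if lo <= 0.0 <= constrained.reaction(rid).upper_bound:
            constrained.set_bounds(rid, 0.0, 0.0)
    sol = fba(constrained)
    assert sol.objective_value > 0.1


def test_custom_biomass_ratio_propagates():
    model = build_core_model(biomass=BiomassSpec(sucrose_to_amino_acid_ratio=3.0))
    bm = model.reaction("biomass")
    assert -bm.stoichiometry["suc_sh"] == pytest.approx(3.0)
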