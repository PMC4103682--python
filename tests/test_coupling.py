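"""Scenario definitions and the mechanistic-constraint translation."""

import pytest

from c2flux.coupling import (
    EQUALITY_BAND,
    ScenarioSpec,
    apply_constraints,
    build_constraint_set,
    make_scenario,
)
from c2flux.network import transport_id


def test_named_scenario_block_sets():
    assert make_scenario("A").blocked_transports == frozenset()
    assert make_scenario("B").blocked_transports == {"og", "glu"}
    assert make_scenario("C").blocked_transports >= {"ala", "pyr", "og", "glu"}
    # D blocks every N carrier except glycine/serine
    d = make_scenario("D").blocked_transports
    assert {"glu", "gln", "asn", "thr", "asp", "ala"} <= d
    assert "gly" not in d and "ser" not in d


def test_block_sets_are_nested():
    blocks = [make_scenario(n).blocked_transports for n in "ABCD"]
    for smaller, larger in zip(blocks, blocks[1:]):
        assert smaller < larger


def test_default_plasmodesmatal_weight_is_1_1():
    assert make_scenario("A").plasmodesmatal_weight == pytest.approx(1.1)


def test_c4_scenario_has_positive_activity():
    c4 = make_scenario("C4")
    assert c4.c4_activity > 0
    assert c4.blocked_transports == frozenset()


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError, match="unknown scenario"):
        make_scenario("Z")


def test_blocking_glycine_or_serine_forbidden():
    with pytest.raises(ValueError, match="C2 cycle"):
        ScenarioSpec(name="bad", blocked_transports=frozenset({"gly"}))
    with pytest.raises(ValueError, match="C2 cycle"):
        ScenarioSpec(name="bad", blocked_transports=frozenset({"serine"}))


def test_friendly_species_names_are_canonicalized():
    s = ScenarioSpec(name="x", blocked_transports=frozenset({"2-oxoglutarate", "Glutamate"}))
    assert s.blocked_transports == {"og", "glu"}


def test_equality_constraints_are_tight_bands(core_model, c3_state):
    cs = build_constraint_set(c3_state, make_scenario("A"))
    by_id = {a.reaction_id: a for a in cs.assignments}
    rbc = by_id["rbc_m"]
    assert rbc.upper - rbc.lower == pytest.approx(2 * EQUALITY_BAND)
    assert (rbc.lower + rbc.upper) / 2 == pytest.approx(c3_state.V_cm)
    # leakage enters with the M->BS sign convention
    leak = by_id[transport_id("co2")]
    assert (leak.lower + leak.upper) / 2 == pytest.approx(-c3_state.L)


def test_photorespiratory_lower_bounds_applied(core_model, c3_state):
    con = apply_constraints(core_model, c3_state, make_scenario("A"))
    xi_vom = c3_state.xi * c3_state.V_om
    assert con.reaction(transport_id("gly")).lower_bound == pytest.approx(xi_vom)
    # serine returns BS->M: the signed upper bound enforces the magnitude
    assert con.reaction(transport_id("ser")).upper_bound == pytest.approx(-0.5 * xi_vom)
    assert con.reaction("gdc_bs").lower_bound == pytest.approx(0.5 * xi_vom)


def test_blocked_transports_pinned_to_zero(core_model, c3_state):
    con = apply_constraints(core_model, c3_state, make_scenario("D"))
    for sp in make_scenario("D").blocked_transports:
        r = con.reaction(transport_id(sp))
        assert r.lower_bound == 0.0 and r.upper_bound == 0.0
    # 3-PGA, triose phosphate and sucrose remain open
    for sp in ("pga", "tp", "suc"):
        assert con.reaction(transport_id(sp)).upper_bound > 0


def test_apply_constraints_is_idempotent(core_model, c3_state):
    once = apply_constraints(core_model, c3_state, make_scenario("B"))
    twice = apply_constraints(once, c3_state, make_scenario("B"))
    for r1, r2 in zip(once.reactions, twice.reactions):
        assert r1.lower_bound == r2.lower_bound
        assert r1.upper_bound == r2.upper_bound
        assert r1.mtf_weight == r2.mtf_weight


def test_missing_reaction_reported(core_model, c3_state):
    crippled = core_model.copy()
    crippled.reactions = [r for r in crippled.reactions if r.id != "me_bs"]
    crippled._rxn_index = {r.id: i for i, r in enumerate(crippled.reactions)}
    with pytest.raises(KeyError, match="me_bs"):
        apply_constraints(crippled, c3_state, make_scenario("A"))


def test_scenario_weight_propagates(core_model, c3_state):
    con = apply_constraints(
        core_model, c3_state, make_scenario("A").with_weight(1.5)
    )
    for r in con.plasmodesmatal_reactions():
        assert r.mtf_weight == pytest.approx(1.5)
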