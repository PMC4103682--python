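"""Scenario pipeline: shuttle classification, nitrogen books, scans."""

import numpy as np
import pytest

from c2flux.analysis import (
    SHUTTLE_ALA_PYR,
    SHUTTLE_ASP_MAL,
    SHUTTLE_C4,
    SHUTTLE_GLU_OG,
    SHUTTLE_PSER,
    classify_shuttle,
    nitrogen_ledger,
    scan_c4_activity,
    weight_sensitivity,
)
from c2flux.coupling import make_scenario
from c2flux.solver import FluxSolution


def _point_solution(core_model, **fluxes):
    base = {r.id: 0.0 for r in core_model.reactions}
    base.update(fluxes)
    return FluxSolution(fluxes=base, objective_value=0.0, weighted_abs_sum=0.0)


def test_classify_glutamate_shuttle_from_point_fluxes(core_model):
    """Glu BS->M and 2-OG M->BS at the N-return level ⇒ Glu/2-OG label."""
    sol = _point_solution(core_model, tx_glu=-4.9, tx_og=4.9)
    assert classify_shuttle(sol, None, core_model) == [SHUTTLE_GLU_OG]


def test_classify_all_zero_is_none(core_model):
    sol = _point_solution(core_model)
    assert classify_shuttle(sol, None, core_model) == []


def test_classify_c4_malate_alanine(core_model):
    sol = _point_solution(core_model, tx_mal=3.0, tx_ala=-3.0, me_bs=3.0)
    assert classify_shuttle(sol, None, core_model) == [SHUTTLE_C4]


def test_scenario_shuttles_match_predictions(scenario_results):
    assert scenario_results["A"].shuttles == [SHUTTLE_GLU_OG]
    assert scenario_results["B"].shuttles == [SHUTTLE_ALA_PYR]
    assert scenario_results["C"].shuttles == [SHUTTLE_ASP_MAL]
    assert scenario_results["D"].shuttles == [SHUTTLE_PSER]
    assert scenario_results["C4"].shuttles == [SHUTTLE_C4]


def test_nitrogen_ledger_closes_per_cell(scenario_results, core_model):
    for res in scenario_results.values():
        for cell, row in res.nitrogen_ledger.items():
            assert abs(row["residual"]) <= 1e-6, (res.scenario.name, cell)


def test_photorespiratory_bounds_respected(scenario_results):
    for res in scenario_results.values():
        xi_vom = res.state.xi * res.state.V_om
        assert res.solution.fluxes["tx_gly"] >= xi_vom - 1e-6
        assert res.solution.fluxes["tx_ser"] <= -0.5 * xi_vom + 1e-6
        assert res.solution.fluxes["gdc_bs"] >= 0.5 * xi_vom - 1e-6


def test_c4_scan_shifts_nitrogen_return_to_the_c4_cycle(core_model, params):
    table = scan_c4_activity(core_model, params, vp_grid=[0.0, 1.0, 2.0])
    assert (table["status"] == "optimal").all()
    # Ala-AT activities rise, Glu/2-OG transfer falls
    assert table["alaat_m"].is_monotonic_increasing
    assert table["glu_transfer"].is_monotonic_decreasing
    # at V_p = 0 the glutamate/2-OG pair carries the N return on its own
    row0 = table.iloc[0]
    assert row0["glu_transfer"] > 1.0
    assert row0["og_transfer"] == pytest.approx(row0["glu_transfer"], abs=1e-6)
    assert row0["alaat_m"] == pytest.approx(0.0, abs=1e-6)


def test_c4_scan_rejects_bad_grid(core_model, params):
    with pytest.raises(ValueError):
        scan_c4_activity(core_model, params, vp_grid=[1.0, 0.5])


def test_weight_scan_biomass_invariant(core_model, params):
    """Weights shape the secondary objective only; biomass is pinned first."""
    table = weight_sensitivity(
        core_model, params, make_scenario("A"), weight_grid=[1.0, 1.1]
    )
    b = table["biomass"].to_numpy()
    assert b[0] == pytest.approx(b[1], rel=1e-9)


def test_weight_scan_crossings_non_increasing(core_model, params):
    table = weight_sensitivity(
        core_model, params, make_scenario("A"), weight_grid=[1.1, 4.0, 12.0]
    )
    sums = table["plasmodesmatal_sum"].to_numpy()
    assert np.all(np.diff(sums) <= 1e-6)


def test_infeasible_scan_points_are_recorded_not_fatal(core_model, params):
    crippled = core_model.copy()
    # without nitrate the fixed CO2 uptake cannot leave through biomass
    crippled.set_bounds("ex_no3_m", 0.0, 0.0)
    crippled.set_bounds("ex_no3_bs", 0.0, 0.0)
    table = scan_c4_activity(crippled, params, vp_grid=[0.0, 1.0])
    assert (table["status"] == "infeasible").all()
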