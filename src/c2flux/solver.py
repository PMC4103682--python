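"""The three-stage LP cascade: FBA, weighted MTF, FVA.

All programs are solved with scipy's HiGHS dual-simplex backend with
tight feasibility tolerances, which is deterministic for a fixed model;
ties among alternative optima are characterized via FVA rather than by
perturbing the solver.

The weighted minimization of total flux (MTF) minimizes Σᵢ wᵢ|vᵢ| at the
pinned FBA optimum.  The absolute value is linearized exactly by splitting
every flux into non-negative forward/backward parts, v = v⁺ − v⁻, and
penalizing wᵢ(v⁺ᵢ + v⁻ᵢ).  FVA then minimizes and maximizes each flux over
the optimal set {c·v = c·v_FBA, Σ w|v| ≤ s_opt (+tiny relaxation)}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import StoichiometricModel

logger = logging.getLogger(__name__)

#: HiGHS settings used for every LP in the cascade
SOLVER_METHOD = "highs-ds"
SOLVER_OPTIONS = {
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

STEADY_STATE_TOL = 1e-8
FVA_ABS_RELAXATION = 1e-6


class InfeasibleModelError(RuntimeError):
    pass


class UnboundedModelError(RuntimeError):
    pass


@dataclass
class FluxSolution:
    fluxes: Dict[str, float]
    objective_value: float
    weighted_abs_sum: float
    status: str = "optimal"

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def vector(self, model: StoichiometricModel) -> np.ndarray:
        return np.array([self.fluxes[r.id] for r in model.reactions])


@dataclass
class FVARange:
    ranges: Dict[str, Tuple[float, float]]

    def __getitem__(self, rid: str) -> Tuple[float, float]:
        return self.ranges[rid]

    def minimum(self, rid: str) -> float:
        return self.ranges[rid][0]

    def maximum(self, rid: str) -> float:
        return self.ranges[rid][1]

    def forced_flux(self, rid: str) -> float:
        """Signed flux magnitude forced across the whole optimal set.

        Returns the interval endpoint closest to zero when the interval
        does not straddle zero, else 0: a reaction is 'forced' only if
        every optimal solution carries at least that much flux in one
        direction.
        """
        lo, hi = self.ranges[rid]
        if lo > 0:
            return lo
        if hi < 0:
            return hi
        return 0.0


def _bound_conflict_hint(model: StoichiometricModel) -> str:
    forced = [
        f"{r.id}[{r.lower_bound:g},{r.upper_bound:g}]"
        for r in model.reactions
        if r.lower_bound > 1e-12 or r.upper_bound < -1e-12
    ]
    return "reactions with sign-forcing bounds: " + (", ".join(forced) or "none")


def _check_solution(model: StoichiometricModel, v: np.ndarray) -> None:
    S = model.stoichiometric_matrix()
    imbalance = np.abs(S @ v).max() if model.n_metabolites else 0.0
    if imbalance > STEADY_STATE_TOL:
        raise RuntimeError(f"steady-state violation |S v| = {imbalance:.3g}")
    lo, hi = model.bounds_arrays()
    if (v < lo - STEADY_STATE_TOL).any() or (v > hi + STEADY_STATE_TOL).any():
        raise RuntimeError("flux bound violation in LP solution")


def fba(model: StoichiometricModel) -> FluxSolution:
    """Maximize cᵀv subject to Sv = 0, v_min ≤ v ≤ v_max."""
    c = model.objective_vector()
    if not np.any(c):
        raise ValueError("model has an empty objective")
    S = model.stoichiometric_matrix()
    lo, hi = model.bounds_arrays()
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(model.n_metabolites),
        bounds=list(zip(lo, hi)),
        method=SOLVER_METHOD,
        options=SOLVER_OPTIONS,
    )
    if res.status == 2:
        raise InfeasibleModelError(
            "FBA infeasible; " + _bound_conflict_hint(model)
        )
    if res.status == 3:
        raise UnboundedModelError("FBA unbounded (objective has an unbounded ray)")
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    v = res.x
    _check_solution(model, v)
    w = model.weight_vector()
    return FluxSolution(
        fluxes={r.id: float(v[j]) for j, r in enumerate(model.reactions)},
        objective_value=float(c @ v),
        weighted_abs_sum=float(w @ np.abs(v)),
    )


def _split_problem(model: StoichiometricModel):
    """Equality system and bounds in the split (v⁺, v⁻) space."""
    n = model.n_reactions
    S = model.stoichiometric_matrix()
    A_steady = sparse.hstack([S, -S], format="csr")
    lo, hi = model.bounds_arrays()
    bounds = []
    for j in range(n):
        bounds.append((max(lo[j], 0.0), max(hi[j], 0.0)))
    for j in range(n):
        bounds.append((max(-hi[j], 0.0), max(-lo[j], 0.0)))
    return A_steady, bounds


def _recombine(x: np.ndarray, n: int) -> np.ndarray:
    return x[:n] - x[n:]


def mtf(
    model: StoichiometricModel,
    v_fba: FluxSolution,
    weights: Optional[np.ndarray] = None,
) -> FluxSolution:
    """Minimize Σ wᵢ|vᵢ| with the biomass objective pinned to its optimum."""
    n = model.n_reactions
    c_obj = model.objective_vector()
    w = model.weight_vector() if weights is None else np.asarray(weights, dtype=float)
    A_steady, bounds = _split_problem(model)
    A_pin = sparse.hstack(
        [sparse.csr_matrix(c_obj), sparse.csr_matrix(-c_obj)], format="csr"
    )
    A_eq = sparse.vstack([A_steady, A_pin], format="csr")
    b_eq = np.zeros(A_eq.shape[0])
    b_eq[-1] = v_fba.objective_value
    cost = np.concatenate([w, w])
    res = linprog(
        cost,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method=SOLVER_METHOD,
        options=SOLVER_OPTIONS,
    )
    if res.status == 2:
        raise InfeasibleModelError(
            "MTF infeasible: pinned biomass "
            f"{v_fba.objective_value:.6g} not achievable; "
            + _bound_conflict_hint(model)
        )
    if not res.success:
        raise RuntimeError(f"MTF solver failure: {res.message}")
    v = _recombine(res.x, n)
    _check_solution(model, v)
    sol = FluxSolution(
        fluxes={r.id: float(v[j]) for j, r in enumerate(model.reactions)},
        objective_value=float(c_obj @ v),
        weighted_abs_sum=float(w @ np.abs(v)),
    )
    rel = abs(sol.objective_value - v_fba.objective_value) / max(
        1.0, abs(v_fba.objective_value)
    )
    if rel > 1e-9:
        raise RuntimeError(f"MTF failed to preserve the FBA objective (rel {rel:.3g})")
    return sol


def fva(
    model: StoichiometricModel,
    v_fba: FluxSolution,
    s_opt: float,
    weights: Optional[np.ndarray] = None,
    reactions: Optional[Iterable[str]] = None,
) -> FVARange:
    """Per-reaction flux range over the MTF-optimal set.

    The Σ w|v| = s_opt condition is imposed as ≤ s_opt (plus a tiny
    relaxation): together with the biomass pin this is equivalent to
    equality, since s_opt is the minimum on that face.
    """
    n = model.n_reactions
    c_obj = model.objective_vector()
    w = model.weight_vector() if weights is None else np.asarray(weights, dtype=float)
    A_steady, bounds = _split_problem(model)
    A_pin = sparse.hstack(
        [sparse.csr_matrix(c_obj), sparse.csr_matrix(-c_obj)], format="csr"
    )
    A_eq = sparse.vstack([A_steady, A_pin], format="csr")
    b_eq = np.zeros(A_eq.shape[0])
    b_eq[-1] = v_fba.objective_value
    cost_row = np.concatenate([w, w])
    A_ub = sparse.csr_matrix(cost_row)
    s_cap = s_opt * (1.0 + 1e-9) + FVA_ABS_RELAXATION
    b_ub = np.array([s_cap])

    rids = list(reactions) if reactions is not None else model.reaction_ids()
    idx = {r.id: j for j, r in enumerate(model.reactions)}
    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in rids:
        j = idx[rid]
        obj = np.zeros(2 * n)
        obj[j] = 1.0
        obj[n + j] = -1.0
        lo_hi = []
        for sign in (1.0, -1.0):
            res = linprog(
                sign * obj,
                A_eq=A_eq,
                b_eq=b_eq,
                A_ub=A_ub,
                b_ub=b_ub,
                bounds=bounds,
                method=SOLVER_METHOD,
                options=SOLVER_OPTIONS,
            )
            if res.status == 2:
                raise InfeasibleModelError(f"FVA infeasible for {rid}")
            if not res.success:
                raise RuntimeError(f"FVA solver failure for {rid}: {res.message}")
            lo_hi.append(sign * res.fun)
        ranges[rid] = (min(lo_hi), max(lo_hi))
    return FVARange(ranges)


def plasmodesmatal_sum(
    solution: FluxSolution, model: StoichiometricModel, weighted: bool = False
) -> float:
    """Σ |vᵢ| over plasmodesmatal reactions (optionally wᵢ-weighted)."""
    total = 0.0
    for r in model.reactions:
        if r.is_plasmodesmatal:
            f = abs(solution.fluxes[r.id])
            total += r.mtf_weight * f if weighted else f
    return total


def solution_tsv(
    model: StoichiometricModel,
    solution: FluxSolution,
    fva_ranges: Optional[FVARange] = None,
) -> str:
    lines = ["reaction\tflux\tfva_min\tfva_max\tweight\tis_plasmodesmatal"]
    for r in model.reactions:
        v = solution.fluxes[r.id]
        if fva_ranges is not None and r.id in fva_ranges.ranges:
            lo, hi = fva_ranges[r.id]
            lo_s, hi_s = f"{lo:.10g}", f"{hi:.10g}"
        else:
            lo_s = hi_s = ""
        lines.append(
            f"{r.id}\t{v:.10g}\t{lo_s}\t{hi_s}\t{r.mtf_weight:g}\t"
            f"{int(r.is_plasmodesmatal)}"
        )
    return "\n".join(lines) + "\n"
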