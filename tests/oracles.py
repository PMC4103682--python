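"""Independent brute-force oracles for the LP cascade.

Exhaustive vertex enumeration over {Sv=b, Gv<=h, lo<=v<=hi}: a vertex has
n active constraints, so we enumerate all ways of activating bounds (and
optionally the single inequality row) and solve the resulting square
systems with plain linear algebra.  The weighted absolute-flux objective
is handled by splitting the box into sign orthants, where it is linear.

Only suitable for networks with a handful of reactions; deliberately
shares no code with the scipy/HiGHS implementation it checks.
"""

from __future__ import annotations

import itertools
from typing import List, Optional, Tuple

import numpy as np

TOL = 1e-9


def enumerate_vertices(
    A_eq: np.ndarray,
    b_eq: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
) -> List[np.ndarray]:
    """All vertices of {A_eq v = b_eq, A_ub v <= b_ub, lo <= v <= hi}."""
    n = A_eq.shape[1]
    rows = [A_eq[i] for i in range(A_eq.shape[0])]
    rhs = [b_eq[i] for i in range(A_eq.shape[0])]
    ineqs = []
    if A_ub is not None:
        ineqs = [(A_ub[i], b_ub[i]) for i in range(A_ub.shape[0])]

    vertices: List[np.ndarray] = []

    def try_active(extra_rows, extra_rhs):
        base = np.array(rows + extra_rows)
        base_rhs = np.array(rhs + extra_rhs)
        r = np.linalg.matrix_rank(base)
        free = n - r
        if free < 0:
            return
        # fix `free` coordinates at a bound, solve for the rest
        for idx in itertools.combinations(range(n), free):
            for pattern in itertools.product((0, 1), repeat=free):
                fixed = {}
                ok = True
                for j, p in zip(idx, pattern):
                    val = lo[j] if p == 0 else hi[j]
                    if not np.isfinite(val):
                        ok = False
                        break
                    fixed[j] = val
                if not ok:
                    continue
                A_full = np.vstack(
                    [base] + [np.eye(n)[j][None, :] for j in idx]
                )
                b_full = np.concatenate([base_rhs, [fixed[j] for j in idx]])
                if np.linalg.matrix_rank(A_full) < n:
                    continue
                sol, res, rank, _ = np.linalg.lstsq(A_full, b_full, rcond=None)
                if np.abs(A_full @ sol - b_full).max() > 1e-7:
                    continue
                if (sol < lo - 1e-7).any() or (sol > hi + 1e-7).any():
                    continue
                feasible = True
                for g, h in ineqs:
                    if g @ sol > h + 1e-7:
                        feasible = False
                        break
                if feasible:
                    vertices.append(np.clip(sol, lo, hi))

    try_active([], [])
    for g, h in ineqs:
        try_active([g], [h])

    unique: List[np.ndarray] = []
    for v in vertices:
        if not any(np.abs(v - u).max() < 1e-6 for u in unique):
            unique.append(v)
    return unique


def _orthants(lo: np.ndarray, hi: np.ndarray):
    """Sign-restricted boxes covering the original box."""
    n = len(lo)
    split = [j for j in range(n) if lo[j] < -TOL and hi[j] > TOL]
    for signs in itertools.product((1, -1), repeat=len(split)):
        l, h = lo.copy(), hi.copy()
        for j, s in zip(split, signs):
            if s > 0:
                l[j] = 0.0
            else:
                h[j] = 0.0
        yield l, h


def fba_oracle(model) -> Tuple[float, np.ndarray]:
    """Maximum of c·v by vertex enumeration."""
    S = model.stoichiometric_matrix().toarray()
    lo, hi = model.bounds_arrays()
    c = model.objective_vector()
    verts = enumerate_vertices(S, np.zeros(S.shape[0]), lo, hi)
    assert verts, "empty feasible polytope"
    vals = [c @ v for v in verts]
    k = int(np.argmax(vals))
    return vals[k], verts[k]


def mtf_oracle(model, z_star: float) -> float:
    """Minimum of Σ w|v| subject to Sv=0, bounds, c·v = z*."""
    S = model.stoichiometric_matrix().toarray()
    lo, hi = model.bounds_arrays()
    c = model.objective_vector()
    w = model.weight_vector()
    A_eq = np.vstack([S, c[None, :]])
    b_eq = np.concatenate([np.zeros(S.shape[0]), [z_star]])
    best = np.inf
    for l, h in _orthants(lo, hi):
        for v in enumerate_vertices(A_eq, b_eq, l, h):
            best = min(best, float(w @ np.abs(v)))
    return best


def fva_oracle(model, z_star: float, s_opt: float):
    """Per-reaction min/max over the MTF-optimal set."""
    S = model.stoichiometric_matrix().toarray()
    lo, hi = model.bounds_arrays()
    c = model.objective_vector()
    w = model.weight_vector()
    A_eq = np.vstack([S, c[None, :]])
    b_eq = np.concatenate([np.zeros(S.shape[0]), [z_star]])
    n = S.shape[1]
    mins = np.full(n, np.inf)
    maxs = np.full(n, -np.inf)
    for l, h in _orthants(lo, hi):
        signs = np.where(l >= 0, 1.0, -1.0)
        A_ub = (w * signs)[None, :]
        b_ub = np.array([s_opt + 1e-7])
        for v in enumerate_vertices(A_eq, b_eq, l, h, A_ub, b_ub):
            mins = np.minimum(mins, v)
            maxs = np.maximum(maxs, v)
    return {
        r.id: (mins[j], maxs[j]) for j, r in enumerate(model.reactions)
    }
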