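"""Steady-state enzyme-limited model of C3–C4 intermediate photosynthesis.

A von Caemmerer-type two-compartment formulation: Rubisco operates in both
mesophyll and bundle sheath with Michaelis–Menten CO2 kinetics and
competitive O2 inhibition; the oxygenation/carboxylation ratio per
compartment is 2·Γ*/C; PEPC activity V_p pumps CO2 into the bundle sheath
via the C4 acids; the photorespiratory pump moves glycine into the bundle
sheath where a fraction ξ of mesophyll-derived photorespiratory CO2 is
released by GDC.  The bundle-sheath CO2 partial pressure C_bs is the
single unknown, fixed by the CO2 mass balance

    V_p + 0.5·ξ·V_om + 0.5·V_obs(C_bs) − V_cbs(C_bs) − g_bs·(C_bs − C_m) = 0

solved by bisection.  Only the enzyme-limited regime is implemented.

Γ* is specified at a reference O2 pressure of 210 mbar and scales linearly
with O2, so that oxygenation vanishes without O2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional

#: O2 partial pressure (mbar) at which ``gamma_star`` is specified
O_REFERENCE_MBAR = 210.0


@dataclass(frozen=True)
class MechanisticParams:
    """Enzyme-limited C3–C4 parameter set (C3-state defaults).

    Kinetic constants follow widely used tobacco-derived Rubisco
    parameterizations; fluxes in µmol s⁻¹ m⁻², pressures in µbar (CO2)
    and mbar (O2).
    """

    Vcmax_m: float = 50.0   # mesophyll Rubisco carboxylation capacity
    Vcmax_bs: float = 10.0  # bundle-sheath Rubisco carboxylation capacity
    Vpmax: float = 40.0     # PEPC capacity (used when V_p is enzyme-limited)
    Kc: float = 405.0       # Rubisco CO2 Michaelis constant (µbar)
    Ko: float = 278.0       # Rubisco O2 Michaelis constant (mbar)
    Kp: float = 80.0        # PEPC CO2 Michaelis constant (µbar)
    gamma_star: float = 43.0  # Γ* at 210 mbar O2 (µbar)
    g_bs: float = 0.003     # bundle-sheath CO2 conductance (µmol s⁻¹ m⁻² µbar⁻¹)
    Rd: float = 0.0         # day respiration (µmol s⁻¹ m⁻²)
    xi: float = 0.98        # fraction of photorespiratory CO2 released in BS
    Ca: float = 380.0       # ambient CO2 (µbar)
    O: float = 210.0        # O2 partial pressure (mbar)
    mesophyll_drawdown: float = 0.7  # C_m = drawdown · Ca
    Cm: Optional[float] = None       # explicit mesophyll CO2, overrides drawdown

    def __post_init__(self) -> None:
        for name in ("Vcmax_m", "Vcmax_bs", "Vpmax", "Kc", "Ko", "Kp",
                     "gamma_star", "g_bs", "Rd", "Ca", "O"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative parameter {name}")
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError("xi must lie in [0, 1]")
        if not 0.0 < self.mesophyll_drawdown <= 1.0:
            raise ValueError("mesophyll drawdown must lie in (0, 1]")

    @property
    def C_m(self) -> float:
        return self.Cm if self.Cm is not None else self.mesophyll_drawdown * self.Ca

    def gamma_star_at_O(self) -> float:
        return self.gamma_star * self.O / O_REFERENCE_MBAR


@dataclass
class MechanisticState:
    """Steady-state rates handed to the FBA layer (µmol s⁻¹ m⁻²)."""

    V_cm: float
    V_om: float
    V_cbs: float
    V_obs: float
    V_p: float
    V_me: float
    L: float
    A_net: float
    v_gly: float
    v_ser: float
    v_gdc: float
    C_m: float
    C_bs: float
    xi: float
    residual: float = 0.0

    def as_dict(self) -> Dict[str, float]:
        return asdict(self)


def _carboxylation(C: float, Vcmax: float, Kc_eff: float) -> float:
    return Vcmax * C / (C + Kc_eff)


def photorespiratory_bounds(V_om: float, xi: float) -> Dict[str, float]:
    """Lower bounds on the C2-cycle reactions from mesophyll oxygenation.

    v_min,Gly = ξ·V_om ; v_min,Ser = v_min,GDC = 0.5·ξ·V_om.
    """
    if V_om < 0:
        raise ValueError("V_om must be non-negative")
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    return {
        "v_min_gly": xi * V_om,
        "v_min_ser": 0.5 * xi * V_om,
        "v_min_gdc": 0.5 * xi * V_om,
    }


def solve_steady_state(
    params: MechanisticParams,
    V_p: Optional[float] = None,
    tol: float = 1e-12,
    bracket_factor: float = 1e-3,
    C_bs_max: float = 1e4,
) -> MechanisticState:
    """Solve the bundle-sheath CO2 balance and return all coupled rates.

    ``V_p`` fixes the PEPC (C4 cycle) activity; by default it is 0 (pure
    C2 operation).  Pass a positive value to superimpose a C4 cycle; the
    whole state (leakage, C_bs, bundle-sheath rates) re-equilibrates.
    """
    if V_p is None:
        V_p = 0.0
    if V_p < 0:
        raise ValueError("V_p must be non-negative")

    C_m = params.C_m
    gs = params.gamma_star_at_O()
    Kc_eff = params.Kc * (1.0 + params.O / params.Ko)

    V_cm = _carboxylation(C_m, params.Vcmax_m, Kc_eff)
    V_om = V_cm * 2.0 * gs / C_m if C_m > 0 else 0.0

    def residual_at(C_bs: float) -> float:
        V_cbs = _carboxylation(C_bs, params.Vcmax_bs, Kc_eff)
        V_obs = V_cbs * 2.0 * gs / C_bs if C_bs > 0 else 0.0
        return (
            V_p
            + 0.5 * params.xi * V_om
            + 0.5 * V_obs
            - V_cbs
            - params.g_bs * (C_bs - C_m)
        )

    lo, hi = C_m * bracket_factor, C_bs_max
    f_lo, f_hi = residual_at(lo), residual_at(hi)
    if f_lo * f_hi > 0:
        raise RuntimeError(
            "no root in bracket for bundle-sheath CO2 balance: "
            f"f({lo:.3g})={f_lo:.3g}, f({hi:.3g})={f_hi:.3g}"
        )
    # plain bisection: deterministic and robust for this monotone balance
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = residual_at(mid)
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
        if hi - lo < tol:
            break
    C_bs = 0.5 * (lo + hi)

    V_cbs = _carboxylation(C_bs, params.Vcmax_bs, Kc_eff)
    V_obs = V_cbs * 2.0 * gs / C_bs if C_bs > 0 else 0.0
    L = params.g_bs * (C_bs - C_m)
    A_net = V_cm + V_cbs - 0.5 * (V_om + V_obs) - params.Rd
    v_gly = params.xi * V_om
    state = MechanisticState(
        V_cm=V_cm,
        V_om=V_om,
        V_cbs=V_cbs,
        V_obs=V_obs,
        V_p=V_p,
        V_me=V_p,
        L=L,
        A_net=A_net,
        v_gly=v_gly,
        v_ser=0.5 * v_gly,
        v_gdc=0.5 * v_gly,
        C_m=C_m,
        C_bs=C_bs,
        xi=params.xi,
        residual=residual_at(C_bs),
    )
    # the achievable residual is floored by the float spacing of C_bs times
    # the balance slope (≈ g_bs); 1e-9 applies whenever it is attainable
    floor = 64.0 * params.g_bs * max(C_bs, 1.0) * 2.220446049250313e-16
    if abs(state.residual) > max(1e-9, floor):
        raise RuntimeError(
            f"bundle-sheath CO2 balance residual {state.residual:.3g} exceeds 1e-9"
        )
    return state


def state_tsv(state: MechanisticState) -> str:
    lines = ["quantity\tvalue"]
    for k, v in state.as_dict().items():
        lines.append(f"{k}\t{v:.10g}")
    return "\n".join(lines) + "\n"
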