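# Methods

`c2flux` couples a steady-state, enzyme-limited model of C3–C4
intermediate photosynthesis to a two-cell stoichiometric model of leaf
metabolism, and asks a constraint-based question: once a photorespiratory
CO2 pump (C2 photosynthesis) is running, how must the leaf re-balance its
nitrogen metabolism between mesophyll (M) and bundle sheath (BS)?

## The mechanistic layer

Rubisco operates in both cells with Michaelis–Menten CO2 kinetics and
competitive O2 inhibition,

    V_c(C) = Vcmax · C / (C + Kc·(1 + O/Ko)),      V_o/V_c = 2·Γ*/C,

where C is the local CO2 partial pressure. Γ* is specified at a reference
O2 pressure of 210 mbar and scaled linearly in O, so oxygenation vanishes
in an O2-free atmosphere. The mesophyll CO2 pressure is a fixed stomatal
drawdown of ambient, C_m = 0.7·Ca (no stomatal model). The C2 pump moves
the glycine produced by mesophyll oxygenation into the bundle sheath,
where a fraction ξ (default 0.98, reflecting near-complete confinement of
GDC activity to the bundle sheath) of its decarboxylation CO2 is
released. A superimposed C4 cycle of activity V_p (mesophyll PEPC →
malate → BS NADP-ME) adds CO2 at rate V_p. The single unknown, the
bundle-sheath CO2 pressure C_bs, solves the mass balance

    V_p + 0.5·ξ·V_om + 0.5·V_obs(C_bs) − V_cbs(C_bs) − g_bs·(C_bs − C_m) = 0

by bisection on [10⁻³·C_m, 10⁴ µbar]. The residual at the root is checked
against 1e-9 (relaxed only by the floating-point floor g_bs·eps(C_bs) at
extreme conductances). There is no randomness anywhere in the package.

Default parameters are literature-standard C3 Rubisco kinetics and leaf
geometry (µbar, mbar, µmol s⁻¹ m⁻²): Vcmax_m = 50, Vcmax_bs = 10
(mesophyll-dominated Rubisco, as in a type-I intermediate), Kc = 405,
Ko = 278, Γ* = 43 at 210 mbar O2, Kp = 80, g_bs = 0.003, Ca = 380,
O = 210, ξ = 0.98. Day respiration Rd defaults to 0 because the core
network carries no maintenance drain; a nonzero Rd would make the net-CO2
equality inconsistent with the network's carbon balance. With these
defaults the whole-leaf oxygenation:carboxylation ratio is ≈ 0.33 — the
"about one third" regime in which the C2 pump matters. They are config
values, not constants; any of them can be overridden from a YAML block.

Only the enzyme-limited regime is implemented; light limitation,
temperature response and stomatal feedback are out of scope.

## The coupling

The mechanistic state fixes, as two-sided bounds with a ±1e-6 band (an
exact equality invites LP infeasibility from rounding): net CO2 uptake
A_net, Rubisco carboxylation and oxygenation in both cells (V_cm, V_om,
V_cbs, V_obs), the inter-cell CO2 flux (= −L, leakage, with positive
plasmodesmatal flux defined M→BS), mesophyll PEPC (V_p) and bundle-sheath
NADP-ME (V_me = V_p). The photorespiratory pump enters as lower bounds

    v_min,Gly = ξ·V_om  (glycine M→BS),
    v_min,Ser = 0.5·ξ·V_om  (serine BS→M),
    v_min,GDC = 0.5·ξ·V_om  (bundle-sheath GDC),

leaving the network free to run extra glycine/serine traffic if optimal.
A scenario additionally closes a set of plasmodesmatal transports
(never glycine or serine) and sets the MTF weight on the rest.

The C4-activity knob re-solves the mechanistic model at the requested
V_p, so leakage and C_bs stay consistent; it is not a bare FBA bound.

## The stoichiometric core network

The two-cell network (83 metabolites, 108 reactions) carries, in both
cells: Calvin–Benson cycle (lumped regeneration), the full
photorespiratory cycle, GS/GOGAT ammonia refixation, nitrate uptake and
reduction, the NADP-ME-type C4 module (PEPC, PPDK, NADP-MDH, Ala-AT,
Asp-AT; NADP-ME in the bundle sheath), the phosphoserine pathway,
sucrose synthesis, a lumped anaplerotic 2-oxoglutarate synthesis,
pyruvate oxidation (PDH+TCA), linear and cyclic electron transport and a
mitochondrial NADH oxidase. Exactly 19 plasmodesmatal transport species
connect the cells — malate, pyruvate, 3-PGA, triose phosphate,
phosphate, sucrose, aspartate, alanine, PEP, CO2 and O2, plus serine,
glycine, glutamate, glutamine, asparagine, threonine, 2-oxoglutarate and
water. Ammonia is deliberately not transportable (it is toxic and
uncouples gradients), which is what creates the nitrogen-return problem.

Every internal reaction balances C, N, O, P and S exactly (protons are
not tracked); `check_balances` audits this and the builder ships with a
clean report. Cofactors use their full elemental formulas so that the
audit is meaningful.

Curation choices that shape the results, with their rationale:

- **Light is explicit.** A massless photon species is consumed by linear
  (8 hν per 2 NADPH, Z-scheme) and cyclic (≈2 hν per ATP) electron
  transport and enters through uptake reactions in both cells. Without
  photon accounting, ATP/NADPH are nearly free in the flux-minimization
  step and energy-expensive nitrogen routes are underpriced; with it,
  redox-neutral shuttles (e.g. aspartate/malate, which doubles as a
  malate-valve redox shuttle) are correctly favored.
- **Plastid-confined GS2/Fd-GOGAT.** Photorespiratory ammonia refixation
  is a lumped plastidic reaction (NH3 + 2-OG + ATP + NADH → Glu); the
  chloroplast envelope has no documented glutamine exporter (DiT1/DiT2
  carry 2-OG, glutamate and malate), so the refixation cycle's glutamine
  never reaches the cytosolic pool. A separate cytosolic glutamine
  synthetase (GS1) supplies transportable/biomass glutamine. Without
  this confinement a glutamine/2-oxoglutarate shuttle (two N per
  crossing) artifactually displaces the glutamate shuttle.
- **Canonical peroxisomal transamination.** The photorespiratory
  glyoxylate aminations run 1:1 from glutamate and serine as a lumped
  reaction; standalone GGT covers amination when serine is committed to
  export, and serine ammonia-lyase provides the mesophyll sink for
  nitrogen returned as serine. There is deliberately no standalone
  serine:glyoxylate route, which would let the bundle sheath over-return
  serine as a cut-price nitrogen carrier.
- **Asparagine synthetase** costs two ATP equivalents (ATP → AMP + PPi)
  and sits in the bundle sheath only (AS expression is
  phloem/vasculature-associated). Both facts matter: at one ATP, or
  present in the mesophyll, asparagine- and glutamine-based bypasses
  undercut the low-weight amino-acid shuttles.
- **Phloem loading is bundle-sheath-sided.** In Kranz anatomy the
  vasculature sits inside the bundle-sheath ring, so the biomass drain —
  sucrose and a fixed amino-acid mix at 5:1 molar sucrose:total amino
  acids, equal shares of Ala, Asp, Asn, Gln, Glu, Gly, Ser, Thr — pulls
  on bundle-sheath pools; mesophyll photosynthate reaches it as sucrose
  through the plasmodesmata. A drain fed from both cells lets biomass
  nitrogen free-ride on the obligate glycine flux and blurs the
  nitrogen-return bookkeeping.
- **Gas and water boundaries.** CO2 exchanges with the atmosphere only
  through the mesophyll; its inter-cell flux is the mechanistically
  constrained leak — CO2 containment *is* the concentrating mechanism.
  O2 and water, by contrast, have boundary exchanges in both cells
  (xylem water arrives inside the sheath; O2 equilibrates across the
  non-suberized C3–C4 sheath wall). Nitrogen enters as nitrate in either
  cell; GS/GOGAT reactions are irreversible; bundle-sheath PEPC is
  unconstrained (anaplerotic); there are no fixed starch or fatty-acid
  drains.

Flux caps default to ±1000 µmol s⁻¹ m⁻² — effectively unbounded at leaf
scale while keeping every LP bounded.

## The LP cascade

1. **FBA** — maximize biomass subject to S·v = 0 and the bounds
   (HiGHS dual simplex, feasibility tolerances 1e-9; deterministic).
   Because all carbon enters through the pinned net-CO2 uptake and can
   leave only through biomass, the optimum is carbon-determined and
   identical across transport scenarios.
2. **MTF** — minimize Σᵢ wᵢ·|vᵢ| with biomass pinned to the FBA optimum;
   wᵢ = 1.1 for plasmodesmatal reactions, 1 otherwise (the higher
   weight prices the trade-off between CO2 containment and inter-cell
   diffusion). |v| is linearized exactly by non-negative splitting
   v = v⁺ − v⁻.
3. **FVA** — per reaction, minimize and maximize vᵢ over the optimal set
   {biomass = optimum, Σ w|v| ≤ s_opt(1+1e-9)+1e-6}; at the minimum the
   inequality is equivalent to the equality and avoids knife-edge
   infeasibility.

Shuttle classification uses FVA-forced fluxes (the interval endpoint
nearer zero): a shuttle is reported only if every optimal solution
carries it past the 1 µmol s⁻¹ m⁻² reporting threshold. The forward
carbon leg of the phosphoserine route is the one exception — 3-PGA,
triose phosphate and PEP are mutually degenerate carriers, so their
summed point-solution flux is used while the pathway-defining markers
(phosphoserine phosphatase flux, serine return in excess of the C2
requirement) remain FVA-forced.

## Nitrogen bookkeeping

All nitrogen accounting is done from metabolite formulas × fluxes. The
per-cell ledger (nitrate in, biomass N out, net plasmodesmatal N) closes
to ≤1e-6 at steady state. The *nitrogen return* is the bundle-sheath
ledger closure: N carried BS→M over the plasmodesmata, plus biomass N
the bundle sheath retains net of its own nitrate uptake, minus the C2
serine share 0.5·ξ·V_om. It equals 0.5·ξ·V_om exactly when — and only
when — the optimal solution ships no nitrogen M→BS beyond the
mechanistically pinned glycine flux; it is therefore a non-trivial check
on both the solution and the atom bookkeeping, and holds to 1e-6 in all
five shipped scenarios.

## Scenarios and scans

The named scenarios progressively restrict which metabolites may diffuse
(blocked sets nested A ⊂ B ⊂ C ⊂ D): A blocks nothing; B closes
glutamate/2-oxoglutarate; C additionally alanine/pyruvate; D every
remaining nitrogen carrier except glycine and serine. C4 is scenario A's
transport freedom plus V_p = 2 µmol s⁻¹ m⁻² of C4-cycle activity (PEPC
activity of the order measured in C3 relatives). The C4-activity scan
re-runs the whole pipeline over V_p ∈ [0, 5] (11 points, FBA+MTF only);
the weight scan covers w ∈ [1.0, 2.0] by default and is extendable — on
this core network asparagine displaces the amino-acid shuttles at
w ≈ 9–10, consistent with its double nitrogen payload per crossing
(carrier activity is judged by nitrogen flux, molar flux × N atoms).

## What the core network does and does not capture

It is a curated stand-in for a genome-scale two-cell reconstruction at
roughly 5% of the reaction count: enough to reproduce the qualitative
predictions — shuttle identities per scenario, equal biomass across
transport scenarios, the ordering of minimal plasmodesmatal flux sums,
the linear biomass gain with C4 activity, the high-weight shift to
asparagine — but not the absolute plasmodesmatal flux sums printed for
the genome-scale model, which depend on its full biomass composition and
intracellular compartment transports. Passing tests therefore validate
the mechanism and the machinery, not genome-scale flux magnitudes. A
genuine SBML reconstruction can be loaded through `read_model` (SBML
L3+FBC; inter-cell reactions tagged by a compartment-pair rule) and run
through the identical pipeline.

Intra-cell compartments are labels, not barriers: each cell is one
metabolite pool except where a curation choice above says otherwise.
Charge and protons are not balanced. The LP cascade suppresses futile
cycles through the flux-minimization objective, not loop-law
constraints.

## Problem sizes

The default test-and-analysis configuration runs each scenario's full
cascade (2 + 2·108 LPs ≈ 1 s) and the scans at 11 grid points each;
the complete five-scenario study with FVA finishes in a few seconds on
one core.
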