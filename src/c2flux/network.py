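"""Builder for the curated two-cell core network.

This module constructs the synthetic stand-in for the modified C4GEM
reconstruction: a mesophyll/bundle-sheath leaf model carrying the
Calvin–Benson cycle, the full photorespiratory cycle, GS/GOGAT ammonia
refixation, the NADP-ME-type C4 module, the phosphoserine pathway,
electron transport, nitrate assimilation and a sucrose/amino-acid biomass
drain in both cell types, joined by exactly 19 plasmodesmatal transport
species.

Curation choices mirror the modifications applied to the published
reconstruction: no plasmodesmatal ammonia, linear electron transport and
plastidic NADP-MDH present in the bundle sheath, irreversible GS/GOGAT,
nitrogen entering as nitrate, bundle-sheath PEPC unconstrained, no fixed
starch or fatty-acid drains, and a sucrose:amino-acid output ratio of 5.

Ammonia refixation is split into a lumped plastidic GS2/Fd-GOGAT cycle
(``gsgogat``: NH3 + 2-OG + ATP + NADH -> Glu) and a cytosolic glutamine
synthetase (``gs1``) that feeds the transportable glutamine pool.  The
chloroplast envelope carries no documented glutamine exporter (the DiT1
and DiT2 translocators exchange 2-oxoglutarate, glutamate and malate), so
glutamine produced inside the photorespiratory refixation cycle is not
available to the cytosol; only GS1 product is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .model import BIG, Metabolite, Reaction, StoichiometricModel

# ---------------------------------------------------------------------------
# species definitions
# ---------------------------------------------------------------------------

#: formulas as element->count mappings (H kept for completeness; not balanced)
FORMULAS: Dict[str, Dict[str, int]] = {
    "co2": {"C": 1, "O": 2},
    "o2": {"O": 2},
    "h2o": {"H": 2, "O": 1},
    "pi": {"H": 1, "O": 4, "P": 1},
    "no3": {"N": 1, "O": 3},
    "nh3": {"H": 3, "N": 1},
    "atp": {"C": 10, "H": 16, "N": 5, "O": 13, "P": 3},
    "adp": {"C": 10, "H": 15, "N": 5, "O": 10, "P": 2},
    "nadp": {"C": 21, "H": 28, "N": 7, "O": 17, "P": 3},
    "nadph": {"C": 21, "H": 29, "N": 7, "O": 17, "P": 3},
    "nad": {"C": 21, "H": 27, "N": 7, "O": 14, "P": 2},
    "nadh": {"C": 21, "H": 28, "N": 7, "O": 14, "P": 2},
    "rubp": {"C": 5, "H": 12, "O": 11, "P": 2},
    "pga": {"C": 3, "H": 7, "O": 7, "P": 1},
    "tp": {"C": 3, "H": 7, "O": 6, "P": 1},
    "pg2": {"C": 2, "H": 5, "O": 6, "P": 1},
    "glycolate": {"C": 2, "H": 4, "O": 3},
    "glyoxylate": {"C": 2, "H": 2, "O": 3},
    "gly": {"C": 2, "H": 5, "N": 1, "O": 2},
    "ser": {"C": 3, "H": 7, "N": 1, "O": 3},
    "hpyr": {"C": 3, "H": 4, "O": 4},
    "glyc": {"C": 3, "H": 6, "O": 4},
    "suc": {"C": 12, "H": 22, "O": 11},
    "pep": {"C": 3, "H": 5, "O": 6, "P": 1},
    "pyr": {"C": 3, "H": 4, "O": 3},
    "oaa": {"C": 4, "H": 4, "O": 5},
    "mal": {"C": 4, "H": 6, "O": 5},
    "og": {"C": 5, "H": 6, "O": 5},
    "glu": {"C": 5, "H": 9, "N": 1, "O": 4},
    "gln": {"C": 5, "H": 10, "N": 2, "O": 3},
    "asp": {"C": 4, "H": 7, "N": 1, "O": 4},
    "asn": {"C": 4, "H": 8, "N": 2, "O": 3},
    "ala": {"C": 3, "H": 7, "N": 1, "O": 2},
    "thr": {"C": 4, "H": 9, "N": 1, "O": 3},
    "php": {"C": 3, "H": 5, "O": 7, "P": 1},
    "pser": {"C": 3, "H": 8, "N": 1, "O": 6, "P": 1},
    # massless energy carrier (all element counts zero)
    "photon": {"H": 0},
}

_NAMES = {
    "photon": "photon",
    "co2": "CO2", "o2": "O2", "h2o": "water", "pi": "orthophosphate",
    "no3": "nitrate", "nh3": "ammonia", "atp": "ATP", "adp": "ADP",
    "nadp": "NADP+", "nadph": "NADPH", "nad": "NAD+", "nadh": "NADH",
    "rubp": "ribulose-1,5-bisphosphate", "pga": "3-phosphoglycerate",
    "tp": "triose phosphate", "pg2": "2-phosphoglycolate",
    "glycolate": "glycolate", "glyoxylate": "glyoxylate", "gly": "glycine",
    "ser": "serine", "hpyr": "hydroxypyruvate", "glyc": "glycerate",
    "suc": "sucrose", "pep": "phosphoenolpyruvate", "pyr": "pyruvate",
    "oaa": "oxaloacetate", "mal": "malate", "og": "2-oxoglutarate",
    "glu": "glutamate", "gln": "glutamine", "asp": "aspartate",
    "asn": "asparagine", "ala": "alanine", "thr": "threonine",
    "php": "3-phosphohydroxypyruvate", "pser": "O-phospho-L-serine",
}

_COMPARTMENT = {
    "rubp": "chloroplast", "pg2": "chloroplast", "php": "chloroplast",
    "pser": "chloroplast", "photon": "chloroplast",
    "glycolate": "peroxisome", "glyoxylate": "peroxisome",
    "hpyr": "peroxisome", "glyc": "peroxisome",
}

#: the 19 plasmodesmatal transport species: the 11 from the original
#: reconstruction (malate, pyruvate, 3-PGA, trioses, phosphates, sucrose,
#: aspartate, alanine, PEP, CO2, O2) plus the 8 added ones (serine,
#: glycine, glutamate, glutamine, asparagine, threonine, 2-oxoglutarate,
#: water).  Ammonia is deliberately absent.
PLASMODESMATAL_SPECIES: Tuple[str, ...] = (
    "mal", "pyr", "pga", "tp", "pi", "suc", "asp", "ala", "pep", "co2", "o2",
    "ser", "gly", "glu", "gln", "asn", "thr", "og", "h2o",
)

#: species name -> nitrogen atoms, for scenario blocking of N carriers
NITROGEN_TRANSPORT_SPECIES: Tuple[str, ...] = tuple(
    s for s in PLASMODESMATAL_SPECIES if FORMULAS[s].get("N", 0) > 0
)

#: amino acids available to the biomass drain
BIOMASS_AMINO_ACIDS: Tuple[str, ...] = (
    "ala", "asp", "asn", "gln", "glu", "gly", "ser", "thr",
)

DEFAULT_PLASMODESMATAL_WEIGHT = 1.1


@dataclass
class BiomassSpec:
    """Molar sucrose : total amino-acid output ratio and the amino-acid mix."""

    sucrose_to_amino_acid_ratio: float = 5.0
    amino_acid_mix: Dict[str, float] = field(
        default_factory=lambda: {aa: 1.0 / len(BIOMASS_AMINO_ACIDS) for aa in BIOMASS_AMINO_ACIDS}
    )

    def __post_init__(self) -> None:
        if self.sucrose_to_amino_acid_ratio <= 0:
            raise ValueError("sucrose:amino-acid ratio must be positive")
        total = sum(self.amino_acid_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"amino-acid shares must sum to 1 (got {total})")
        for aa in self.amino_acid_mix:
            if aa not in BIOMASS_AMINO_ACIDS:
                raise ValueError(f"unknown biomass amino acid {aa!r}")


# ---------------------------------------------------------------------------
# per-cell reaction table
# ---------------------------------------------------------------------------

# (id, name, {species: coef}, reversible, block); species ids are per-cell
# and receive the _m / _bs suffix at build time.
_CELL_REACTIONS = [
    # light reactions and redox bookkeeping; photon costs follow the
    # Z-scheme (2 quanta per electron: 8 per 2 NADPH) and ~2 quanta per
    # ATP for PSI cyclic flow
    ("let", "linear electron transport (PSII+PSI)",
     {"photon": -8, "h2o": -2, "nadp": -2, "o2": 1, "nadph": 2},
     False, "electron_transport"),
    ("cet", "cyclic electron transport photophosphorylation",
     {"photon": -2, "adp": -1, "pi": -1, "atp": 1, "h2o": 1},
     False, "electron_transport"),
    ("oxphos", "mitochondrial NADH oxidation",
     {"nadh": -1, "o2": -0.5, "adp": -2, "pi": -2, "nad": 1, "atp": 2, "h2o": 3},
     False, "electron_transport"),
    ("nadtrans", "NADPH/NADH redox shuttle",
     {"nadph": -1, "nad": -1, "nadp": 1, "nadh": 1}, True, "electron_transport"),
    # Calvin-Benson cycle
    ("rbc", "Rubisco carboxylase",
     {"rubp": -1, "co2": -1, "h2o": -1, "pga": 2}, False, "calvin"),
    ("rbo", "Rubisco oxygenase",
     {"rubp": -1, "o2": -1, "pga": 1, "pg2": 1}, False, "calvin"),
    ("pgared", "phosphoglycerate reduction (PGK+GAPDH)",
     {"pga": -1, "atp": -1, "nadph": -1, "tp": 1, "adp": 1, "pi": 1, "nadp": 1},
     False, "calvin"),
    ("rregen", "RuBP regeneration (lumped)",
     {"tp": -5, "atp": -3, "h2o": -2, "rubp": 3, "adp": 3, "pi": 2},
     False, "calvin"),
    # photorespiratory cycle
    ("pglp", "2-phosphoglycolate phosphatase",
     {"pg2": -1, "h2o": -1, "glycolate": 1, "pi": 1}, False, "photorespiration"),
    ("gox", "glycolate oxidase (+catalase)",
     {"glycolate": -1, "o2": -0.5, "glyoxylate": 1, "h2o": 1}, False, "photorespiration"),
    # GGT and SGAT run 1:1 in the canonical photorespiratory cycle (per
    # two glyoxylates, one amination from glutamate and one from serine);
    # the lumped reaction enforces that coupling.  Standalone GGT covers
    # glyoxylate amination when serine is committed elsewhere (e.g. to
    # phloem export); there is no standalone serine-consuming route, so
    # serine cannot be over-returned as a cut-price nitrogen carrier.
    ("pramn", "peroxisomal glyoxylate transamination (GGT + SGAT, lumped)",
     {"glyoxylate": -2, "glu": -1, "ser": -1, "gly": 2, "og": 1, "hpyr": 1},
     False, "photorespiration"),
    ("ggt", "glutamate:glyoxylate aminotransferase",
     {"glyoxylate": -1, "glu": -1, "gly": 1, "og": 1},
     False, "photorespiration"),
    ("gdc", "glycine decarboxylase complex (+SHMT)",
     {"gly": -2, "nad": -1, "h2o": -1, "ser": 1, "co2": 1, "nh3": 1, "nadh": 1},
     False, "photorespiration"),
    ("hpr", "hydroxypyruvate reductase",
     {"hpyr": -1, "nadh": -1, "glyc": 1, "nad": 1}, False, "photorespiration"),
    ("glyk", "glycerate 3-kinase",
     {"glyc": -1, "atp": -1, "pga": 1, "adp": 1}, False, "photorespiration"),
    # central carbon
    ("sucs", "sucrose synthesis from triose phosphate (lumped)",
     {"tp": -4, "h2o": -3, "suc": 1, "pi": 4}, False, "central_carbon"),
    ("pgm", "phosphoglycerate mutase + enolase",
     {"pga": -1, "pep": 1, "h2o": 1}, True, "central_carbon"),
    ("pk", "pyruvate kinase",
     {"pep": -1, "adp": -1, "pyr": 1, "atp": 1}, False, "central_carbon"),
    ("ogsyn", "2-oxoglutarate synthesis (CS+aconitase+IDH, lumped)",
     {"pyr": -1, "oaa": -1, "nad": -2, "h2o": -1, "og": 1, "co2": 2, "nadh": 2},
     False, "central_carbon"),
    ("resp", "pyruvate oxidation (PDH + TCA cycle, lumped)",
     {"pyr": -1, "h2o": -3, "nad": -5, "co2": 3, "nadh": 5},
     False, "central_carbon"),
    # C4 module (NADP-ME type)
    ("pepc", "PEP carboxylase",
     {"pep": -1, "co2": -1, "h2o": -1, "oaa": 1, "pi": 1}, False, "c4_cycle"),
    ("ppdk", "pyruvate orthophosphate dikinase (lumped, 2 ATP equiv.)",
     {"pyr": -1, "atp": -2, "h2o": -1, "pep": 1, "adp": 2, "pi": 1},
     False, "c4_cycle"),
    ("mdh", "plastidic NADP-malate dehydrogenase",
     {"oaa": -1, "nadph": -1, "mal": 1, "nadp": 1}, True, "c4_cycle"),
    ("alaat", "alanine aminotransferase",
     {"pyr": -1, "glu": -1, "ala": 1, "og": 1}, True, "c4_cycle"),
    ("aspat", "aspartate aminotransferase",
     {"oaa": -1, "glu": -1, "asp": 1, "og": 1}, True, "c4_cycle"),
    # phosphoserine pathway
    ("pgdh", "3-phosphoglycerate dehydrogenase",
     {"pga": -1, "nad": -1, "php": 1, "nadh": 1}, False, "phosphoserine"),
    ("psat", "phosphoserine aminotransferase",
     {"php": -1, "glu": -1, "pser": 1, "og": 1}, False, "phosphoserine"),
    ("psp", "phosphoserine phosphatase",
     {"pser": -1, "h2o": -1, "ser": 1, "pi": 1}, False, "phosphoserine"),
    # ammonia refixation (irreversible by construction)
    ("gsgogat", "plastidic GS2/Fd-GOGAT cycle (lumped)",
     {"nh3": -1, "og": -1, "atp": -1, "nadh": -1,
      "glu": 1, "adp": 1, "pi": 1, "nad": 1}, False, "gs_gogat"),
    ("gs1", "cytosolic glutamine synthetase",
     {"glu": -1, "nh3": -1, "atp": -1, "gln": 1, "adp": 1, "pi": 1},
     False, "gs_gogat"),
    # amino-acid metabolism
    ("asnase", "asparaginase",
     {"asn": -1, "h2o": -1, "asp": 1, "nh3": 1}, False, "amino_acid"),
    ("serd", "serine ammonia-lyase",
     {"ser": -1, "pyr": 1, "nh3": 1}, False, "amino_acid"),
    ("thrs", "threonine synthesis from aspartate (lumped)",
     {"asp": -1, "atp": -2, "nadph": -2, "h2o": -1,
      "thr": 1, "adp": 2, "pi": 2, "nadp": 2}, False, "amino_acid"),
    # nitrate assimilation
    ("nr", "nitrate + nitrite reductase (lumped)",
     {"no3": -1, "nadph": -4, "nh3": 1, "h2o": 3, "nadp": 4},
     False, "nitrate_assimilation"),
]

_BS_ONLY = [
    ("me", "NADP-dependent malic enzyme",
     {"mal": -1, "nadp": -1, "pyr": 1, "co2": 1, "nadph": 1}, False, "c4_cycle"),
    # asparagine synthetase is phloem/vasculature-associated, hence
    # bundle-sheath only; it hydrolyzes ATP to AMP + PPi (2 ATP equiv.)
    ("asns", "asparagine synthetase (ATP -> AMP + PPi)",
     {"asp": -1, "gln": -1, "atp": -2, "h2o": -2,
      "asn": 1, "glu": 1, "adp": 2, "pi": 2}, False, "amino_acid"),
]

PATHWAY_BLOCKS: Tuple[str, ...] = (
    "electron_transport", "calvin", "photorespiration", "central_carbon",
    "c4_cycle", "phosphoserine", "gs_gogat", "amino_acid",
    "nitrate_assimilation",
)

#: reactions forming the CO2-concentrating C4 pump proper (bounds-blocked for
#: the C3-operation feasibility check); bundle-sheath PEPC stays open
#: (anaplerotic) and the basal aminotransferases stay open.
CCM_REACTION_IDS: Tuple[str, ...] = (
    "pepc_m", "ppdk_m", "ppdk_bs", "mdh_m", "mdh_bs", "me_bs",
)

PHOSPHOSERINE_REACTION_IDS: Tuple[str, ...] = (
    "pgdh_m", "pgdh_bs", "psat_m", "psat_bs", "psp_m", "psp_bs",
)


def transport_id(species: str) -> str:
    return f"tx_{species}"


def build_core_model(
    biomass: Optional[BiomassSpec] = None,
    blocks: Optional[Iterable[str]] = None,
    plasmodesmatal_weight: float = DEFAULT_PLASMODESMATAL_WEIGHT,
) -> StoichiometricModel:
    """Construct the default two-cell core model.

    Parameters
    ----------
    biomass:
        Sucrose:amino-acid drain specification (default ratio 5, equal
        molar shares over the eight transportable amino acids).
    blocks:
        Pathway blocks to include (default: all of ``PATHWAY_BLOCKS``).
        Unknown names raise ``ValueError``.
    plasmodesmatal_weight:
        MTF weight on the inter-cell transport reactions (default 1.1).
    """
    biomass = biomass or BiomassSpec()
    if blocks is None:
        use_blocks = set(PATHWAY_BLOCKS)
    else:
        use_blocks = set(blocks)
        unknown = use_blocks - set(PATHWAY_BLOCKS)
        if unknown:
            raise ValueError(f"unknown pathway block(s): {sorted(unknown)}")

    mets: List[Metabolite] = []
    rxns: List[Reaction] = []

    def add_rxn(r: Reaction) -> None:
        rxns.append(r)

    # metabolite pools ----------------------------------------------------
    for suffix, cell in (("m", "mesophyll"), ("bs", "bundle_sheath")):
        for sp in sorted(FORMULAS):
            mets.append(
                Metabolite(
                    id=f"{sp}_{suffix}",
                    name=f"{_NAMES[sp]} ({cell})",
                    cell=cell,
                    compartment=_COMPARTMENT.get(sp, "cytosol"),
                    formula=FORMULAS[sp],
                )
            )
    for sp in ("suc",) + BIOMASS_AMINO_ACIDS:
        mets.append(
            Metabolite(
                id=f"{sp}_sh",
                name=f"{_NAMES[sp]} (phloem export pool)",
                cell="shared",
                compartment="apoplast",
                formula=FORMULAS[sp],
            )
        )

    # per-cell reactions --------------------------------------------------
    all_cell_rxns = list(_CELL_REACTIONS)
    for suffix, cell in (("m", "mesophyll"), ("bs", "bundle_sheath")):
        table = all_cell_rxns + (list(_BS_ONLY) if suffix == "bs" else [])
        for rid, name, stoich, reversible, block in table:
            if block not in use_blocks:
                continue
            add_rxn(
                Reaction(
                    id=f"{rid}_{suffix}",
                    name=f"{name} [{cell}]",
                    stoichiometry={f"{sp}_{suffix}": c for sp, c in stoich.items()},
                    cell=cell,
                    lower_bound=-BIG if reversible else 0.0,
                    upper_bound=BIG,
                    reversible=reversible,
                )
            )
        # nitrate uptake accompanies the assimilation block
        if "nitrate_assimilation" in use_blocks:
            add_rxn(
                Reaction(
                    id=f"ex_no3_{suffix}",
                    name=f"nitrate uptake [{cell}]",
                    stoichiometry={f"no3_{suffix}": 1},
                    cell="boundary",
                    lower_bound=0.0,
                    upper_bound=BIG,
                    is_boundary=True,
                )
            )

    # atmospheric / apoplastic exchange.  CO2 reaches the bundle sheath
    # only through the mesophyll (its containment is the CO2-concentrating
    # mechanism and its inter-cell flux is mechanistically constrained),
    # but water arrives via the xylem inside the bundle-sheath ring and O2
    # equilibrates across the non-suberized C3-C4 sheath wall, so both
    # cells carry O2/H2O exchanges.
    for sp, suffixes in (
        ("co2", ("m",)),
        ("o2", ("m", "bs")),
        ("h2o", ("m", "bs")),
        ("photon", ("m", "bs")),
    ):
        for sfx in suffixes:
            uptake_only = sp == "photon"
            add_rxn(
                Reaction(
                    id=f"ex_{sp}_{sfx}",
                    name=f"{_NAMES[sp]} exchange [{sfx}]",
                    stoichiometry={f"{sp}_{sfx}": 1},
                    cell="boundary",
                    lower_bound=0.0 if uptake_only else -BIG,
                    upper_bound=BIG,
                    reversible=not uptake_only,
                    is_boundary=True,
                )
            )

    # plasmodesmatal transports (positive = mesophyll -> bundle sheath) ---
    for sp in PLASMODESMATAL_SPECIES:
        add_rxn(
            Reaction(
                id=transport_id(sp),
                name=f"plasmodesmatal {_NAMES[sp]} transport (M->BS)",
                stoichiometry={f"{sp}_m": -1, f"{sp}_bs": 1},
                cell="inter_cell",
                lower_bound=-BIG,
                upper_bound=BIG,
                mtf_weight=plasmodesmatal_weight,
                is_plasmodesmatal=True,
                reversible=True,
            )
        )

    # phloem export and the biomass drain.  The vasculature lies inside the
    # bundle-sheath ring in Kranz anatomy, so phloem loading draws on the
    # bundle-sheath pools only; mesophyll photosynthate reaches the drain
    # through the plasmodesmata (sucrose being the efficient carbon carrier).
    for sp in ("suc",) + BIOMASS_AMINO_ACIDS:
        add_rxn(
            Reaction(
                id=f"exp_{sp}_bs",
                name=f"phloem loading of {_NAMES[sp]} [bundle sheath]",
                stoichiometry={f"{sp}_bs": -1, f"{sp}_sh": 1},
                cell="bundle_sheath",
            )
        )
    bm_stoich: Dict[str, float] = {
        "suc_sh": -biomass.sucrose_to_amino_acid_ratio,
    }
    for aa, share in sorted(biomass.amino_acid_mix.items()):
        if share > 0:
            bm_stoich[f"{aa}_sh"] = -share
    add_rxn(
        Reaction(
            id="biomass",
            name="leaf biomass output (sucrose + amino-acid mix)",
            stoichiometry=bm_stoich,
            cell="boundary",
            is_boundary=True,
            is_biomass=True,
        )
    )

    rxns.sort(key=lambda r: r.id)
    mets.sort(key=lambda m: m.id)
    return StoichiometricModel(mets, rxns, objective={"biomass": 1.0}, name="c2_core")


def blocked_n_transport_ids() -> List[str]:
    """Transport ids of the nitrogen carriers other than glycine/serine."""
    return [
        transport_id(sp)
        for sp in NITROGEN_TRANSPORT_SPECIES
        if sp not in ("gly", "ser")
    ]
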