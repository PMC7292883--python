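"""Deterministic generators for every input the pipeline consumes.

The centerpiece is a toy aerobic diazotroph: a three-compartment
(c/p/e) network with glucose, fructose and pyruvate uptake, lumped
glycolysis and Entner-Doudoroff routes, a lumped TCA cycle and oxidative
phosphorylation, the canonical Mo-nitrogenase equation (N2 + 8 H+ +
8 e- + 16 ATP -> 2 NH3 + H2, electrons delivered by a lumped one-electron
ferredoxin couple fed from NADH), ammonium assimilation through a net
GS/GOGAT reaction, a six-reaction alginate branch ending in periplasmic
mannuronate monomer secretion, and a three-reaction PHB branch from
acetoacetyl-CoA.  Every internal reaction is element- and charge-balanced
by construction, so the QC suite is fully green on the defect-free model;
named defects (an unbalanced reaction, a free-ATP cycle, an orphan
metabolite) can be injected for negative tests, each tripping exactly one
QC check.

The other generators emit Biolog-style plates with ground-truth growth
calls, proteomes of known amino-acid composition, and homology-hit
tables stratified over all accept/reject combinations of the curation
thresholds.  Every generator is a pure function of its arguments and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .biomass import build_alginate_bof, build_bof
from .core_model import (
    DEFAULT_BOUND,
    DiazogemError,
    GprTree,
    Medium,
    MetabolicModel,
    Metabolite,
    ReactionRecord,
)
from .reconstruction import HomologyHit

__all__ = [
    "ToyManifest",
    "make_toy_diazotroph",
    "GLUCOSE_NH4_MEDIUM",
    "GLUCOSE_N2_MEDIUM",
    "toy_medium",
    "PlateResult",
    "make_plate",
    "ProteomeResult",
    "make_proteome",
    "write_proteome_fasta",
    "HomologyTable",
    "make_homology_table",
]

DEFECTS = ("unbalanced", "atp_cycle", "orphan_metabolite")

#: alginate monomer coefficient of the second biomass function, mmol/gDW
ALGINATE_BOF_COEFFICIENT = 0.5

# -- metabolite table: id stem -> (name, formula, charge) -------------------
_METS: Dict[str, Tuple[str, str, int]] = {
    "glc__D": ("D-glucose", "C6H12O6", 0),
    "fru": ("D-fructose", "C6H12O6", 0),
    "pyr": ("pyruvate", "C3H3O3", -1),
    "o2": ("oxygen", "O2", 0),
    "co2": ("carbon dioxide", "CO2", 0),
    "h2o": ("water", "H2O", 0),
    "h": ("proton", "H", 1),
    "nh4": ("ammonium", "H4N", 1),
    "n2": ("dinitrogen", "N2", 0),
    "h2": ("dihydrogen", "H2", 0),
    "atp": ("ATP", "C10H12N5O13P3", -4),
    "adp": ("ADP", "C10H12N5O10P2", -3),
    "pi": ("phosphate", "HO4P", -2),
    "ppi": ("diphosphate", "HO7P2", -3),
    "nad": ("NAD+", "C21H26N7O14P2", -1),
    "nadh": ("NADH", "C21H27N7O14P2", -2),
    "nadp": ("NADP+", "C21H25N7O17P3", -3),
    "nadph": ("NADPH", "C21H26N7O17P3", -4),
    "coa": ("coenzyme A", "C21H32N7O16P3S", -4),
    "accoa": ("acetyl-CoA", "C23H34N7O17P3S", -4),
    "aacoa": ("acetoacetyl-CoA", "C25H36N7O18P3S", -4),
    "hbcoa": ("(R)-3-hydroxybutyryl-CoA", "C25H38N7O18P3S", -4),
    "phb": ("PHB monomer unit", "C4H6O2", 0),
    "oaa": ("oxaloacetate", "C4H2O5", -2),
    "akg": ("2-oxoglutarate", "C5H4O5", -2),
    "glu__L": ("L-glutamate", "C5H8NO4", -1),
    "g6p": ("glucose 6-phosphate", "C6H11O9P", -2),
    "man6p": ("mannose 6-phosphate", "C6H11O9P", -2),
    "man1p": ("mannose 1-phosphate", "C6H11O9P", -2),
    "gtp": ("GTP", "C10H12N5O14P3", -4),
    "gdp": ("GDP", "C10H12N5O11P2", -3),
    "gdpmann": ("GDP-D-mannose", "C16H23N5O16P2", -2),
    "gdpmannur": ("GDP-D-mannuronate", "C16H20N5O17P2", -3),
    "alg": ("alginate (mannuronate unit)", "C6H9O7", -1),
    "fdxox": ("oxidized ferredoxin", "Fe2S2", 2),
    "fdxrd": ("reduced ferredoxin", "Fe2S2", 1),
}


@dataclass
class ToyManifest:
    """Exact description of the emitted toy model, checked in tests."""

    reactions: int
    metabolites: int
    genes: int
    subsystems: List[str]
    growth_truth: Dict[str, bool]
    internal_reactions_balanced: bool
    defects: List[str] = field(default_factory=list)
    defect_reactions: Dict[str, str] = field(default_factory=dict)
    defect_metabolites: Dict[str, str] = field(default_factory=dict)
    alginate_reactions: List[str] = field(default_factory=list)
    phb_reactions: List[str] = field(default_factory=list)
    nitrogenase_reaction: str = "NIT"
    nitrogenase_genes: List[str] = field(default_factory=list)


def _mineral_exchanges() -> Medium:
    return {
        "EX_o2_e": (-DEFAULT_BOUND, DEFAULT_BOUND),
        "EX_co2_e": (0.0, DEFAULT_BOUND),
        "EX_h2o_e": (-DEFAULT_BOUND, DEFAULT_BOUND),
        "EX_h_e": (-DEFAULT_BOUND, DEFAULT_BOUND),
        "EX_h2_e": (0.0, DEFAULT_BOUND),
        "EX_alg_e": (0.0, DEFAULT_BOUND),
    }


def toy_medium(
    carbon: Optional[str] = "EX_glc__D_e",
    uptake: float = 10.0,
    diazotrophic: bool = False,
) -> Medium:
    """Medium for the toy model: mineral base, one carbon source, and
    ammonium or N2 as nitrogen source."""
    medium = _mineral_exchanges()
    if carbon is not None:
        medium[carbon] = (-abs(uptake), DEFAULT_BOUND)
    if diazotrophic:
        medium["EX_n2_e"] = (-DEFAULT_BOUND, DEFAULT_BOUND)
        medium["EX_nh4_e"] = (0.0, DEFAULT_BOUND)
    else:
        medium["EX_nh4_e"] = (-DEFAULT_BOUND, DEFAULT_BOUND)
        medium["EX_n2_e"] = (0.0, DEFAULT_BOUND)
    return medium


GLUCOSE_NH4_MEDIUM = toy_medium("EX_glc__D_e", 10.0, diazotrophic=False)
GLUCOSE_N2_MEDIUM = toy_medium("EX_glc__D_e", 10.0, diazotrophic=True)


def make_toy_diazotroph(
    seed: int = 0, defects: Optional[Iterable[str]] = None
) -> Tuple[MetabolicModel, ToyManifest]:
    """Build the toy diazotroph model and its manifest.

    The network is fixed (the seed only keeps the generator signature
    uniform with the stochastic generators); re-running with the same
    arguments yields an identical model.
    """
    defects = list(defects or [])
    unknown = sorted(set(defects) - set(DEFECTS))
    if unknown:
        raise DiazogemError(f"unknown defects {unknown}; available: {DEFECTS}")

    model = MetabolicModel(id="toy_diazotroph")
    for stem, (name, formula, charge) in _METS.items():
        compartments = ["c"]
        if stem in ("glc__D", "fru", "pyr", "o2", "co2", "h2o", "h", "nh4", "n2", "h2"):
            compartments.append("e")
        if stem == "alg":
            compartments = ["p", "e"]
        for comp in compartments:
            model.add_metabolite(
                Metabolite(
                    id=f"{stem}_{comp}",
                    name=name,
                    formula=formula,
                    charge=charge,
                    compartment=comp,
                )
            )

    g = GprTree.leaf
    A, O = GprTree.all_of, GprTree.any_of

    def add(
        rid: str,
        stoich: Dict[str, float],
        lb: float,
        ub: float,
        subsystem: str,
        gpr: Optional[GprTree] = None,
        name: str = "",
        provenance: str = "native",
    ) -> None:
        model.add_reaction(
            ReactionRecord(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                name=name or rid,
                subsystem=subsystem,
                gpr=gpr,
                provenance=provenance,
            )
        )

    # -- exchanges (defaults encode the glucose/ammonium condition) --------
    EX = "Exchange"
    add("EX_glc__D_e", {"glc__D_e": -1}, -10.0, DEFAULT_BOUND, EX, name="glucose exchange")
    add("EX_fru_e", {"fru_e": -1}, 0.0, DEFAULT_BOUND, EX, name="fructose exchange")
    add("EX_pyr_e", {"pyr_e": -1}, 0.0, DEFAULT_BOUND, EX, name="pyruvate exchange")
    add("EX_o2_e", {"o2_e": -1}, -DEFAULT_BOUND, DEFAULT_BOUND, EX, name="O2 exchange")
    add("EX_co2_e", {"co2_e": -1}, 0.0, DEFAULT_BOUND, EX, name="CO2 exchange")
    add("EX_h2o_e", {"h2o_e": -1}, -DEFAULT_BOUND, DEFAULT_BOUND, EX, name="water exchange")
    add("EX_h_e", {"h_e": -1}, -DEFAULT_BOUND, DEFAULT_BOUND, EX, name="proton exchange")
    add("EX_nh4_e", {"nh4_e": -1}, -DEFAULT_BOUND, DEFAULT_BOUND, EX, name="ammonium exchange")
    add("EX_n2_e", {"n2_e": -1}, 0.0, DEFAULT_BOUND, EX, name="N2 exchange")
    add("EX_h2_e", {"h2_e": -1}, 0.0, DEFAULT_BOUND, EX, name="H2 exchange")
    add("EX_alg_e", {"alg_e": -1}, 0.0, DEFAULT_BOUND, EX, name="alginate exchange")

    # -- transport ---------------------------------------------------------
    TR = "Transport"
    add("GLCt", {"glc__D_e": -1, "glc__D_c": 1}, 0.0, DEFAULT_BOUND, TR, g("ptsG"))
    add("FRUt", {"fru_e": -1, "fru_c": 1}, 0.0, DEFAULT_BOUND, TR, g("fruA"))
    add("PYRt", {"pyr_e": -1, "pyr_c": 1}, 0.0, DEFAULT_BOUND, TR)
    add("O2t", {"o2_e": -1, "o2_c": 1}, -DEFAULT_BOUND, DEFAULT_BOUND, TR)
    add("CO2t", {"co2_c": -1, "co2_e": 1}, -DEFAULT_BOUND, DEFAULT_BOUND, TR)
    add("H2Ot", {"h2o_e": -1, "h2o_c": 1}, -DEFAULT_BOUND, DEFAULT_BOUND, TR)
    add("Ht", {"h_e": -1, "h_c": 1}, -DEFAULT_BOUND, DEFAULT_BOUND, TR)
    add("NH4t", {"nh4_e": -1, "nh4_c": 1}, 0.0, DEFAULT_BOUND, TR, g("amtB"))
    add("N2t", {"n2_e": -1, "n2_c": 1}, 0.0, DEFAULT_BOUND, TR)
    add("H2t", {"h2_c": -1, "h2_e": 1}, 0.0, DEFAULT_BOUND, TR)

    # -- central carbon metabolism (lumped, balanced) ----------------------
    CH = "Carbohydrate metabolism"
    add(
        "GLYC",
        {"glc__D_c": -1, "nad_c": -2, "adp_c": -2, "pi_c": -2,
         "pyr_c": 2, "nadh_c": 2, "h_c": 2, "atp_c": 2, "h2o_c": 2},
        0.0, DEFAULT_BOUND, CH, A(g("gly1"), g("gly2")), name="glycolysis (lumped)",
    )
    add(
        "ED",
        {"glc__D_c": -1, "nad_c": -1, "nadp_c": -1, "adp_c": -1, "pi_c": -1,
         "pyr_c": 2, "nadh_c": 1, "nadph_c": 1, "atp_c": 1, "h2o_c": 1, "h_c": 3},
        0.0, DEFAULT_BOUND, CH, A(g("ed1"), g("ed2")),
        name="Entner-Doudoroff route (lumped)",
    )
    add("FRUI", {"fru_c": -1, "glc__D_c": 1}, 0.0, DEFAULT_BOUND, CH, g("fruI"))
    add(
        "HEXK",
        {"glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1},
        0.0, DEFAULT_BOUND, CH, g("hexK"), name="hexokinase",
    )

    TCA = "TCA cycle"
    add(
        "PDH",
        {"pyr_c": -1, "coa_c": -1, "nad_c": -1,
         "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
        0.0, DEFAULT_BOUND, TCA, A(g("pdhA"), g("pdhB")), name="pyruvate dehydrogenase",
    )
    add(
        "TCAL",
        {"accoa_c": -1, "nad_c": -4, "adp_c": -1, "pi_c": -1, "h2o_c": -2,
         "coa_c": 1, "co2_c": 2, "nadh_c": 4, "atp_c": 1, "h_c": 3},
        0.0, DEFAULT_BOUND, TCA, g("tcaL"), name="TCA cycle (lumped)",
    )
    add(
        "PC",
        {"pyr_c": -1, "co2_c": -1, "atp_c": -1, "h2o_c": -1,
         "oaa_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 2},
        0.0, DEFAULT_BOUND, TCA, g("pycA"), name="pyruvate carboxylase",
    )
    add(
        "CSIDH",
        {"accoa_c": -1, "oaa_c": -1, "h2o_c": -1, "nadp_c": -1,
         "akg_c": 1, "coa_c": 1, "co2_c": 1, "nadph_c": 1, "h_c": 1},
        0.0, DEFAULT_BOUND, TCA, O(g("icd1"), g("icd2")),
        name="citrate synthase + isocitrate dehydrogenase (lumped)",
    )

    add(
        "OXPHOS",
        {"nadh_c": -1, "o2_c": -0.5, "adp_c": -2, "pi_c": -2, "h_c": -3,
         "nad_c": 1, "atp_c": 2, "h2o_c": 3},
        0.0, DEFAULT_BOUND, "Oxidative phosphorylation",
        A(g("nuoA"), g("atpA")), name="respiratory chain + ATP synthase (lumped)",
    )

    add(
        "ATPM",
        {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
        0.0, DEFAULT_BOUND, "Biomass and maintenance", None,
        name="non-growth-associated maintenance",
    )

    AA = "Amino acid metabolism"
    add(
        "GSGOGAT",
        {"nh4_c": -1, "akg_c": -1, "nadph_c": -1, "atp_c": -1,
         "glu__L_c": 1, "nadp_c": 1, "adp_c": 1, "pi_c": 1},
        0.0, DEFAULT_BOUND, AA, A(g("glnA"), g("gltB")), name="GS/GOGAT (net)",
    )

    NIT = "Nitrogen metabolism"
    add(
        "FDNR",
        {"nadh_c": -1, "fdxox_c": -2, "nad_c": 1, "h_c": 1, "fdxrd_c": 2},
        0.0, DEFAULT_BOUND, NIT, g("fdxR"), name="ferredoxin-NAD+ reductase",
    )
    nif_genes = ["nifH", "nifD", "nifK"]
    add(
        "NIT",
        {"n2_c": -1, "fdxrd_c": -8, "atp_c": -16, "h2o_c": -16,
         "nh4_c": 2, "h2_c": 1, "fdxox_c": 8, "adp_c": 16, "pi_c": 16, "h_c": 6},
        0.0, DEFAULT_BOUND, NIT, A(*(g(x) for x in nif_genes)),
        name="Mo-nitrogenase (lumped)",
    )

    GB = "Glycan biosynthesis"
    add("PMI", {"g6p_c": -1, "man6p_c": 1}, 0.0, DEFAULT_BOUND, GB, g("algA1"),
        name="phosphohexose isomerase (lumped)")
    add("PMM", {"man6p_c": -1, "man1p_c": 1}, 0.0, DEFAULT_BOUND, GB, g("algC"),
        name="phosphomannomutase")
    add(
        "MAN1PG",
        {"man1p_c": -1, "gtp_c": -1, "h_c": -1, "gdpmann_c": 1, "ppi_c": 1},
        0.0, DEFAULT_BOUND, GB, g("algA2"), name="GDP-mannose pyrophosphorylase",
    )
    add(
        "GMD",
        {"gdpmann_c": -1, "nad_c": -2, "h2o_c": -1,
         "gdpmannur_c": 1, "nadh_c": 2, "h_c": 3},
        0.0, DEFAULT_BOUND, GB, g("algD"), name="GDP-mannose 6-dehydrogenase",
    )
    add(
        "ALGE",
        {"gdpmannur_c": -1, "h2o_c": -1, "alg_p": 1, "gdp_c": 1, "h_c": 1},
        0.0, DEFAULT_BOUND, GB, A(g("algE"), g("algG"), g("alg8")),
        name="alginate polymerase/epimerase + periplasmic export (lumped)",
    )
    add("ALGt", {"alg_p": -1, "alg_e": 1}, 0.0, DEFAULT_BOUND, GB, g("algJ"),
        name="alginate secretion")

    CF = "Cofactor and vitamin metabolism"
    add("NDPK", {"atp_c": -1, "gdp_c": -1, "adp_c": 1, "gtp_c": 1},
        -DEFAULT_BOUND, DEFAULT_BOUND, CF, g("ndk"), name="nucleoside-diphosphate kinase")
    add("PPA", {"ppi_c": -1, "h2o_c": -1, "pi_c": 2, "h_c": 1},
        0.0, DEFAULT_BOUND, CF, None, name="inorganic pyrophosphatase",
        provenance="orphan")

    SM = "Secondary metabolites biosynthesis"
    add("PHAA", {"accoa_c": -2, "aacoa_c": 1, "coa_c": 1},
        0.0, DEFAULT_BOUND, SM, g("phbA"), name="beta-ketothiolase")
    add(
        "PHAB",
        {"aacoa_c": -1, "nadph_c": -1, "h_c": -1, "hbcoa_c": 1, "nadp_c": 1},
        0.0, DEFAULT_BOUND, SM, g("phbB"), name="acetoacetyl-CoA reductase",
    )
    add("PHAC", {"hbcoa_c": -1, "phb_c": 1, "coa_c": 1},
        0.0, DEFAULT_BOUND, SM, g("phbC"), name="PHB synthase (monomer basis)")

    # -- biomass: lumped amino-acid pool (glutamate) + GAM template --------
    template = ReactionRecord(
        id="BOF_TEMPLATE",
        stoichiometry={
            "atp_c": -40.0, "h2o_c": -40.0, "accoa_c": -0.2,
            "adp_c": 40.0, "pi_c": 40.0, "h_c": 40.0, "coa_c": 0.2,
        },
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
        subsystem="Biomass and maintenance",
    )
    _, bof = build_bof(
        {"E": 1.0},
        protein_mass_fraction=0.55,
        template_bof=template,
        aa_metabolites={"E": "glu__L_c"},
        bof_id="BOF",
    )
    model.add_reaction(bof)
    build_alginate_bof(
        bof, ALGINATE_BOF_COEFFICIENT, "alg_p", model=model, bof_id="BOF_alg"
    )
    model.objective_id = "BOF"

    # -- defects -----------------------------------------------------------
    manifest_defect_rxns: Dict[str, str] = {}
    manifest_defect_mets: Dict[str, str] = {}
    if "unbalanced" in defects:
        add("RX_UNBAL", {"h2o_c": -1, "h2_c": 1}, 0.0, DEFAULT_BOUND,
            CF, name="water-splitting typo (drops O)")
        manifest_defect_rxns["unbalanced"] = "RX_UNBAL"
    if "atp_cycle" in defects:
        add("RX_ATPCYC", {"adp_c": -1, "pi_c": -1, "h_c": -1,
                          "atp_c": 1, "h2o_c": 1},
            0.0, DEFAULT_BOUND, CF, name="costless ATP regeneration (sabotage)")
        manifest_defect_rxns["atp_cycle"] = "RX_ATPCYC"
    if "orphan_metabolite" in defects:
        model.add_metabolite(
            Metabolite(id="orphanX_c", name="declared but unused",
                       formula="C", charge=0, compartment="c")
        )
        manifest_defect_mets["orphan_metabolite"] = "orphanX_c"

    model.validate()
    manifest = ToyManifest(
        reactions=len(model.reactions),
        metabolites=len(model.metabolites),
        genes=len(model.genes),
        subsystems=sorted({r.subsystem for r in model.reactions.values()}),
        growth_truth={
            "glucose/non-diazotrophic": True,
            "glucose/diazotrophic": True,
            "fructose/non-diazotrophic": True,
            "fructose/diazotrophic": True,
            "pyruvate/non-diazotrophic": True,
            "pyruvate/diazotrophic": True,
            "starvation": False,
        },
        internal_reactions_balanced="unbalanced" not in defects,
        defects=defects,
        defect_reactions=manifest_defect_rxns,
        defect_metabolites=manifest_defect_mets,
        alginate_reactions=["PMI", "PMM", "MAN1PG", "GMD", "ALGE", "ALGt"],
        phb_reactions=["PHAA", "PHAB", "PHAC"],
        nitrogenase_reaction="NIT",
        nitrogenase_genes=nif_genes,
    )
    return model, manifest


# ---------------------------------------------------------------------------
# phenotype plates with ground truth


@dataclass
class PlateResult:
    model: MetabolicModel
    plate: "pd.DataFrame"
    truth: "pd.DataFrame"
    ground_truth: Dict[str, bool]


def make_plate(
    model: MetabolicModel,
    n_sources: int,
    n_growers: int,
    role: str = "carbon",
    seed: int = 0,
) -> PlateResult:
    """Augment the toy model with ``n_sources`` screen sources of which
    exactly ``n_growers`` are connected to the network (ground-truth
    positive); the rest get an exchange reaction but no route inward
    (declared-but-disconnected, ground-truth negative).

    Carbon growers are hexose isomers funneled to glucose; nitrogen
    growers are alanine-like aminotransferase substrates releasing
    ammonium and pyruvate.  The grower positions are a seeded choice, so
    the plate layout is reproducible.
    """
    import pandas as pd

    if role not in ("carbon", "nitrogen"):
        raise DiazogemError(f"unknown plate role {role!r}")
    if n_growers > n_sources:
        raise DiazogemError("n_growers cannot exceed n_sources")
    rng = np.random.default_rng(seed)
    grower_idx = set(rng.choice(n_sources, size=n_growers, replace=False).tolist())

    out = model.copy()
    plate_id = "PM1" if role == "carbon" else "PM3"
    formula, charge = ("C6H12O6", 0) if role == "carbon" else ("C3H7NO2", 0)
    rows, truth_rows = [], []
    ground_truth: Dict[str, bool] = {}
    for i in range(n_sources):
        stem = f"src{'C' if role == 'carbon' else 'N'}{i:02d}"
        well = f"{chr(ord('A') + i // 12)}{i % 12 + 1:02d}"
        grows = i in grower_idx
        out.add_metabolite(
            Metabolite(id=f"{stem}_e", name=f"screen source {i}",
                       formula=formula, charge=charge, compartment="e")
        )
        out.add_reaction(
            ReactionRecord(
                id=f"EX_{stem}_e", stoichiometry={f"{stem}_e": -1.0},
                lower_bound=0.0, upper_bound=DEFAULT_BOUND,
                subsystem="Exchange", name=f"{stem} exchange",
            )
        )
        if grows:
            out.add_metabolite(
                Metabolite(id=f"{stem}_c", name=f"screen source {i}",
                           formula=formula, charge=charge, compartment="c")
            )
            out.add_reaction(
                ReactionRecord(
                    id=f"{stem.upper()}t",
                    stoichiometry={f"{stem}_e": -1.0, f"{stem}_c": 1.0},
                    lower_bound=0.0, upper_bound=DEFAULT_BOUND,
                    subsystem="Transport", name=f"{stem} transport",
                )
            )
            if role == "carbon":
                stoich = {f"{stem}_c": -1.0, "glc__D_c": 1.0}
            else:
                stoich = {
                    f"{stem}_c": -1.0, "h2o_c": -1.0, "nad_c": -1.0,
                    "pyr_c": 1.0, "nh4_c": 1.0, "nadh_c": 1.0, "h_c": 1.0,
                }
            out.add_reaction(
                ReactionRecord(
                    id=f"{stem.upper()}deg", stoichiometry=stoich,
                    lower_bound=0.0, upper_bound=DEFAULT_BOUND,
                    subsystem=(
                        "Carbohydrate metabolism" if role == "carbon"
                        else "Amino acid metabolism"
                    ),
                    name=f"{stem} assimilation",
                )
            )
        rows.append(
            {"well": well, "source_metabolite_id": f"{stem}_e",
             "role": role, "plate_id": plate_id}
        )
        truth_rows.append({"well": well, "grew": int(grows)})
        ground_truth[f"{stem}_e"] = grows
    out.validate()
    return PlateResult(
        model=out,
        plate=pd.DataFrame(rows),
        truth=pd.DataFrame(truth_rows),
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# proteomes of known composition


@dataclass
class ProteomeResult:
    records: List[Tuple[str, str]]
    target_composition: Dict[str, float]
    realized_composition: Dict[str, float]


def make_proteome(
    composition: Dict[str, float],
    n_proteins: int = 100,
    mean_length: int = 300,
    seed: int = 0,
) -> ProteomeResult:
    """Sample a proteome with residues drawn from ``composition``.

    Multinomial sampling with a fixed seed; the realized composition is
    returned alongside for recovery tests.
    """
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-9:
        raise DiazogemError("composition fractions must sum to 1")
    rng = np.random.default_rng(seed)
    letters = sorted(composition)
    probs = np.array([composition[a] for a in letters])
    records: List[Tuple[str, str]] = []
    counts = {a: 0 for a in letters}
    for i in range(n_proteins):
        length = max(1, int(rng.poisson(mean_length)))
        seq_letters = rng.choice(len(letters), size=length, p=probs)
        seq = "".join(letters[j] for j in seq_letters)
        for j in seq_letters:
            counts[letters[j]] += 1
        records.append((f"prot{i:04d}", seq))
    total_res = sum(counts.values())
    realized = {a: n / total_res for a, n in counts.items() if n}
    return ProteomeResult(
        records=records,
        target_composition=dict(composition),
        realized_composition=realized,
    )


def write_proteome_fasta(result: ProteomeResult, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in result.records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# homology-hit tables spanning the acceptance thresholds


@dataclass
class HomologyTable:
    hits: List[HomologyHit]
    expected_accepted: Set[Tuple[str, str]]


def make_homology_table(n_hits: int = 25, seed: int = 0) -> HomologyTable:
    """Hit table stratified over all 8 accept/reject combinations of the
    identity / e-value / coverage thresholds, plus the exact-boundary row
    (40.0, 1e-4, 85.0), shuffled deterministically.

    The expected accept set is returned alongside (sidecar contract).
    """
    rng = np.random.default_rng(seed)
    hits: List[HomologyHit] = []
    expected: Set[Tuple[str, str]] = set()
    combos = [(i, e, c) for i in (True, False) for e in (True, False)
              for c in (True, False)]
    i = 0
    while len(hits) < n_hits - 1:
        ok_i, ok_e, ok_c = combos[i % 8]
        identity = float(rng.uniform(45, 95)) if ok_i else float(rng.uniform(5, 39.5))
        evalue = float(10 ** rng.uniform(-50, -5)) if ok_e else float(
            10 ** rng.uniform(-3.5, 0)
        )
        coverage = float(rng.uniform(86, 100)) if ok_c else float(rng.uniform(10, 84.5))
        hit = HomologyHit(
            query=f"tmpl_{i:04d}", subject=f"avin_{i:04d}",
            identity=round(identity, 1), evalue=evalue, coverage=round(coverage, 1),
        )
        hits.append(hit)
        if ok_i and ok_e and ok_c:
            expected.add((hit.query, hit.subject))
        i += 1
    boundary = HomologyHit(
        query="tmpl_edge", subject="avin_edge",
        identity=40.0, evalue=1e-4, coverage=85.0,
    )
    hits.append(boundary)
    expected.add((boundary.query, boundary.subject))
    order = rng.permutation(len(hits))
    hits = [hits[j] for j in order]
    return HomologyTable(hits=hits, expected_accepted=expected)
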