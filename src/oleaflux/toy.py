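"""Synthetic oleaginous-yeast genome-scale model generator.

Builds a small (~125 reaction) compartmentalized network that mirrors the
lipid-accumulation physiology of an oleaginous basidiomycete yeast: sugar and
glycerol uptake, glycolysis, oxidative and non-oxidative pentose phosphate
pathway, the phosphoketolase route for xylose, a mitochondrial TCA cycle with
citrate export, ATP-citrate lyase (ACL) as the sole source of cytosolic
acetyl-CoA, acetyl-CoA carboxylase, a lumped fatty-acid synthase,
elongation/desaturation to C18 acyl-CoAs, the acyl-CoA pool, TAG and
phospholipid synthesis, a lipid-body export, lumped protein/carbohydrate
synthesis, lumped oxidative phosphorylation and maintenance ATPases.

Compartments: c (cytosol), m (mitochondrion), e (extracellular), l (lipid
particle).  All metabolic reactions outside the explicitly lumped set are
elementally and charge balanced against standard metabolite formulas.

Deliberate physiology encoded by construction:

* ethanol exchange/transport exist but assimilation (ADH/ALDH) is absent by
  default, so ethanol supports no growth; ``include_ethanol_assimilation``
  restores the pathway together with the glyoxylate shunt and PEP
  carboxykinase;
* glycerol enters by proton symport (offset by the plasma-membrane
  H+-ATPase) and is oxidized obligatorily through the FAD-linked
  glycerol-3-phosphate shuttle, so with the lumped P/O ratios (NADH 1.5,
  FADH2 0.5) its ATP yield per C-mol is below that of glucose;
* ACL carries a dedicated gene and there is no cytosolic acetyl-CoA
  synthetase, making ACL essential for lipid synthesis and hence for growth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .biomass import (
    ACYL_POOL_COEFFICIENTS,
    DEFAULT_GAM,
    PROTEIN_RESIDUE_MW,
    OTHER_MW,
    acyl_pool_fractions,
    acyl_pool_reaction,
    compose_biomass,
    install_biomass,
)
from .elements import molecular_weight
from .model import MetabolicModel, Metabolite, Reaction, gpr_from_string

#: Lumped P/O ratios of the simplified respiratory chain (mol ATP per mol
#: carrier oxidized).
PO_NADH = 1.5
PO_FADH2 = 0.5

COMPARTMENTS = {
    "c": "cytosol",
    "m": "mitochondrion",
    "e": "extracellular",
    "l": "lipid particle",
}

_FA_FORMULAS = {
    "C16:0": "C16H32O2",
    "C18:0": "C18H36O2",
    "C18:1": "C18H34O2",
    "C18:2": "C18H32O2",
}

_ACYL_COA_FORMULAS = {
    "C16:0": "C37H62N7O17P3S",
    "C18:0": "C39H66N7O17P3S",
    "C18:1": "C39H64N7O17P3S",
    "C18:2": "C39H62N7O17P3S",
}


def lipid_component_mws() -> dict[str, float]:
    """Molecular weights (g/mmol) of the lipid pseudo-species.

    Derived from the normalized fatty-acid weight shares: the mean acyl
    residue mass enters TAG (glycerol + 3 acyls) and the diacyl phospholipids
    (glycerophosphate backbone + head group + 2 acyls).
    """
    mw_h2o = molecular_weight("H2O")
    frac = acyl_pool_fractions()
    avg_fa = sum(frac[k] * molecular_weight(v) for k, v in _FA_FORMULAS.items())
    acyl = avg_fa - mw_h2o  # esterified residue
    glycerol = molecular_weight("C3H8O3")
    backbone = glycerol + molecular_weight("H3O4P") - mw_h2o
    mws = {
        "tag": glycerol + 3 * acyl,
        "pa": backbone + 2 * acyl,
        "dag": glycerol + 2 * acyl,
        "ps": backbone + molecular_weight("C3H7NO3") - mw_h2o + 2 * acyl,
        "pe": backbone + molecular_weight("C2H7NO") - mw_h2o + 2 * acyl,
        "pc": backbone + molecular_weight("C5H13NO") - mw_h2o + 2 * acyl,
    }
    mws["cdpdag"] = mws["pa"] + molecular_weight("C9H13N3O7P")  # + CMP residue
    mws["acylcoa_pool"] = sum(
        coeff * molecular_weight(_ACYL_COA_FORMULAS[k])
        for k, coeff in ACYL_POOL_COEFFICIENTS.items()
    )
    return mws


@dataclass
class ToyModelManifest:
    """Ground-truth bookkeeping emitted alongside the generated model."""

    category_counts: dict[str, int] = field(default_factory=dict)
    lumped_reactions: list[str] = field(default_factory=list)
    essential_genes: list[str] = field(default_factory=list)
    acl_gene: str = "gACL1"
    carbon_sources: dict[str, dict] = field(default_factory=dict)
    nitrogen_sources: dict[str, dict] = field(default_factory=dict)
    pathways: dict[str, list[str]] = field(default_factory=dict)
    tracked_reactions: dict[str, str] = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ToyModelManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# metabolite table: id -> (name, compartment, formula, charge)
def _metabolite_table() -> list[tuple[str, str, str, Optional[str], Optional[int]]]:
    mets = []

    def add(mid, name, comp, formula=None, charge=None):
        mets.append((mid, name, comp, formula, charge))

    # extracellular
    add("glc_e", "D-glucose", "e", "C6H12O6", 0)
    add("fru_e", "D-fructose", "e", "C6H12O6", 0)
    add("sucr_e", "sucrose", "e", "C12H22O11", 0)
    add("xyl_e", "D-xylose", "e", "C5H10O5", 0)
    add("glyc_e", "glycerol", "e", "C3H8O3", 0)
    add("etoh_e", "ethanol", "e", "C2H6O", 0)
    add("ac_e", "acetate", "e", "C2H3O2", -1)
    add("o2_e", "oxygen", "e", "O2", 0)
    add("co2_e", "carbon dioxide", "e", "CO2", 0)
    add("h2o_e", "water", "e", "H2O", 0)
    add("h_e", "proton", "e", "H", 1)
    add("pi_e", "phosphate", "e", "HO4P", -2)
    add("so4_e", "sulphate", "e", "O4S", -2)
    add("nh4_e", "ammonium", "e", "H4N", 1)
    add("urea_e", "urea", "e", "CH4N2O", 0)
    add("fe2_e", "Fe2+", "e", "Fe", 2)
    add("k_e", "potassium", "e", "K", 1)
    add("na_e", "sodium", "e", "Na", 1)
    add("ala_e", "L-alanine", "e", "C3H7NO2", 0)
    add("ala_c", "L-alanine", "c", "C3H7NO2", 0)
    # cytosol: imported species
    for b, name, formula, charge in [
        ("glc", "D-glucose", "C6H12O6", 0),
        ("fru", "D-fructose", "C6H12O6", 0),
        ("xyl", "D-xylose", "C5H10O5", 0),
        ("glyc", "glycerol", "C3H8O3", 0),
        ("etoh", "ethanol", "C2H6O", 0),
        ("ac", "acetate", "C2H3O2", -1),
        ("o2", "oxygen", "O2", 0),
        ("co2", "carbon dioxide", "CO2", 0),
        ("h2o", "water", "H2O", 0),
        ("h", "proton", "H", 1),
        ("pi", "phosphate", "HO4P", -2),
        ("so4", "sulphate", "O4S", -2),
        ("nh4", "ammonium", "H4N", 1),
        ("urea", "urea", "CH4N2O", 0),
        ("fe2", "Fe2+", "Fe", 2),
        ("k", "potassium", "K", 1),
        ("na", "sodium", "Na", 1),
    ]:
        add(f"{b}_c", name, "c", formula, charge)
    # central carbon (cytosol)
    for mid, name, formula, charge in [
        ("g6p", "D-glucose 6-phosphate", "C6H11O9P", -2),
        ("f6p", "D-fructose 6-phosphate", "C6H11O9P", -2),
        ("g1p", "D-glucose 1-phosphate", "C6H11O9P", -2),
        ("fdp", "D-fructose 1,6-bisphosphate", "C6H10O12P2", -4),
        ("dhap", "dihydroxyacetone phosphate", "C3H5O6P", -2),
        ("g3p", "glyceraldehyde 3-phosphate", "C3H5O6P", -2),
        ("glyc3p", "sn-glycerol 3-phosphate", "C3H7O6P", -2),
        ("13dpg", "1,3-bisphospho-D-glycerate", "C3H4O10P2", -4),
        ("3pg", "3-phospho-D-glycerate", "C3H4O7P", -3),
        ("2pg", "2-phospho-D-glycerate", "C3H4O7P", -3),
        ("pep", "phosphoenolpyruvate", "C3H2O6P", -3),
        ("pyr", "pyruvate", "C3H3O3", -1),
        ("6pgl", "6-phospho-D-glucono-1,5-lactone", "C6H9O9P", -2),
        ("6pgc", "6-phospho-D-gluconate", "C6H10O10P", -3),
        ("ru5p", "D-ribulose 5-phosphate", "C5H9O8P", -2),
        ("r5p", "D-ribose 5-phosphate", "C5H9O8P", -2),
        ("xu5p", "D-xylulose 5-phosphate", "C5H9O8P", -2),
        ("s7p", "sedoheptulose 7-phosphate", "C7H13O10P", -2),
        ("e4p", "D-erythrose 4-phosphate", "C4H7O7P", -2),
        ("xylt", "xylitol", "C5H12O5", 0),
        ("xylu", "D-xylulose", "C5H10O5", 0),
        ("actp", "acetyl phosphate", "C2H3O5P", -2),
        ("acald", "acetaldehyde", "C2H4O", 0),
        ("atp", "ATP", "C10H12N5O13P3", -4),
        ("adp", "ADP", "C10H12N5O10P2", -3),
        ("amp", "AMP", "C10H12N5O7P", -2),
        ("ppi", "diphosphate", "HO7P2", -3),
        ("nad", "NAD+", "C21H26N7O14P2", -1),
        ("nadh", "NADH", "C21H27N7O14P2", -2),
        ("nadp", "NADP+", "C21H25N7O17P3", -3),
        ("nadph", "NADPH", "C21H26N7O17P3", -4),
        ("utp", "UTP", "C9H11N2O15P3", -4),
        ("udp", "UDP", "C9H11N2O12P2", -3),
        ("udpg", "UDP-glucose", "C15H22N2O17P2", -2),
        ("ctp", "CTP", "C9H12N3O14P3", -4),
        ("cdp", "CDP", "C9H12N3O11P2", -3),
        ("cmp", "CMP", "C9H12N3O8P", -2),
        ("coa", "coenzyme A", "C21H32N7O16P3S", -4),
        ("accoa", "acetyl-CoA", "C23H34N7O17P3S", -4),
        ("malcoa", "malonyl-CoA", "C24H33N7O19P3S", -5),
        ("cit", "citrate", "C6H5O7", -3),
        ("oaa", "oxaloacetate", "C4H2O5", -2),
        ("mal", "(S)-malate", "C4H4O5", -2),
        ("akg", "2-oxoglutarate", "C5H4O5", -2),
        ("pmtcoa", "palmitoyl-CoA", "C37H62N7O17P3S", -4),
        ("stcoa", "stearoyl-CoA", "C39H66N7O17P3S", -4),
        ("odecoa", "oleoyl-CoA", "C39H64N7O17P3S", -4),
        ("lnlccoa", "linoleoyl-CoA", "C39H62N7O17P3S", -4),
        ("carbohydrate", "carbohydrate (anhydroglucose residue)", "C6H10O5", 0),
    ]:
        add(f"{mid}_c", name, "c", formula, charge)
    # mitochondrion
    for mid, name, formula, charge in [
        ("pyr", "pyruvate", "C3H3O3", -1),
        ("accoa", "acetyl-CoA", "C23H34N7O17P3S", -4),
        ("coa", "coenzyme A", "C21H32N7O16P3S", -4),
        ("cit", "citrate", "C6H5O7", -3),
        ("icit", "isocitrate", "C6H5O7", -3),
        ("akg", "2-oxoglutarate", "C5H4O5", -2),
        ("succoa", "succinyl-CoA", "C25H35N7O19P3S", -5),
        ("succ", "succinate", "C4H4O4", -2),
        ("fum", "fumarate", "C4H2O4", -2),
        ("mal", "(S)-malate", "C4H4O5", -2),
        ("oaa", "oxaloacetate", "C4H2O5", -2),
        ("glx", "glyoxylate", "C2HO3", -1),
        ("nad", "NAD+", "C21H26N7O14P2", -1),
        ("nadh", "NADH", "C21H27N7O14P2", -2),
        ("fad", "FAD", "C27H31N9O15P2", -2),
        ("fadh2", "FADH2", "C27H33N9O15P2", -2),
        ("gtp", "GTP", "C10H12N5O14P3", -4),
        ("gdp", "GDP", "C10H12N5O11P2", -3),
        ("atp", "ATP", "C10H12N5O13P3", -4),
        ("adp", "ADP", "C10H12N5O10P2", -3),
        ("amp", "AMP", "C10H12N5O7P", -2),
        ("pi", "phosphate", "HO4P", -2),
        ("ppi", "diphosphate", "HO7P2", -3),
        ("h", "proton", "H", 1),
        ("h2o", "water", "H2O", 0),
        ("co2", "carbon dioxide", "CO2", 0),
        ("o2", "oxygen", "O2", 0),
        ("ac", "acetate", "C2H3O2", -1),
    ]:
        add(f"{mid}_m", name, "m", formula, charge)
    return mets


def build_toy_gem(
    include_ethanol_assimilation: bool = False,
    gam: float = DEFAULT_GAM,
    seed: Optional[int] = None,
    bound_jitter: float = 0.0,
) -> tuple[MetabolicModel, ToyModelManifest]:
    """Build the synthetic oleaginous-yeast model and its manifest.

    Construction is deterministic; ``seed``/``bound_jitter`` only optionally
    perturb non-exchange upper bounds (for property tests).  The default
    biomass is the static nitrogen-replete composition; protocols replace it
    with condition-specific ones.
    """
    model = MetabolicModel(
        "toyOleaginosus",
        "synthetic oleaginous yeast toy model",
        COMPARTMENTS,
    )
    model.annotations["source"] = "oleaflux.toy synthetic generator"

    for mid, name, comp, formula, charge in _metabolite_table():
        model.add_metabolite(
            Metabolite(mid, name=name, compartment=comp, formula=formula, charge=charge)
        )
    mws = lipid_component_mws()
    for mid, name, comp, mw in [
        ("pa_c", "phosphatidate (mean acyl)", "c", mws["pa"]),
        ("dag_c", "diacylglycerol (mean acyl)", "c", mws["dag"]),
        ("tag_c", "triacylglycerol (mean acyl)", "c", mws["tag"]),
        ("cdpdag_c", "CDP-diacylglycerol (mean acyl)", "c", mws["cdpdag"]),
        ("ps_c", "phosphatidylserine (mean acyl)", "c", mws["ps"]),
        ("pe_c", "phosphatidylethanolamine (mean acyl)", "c", mws["pe"]),
        ("pc_c", "phosphatidylcholine (mean acyl)", "c", mws["pc"]),
        ("acylcoa_pool_c", "acyl-CoA pool", "c", mws["acylcoa_pool"]),
        ("protein_c", "protein (mean residue)", "c", PROTEIN_RESIDUE_MW),
        ("other_c", "other biomass (nucleic acids, minerals, cofactors)", "c", OTHER_MW),
        ("tag_l", "triacylglycerol (lipid body)", "l", mws["tag"]),
        ("ps_l", "phosphatidylserine (lipid body)", "l", mws["ps"]),
        ("pe_l", "phosphatidylethanolamine (lipid body)", "l", mws["pe"]),
        ("pc_l", "phosphatidylcholine (lipid body)", "l", mws["pc"]),
        ("lipid_l", "lipid body content", "l", 1.0),
        ("lipid_e", "exported lipid body", "e", 1.0),
    ]:
        model.add_metabolite(Metabolite(mid, name=name, compartment=comp, mw=mw))

    lumped: list[str] = []

    def R(rid, name, stoich, lb=None, ub=1000.0, gpr=None, subsystem="", lump=False):
        if lb is None:
            lb = -1000.0
        rxn = Reaction(
            id=rid,
            name=name,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr_from_string(gpr) if gpr else None,
            subsystem=subsystem,
        )
        model.add_reaction(rxn)
        if lump:
            lumped.append(rid)
        return rxn

    # -- exchanges (positive flux = secretion) -----------------------------
    open_lb = {
        "co2": -1000, "h2o": -1000, "h": -1000, "o2": -1000, "fe2": -1000,
        "pi": -1000, "k": -1000, "na": -1000, "so4": -1000, "nh4": -1000,
        "glc": -10,  # default validation carbon source
    }
    for base in [
        "glc", "fru", "sucr", "xyl", "glyc", "etoh", "ac", "o2", "co2", "h2o",
        "h", "pi", "so4", "nh4", "urea", "fe2", "k", "na", "ala", "lipid",
    ]:
        R(
            f"EX_{base}_e",
            f"{base} exchange",
            {f"{base}_e": -1.0},
            lb=float(open_lb.get(base, 0)),
            subsystem="exchange",
        )

    # -- transport, plasma membrane ----------------------------------------
    R("GLCt", "glucose transport (facilitated)", {"glc_e": -1, "glc_c": 1},
      gpr="gHXT1 or gHXT2", subsystem="transport")
    R("FRUt", "fructose transport (facilitated)", {"fru_e": -1, "fru_c": 1},
      gpr="gHXT1 or gHXT2", subsystem="transport")
    R("XYLt", "xylose transport (facilitated)", {"xyl_e": -1, "xyl_c": 1},
      gpr="gXTR1", subsystem="transport")
    R("GLYCt", "glycerol transport (H+ symport)",
      {"glyc_e": -1, "h_e": -1, "glyc_c": 1, "h_c": 1}, lb=0,
      gpr="gSTL1", subsystem="transport")
    R("ETOHt", "ethanol diffusion", {"etoh_e": -1, "etoh_c": 1},
      subsystem="transport")
    R("ACt", "acetate transport (H+ symport)",
      {"ac_e": -1, "h_e": -1, "ac_c": 1, "h_c": 1}, subsystem="transport")
    for b in ("o2", "co2", "h2o"):
        R(f"{b.upper()}t", f"{b} diffusion", {f"{b}_e": -1, f"{b}_c": 1},
          subsystem="transport")
    R("NH4t", "ammonium transport", {"nh4_e": -1, "nh4_c": 1},
      gpr="gMEP1", subsystem="transport")
    R("UREAt", "urea transport", {"urea_e": -1, "urea_c": 1}, lb=0,
      gpr="gDUR3", subsystem="transport")
    R("PIt", "phosphate transport", {"pi_e": -1, "pi_c": 1},
      gpr="gPHO84", subsystem="transport")
    R("SO4t", "sulphate transport", {"so4_e": -1, "so4_c": 1},
      gpr="gSUL1", subsystem="transport")
    R("FE2t", "iron(II) transport", {"fe2_e": -1, "fe2_c": 1}, subsystem="transport")
    R("Kt", "potassium transport", {"k_e": -1, "k_c": 1}, subsystem="transport")
    R("NAt", "sodium transport", {"na_e": -1, "na_c": 1}, subsystem="transport")
    R("PMA1", "plasma-membrane H+-ATPase",
      {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_e": 1}, lb=0,
      gpr="gPMA1", subsystem="transport")

    # -- transport, mitochondrial ------------------------------------------
    R("PYRtm", "pyruvate mitochondrial transport (H+ symport)",
      {"pyr_c": -1, "h_c": -1, "pyr_m": 1, "h_m": 1}, lb=0, subsystem="transport")
    R("ATPADPtm", "ADP/ATP translocase",
      {"atp_m": -1, "adp_c": -1, "atp_c": 1, "adp_m": 1}, subsystem="transport")
    R("PItm", "phosphate mitochondrial transport", {"pi_c": -1, "pi_m": 1},
      subsystem="transport")
    R("MALtm", "malate mitochondrial transport", {"mal_c": -1, "mal_m": 1},
      subsystem="transport")
    R("AKGtm", "2-oxoglutarate mitochondrial transport", {"akg_m": -1, "akg_c": 1},
      subsystem="transport")
    R("CITtm", "citrate export, mitochondria to cytosol",
      {"cit_m": -1, "cit_c": 1}, lb=0, gpr="gCTP1", subsystem="transport")
    R("ACtm", "acetate mitochondrial transport (H+ symport)",
      {"ac_c": -1, "h_c": -1, "ac_m": 1, "h_m": 1}, lb=0, subsystem="transport")
    R("Htm", "proton exchange across inner membrane (lumped PMF)",
      {"h_c": -1, "h_m": 1}, subsystem="transport")
    for b in ("o2", "co2", "h2o"):
        R(f"{b.upper()}tm", f"{b} mitochondrial diffusion",
          {f"{b}_c": -1, f"{b}_m": 1}, subsystem="transport")
    R("G3PSHUTTLE", "FAD-linked glycerol-3-phosphate dehydrogenase (shuttle)",
      {"glyc3p_c": -1, "fad_m": -1, "dhap_c": 1, "fadh2_m": 1}, lb=0,
      gpr="gGUT2", subsystem="transport")

    # -- glycolysis / gluconeogenesis --------------------------------------
    R("HEX1", "hexokinase (glucose)",
      {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1}, lb=0,
      gpr="gHXK1 or gHXK2", subsystem="glycolysis")
    R("HEXf", "hexokinase (fructose)",
      {"fru_c": -1, "atp_c": -1, "f6p_c": 1, "adp_c": 1, "h_c": 1}, lb=0,
      gpr="gHXK1 or gHXK2", subsystem="glycolysis")
    R("PGI", "glucose-6-phosphate isomerase", {"g6p_c": -1, "f6p_c": 1},
      gpr="gPGI1", subsystem="glycolysis")
    R("PFK", "6-phosphofructokinase",
      {"f6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1, "h_c": 1}, lb=0,
      gpr="gPFK1 and gPFK2", subsystem="glycolysis")
    R("FBP", "fructose-1,6-bisphosphatase",
      {"fdp_c": -1, "h2o_c": -1, "f6p_c": 1, "pi_c": 1}, lb=0,
      gpr="gFBP1", subsystem="glycolysis")
    R("FBA", "fructose-bisphosphate aldolase",
      {"fdp_c": -1, "dhap_c": 1, "g3p_c": 1}, gpr="gFBA1", subsystem="glycolysis")
    R("TPI", "triose-phosphate isomerase", {"dhap_c": -1, "g3p_c": 1},
      gpr="gTPI1", subsystem="glycolysis")
    R("GAPD", "glyceraldehyde-3-phosphate dehydrogenase",
      {"g3p_c": -1, "nad_c": -1, "pi_c": -1, "13dpg_c": 1, "nadh_c": 1, "h_c": 1},
      gpr="gTDH1", subsystem="glycolysis")
    R("PGK", "phosphoglycerate kinase",
      {"13dpg_c": -1, "adp_c": -1, "3pg_c": 1, "atp_c": 1},
      gpr="gPGK1", subsystem="glycolysis")
    R("PGM", "phosphoglycerate mutase", {"3pg_c": -1, "2pg_c": 1},
      gpr="gGPM1", subsystem="glycolysis")
    R("ENO", "enolase", {"2pg_c": -1, "pep_c": 1, "h2o_c": 1},
      gpr="gENO1", subsystem="glycolysis")
    R("PYK", "pyruvate kinase",
      {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1}, lb=0,
      gpr="gPYK1", subsystem="glycolysis")
    R("INVERT", "extracellular invertase",
      {"sucr_e": -1, "h2o_e": -1, "glc_e": 1, "fru_e": 1}, lb=0,
      gpr="gSUC2", subsystem="glycolysis")

    # -- pentose phosphate pathway + phosphoketolase -----------------------
    R("G6PDH", "glucose-6-phosphate dehydrogenase",
      {"g6p_c": -1, "nadp_c": -1, "6pgl_c": 1, "nadph_c": 1, "h_c": 1}, lb=0,
      gpr="gZWF1", subsystem="pentose phosphate pathway")
    R("PGL", "6-phosphogluconolactonase",
      {"6pgl_c": -1, "h2o_c": -1, "6pgc_c": 1, "h_c": 1}, lb=0,
      gpr="gSOL3", subsystem="pentose phosphate pathway")
    R("GND", "6-phosphogluconate dehydrogenase",
      {"6pgc_c": -1, "nadp_c": -1, "ru5p_c": 1, "nadph_c": 1, "co2_c": 1}, lb=0,
      gpr="gGND1", subsystem="pentose phosphate pathway")
    R("RPI", "ribose-5-phosphate isomerase", {"ru5p_c": -1, "r5p_c": 1},
      gpr="gRKI1", subsystem="pentose phosphate pathway")
    R("RPE", "ribulose-5-phosphate epimerase", {"ru5p_c": -1, "xu5p_c": 1},
      gpr="gRPE1", subsystem="pentose phosphate pathway")
    R("TKT1", "transketolase 1",
      {"r5p_c": -1, "xu5p_c": -1, "g3p_c": 1, "s7p_c": 1},
      gpr="gTKL1", subsystem="pentose phosphate pathway")
    R("TAL", "transaldolase",
      {"g3p_c": -1, "s7p_c": -1, "e4p_c": 1, "f6p_c": 1},
      gpr="gTAL1", subsystem="pentose phosphate pathway")
    R("TKT2", "transketolase 2",
      {"e4p_c": -1, "xu5p_c": -1, "f6p_c": 1, "g3p_c": 1},
      gpr="gTKL1", subsystem="pentose phosphate pathway")
    R("XYLR", "xylose reductase (NADPH)",
      {"xyl_c": -1, "nadph_c": -1, "h_c": -1, "xylt_c": 1, "nadp_c": 1}, lb=0,
      gpr="gXYL1", subsystem="xylose assimilation")
    R("XYLDH", "xylitol dehydrogenase (NAD)",
      {"xylt_c": -1, "nad_c": -1, "xylu_c": 1, "nadh_c": 1, "h_c": 1}, lb=0,
      gpr="gXYL2", subsystem="xylose assimilation")
    R("XYLK", "xylulokinase",
      {"xylu_c": -1, "atp_c": -1, "xu5p_c": 1, "adp_c": 1, "h_c": 1}, lb=0,
      gpr="gXKS1", subsystem="xylose assimilation")
    R("XPK", "xylulose-5-phosphate phosphoketolase",
      {"xu5p_c": -1, "pi_c": -1, "actp_c": 1, "g3p_c": 1, "h2o_c": 1}, lb=0,
      gpr="gXPK1", subsystem="phosphoketolase")
    R("ACK", "acetate kinase",
      {"actp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1}, lb=0,
      gpr="gACK1", subsystem="phosphoketolase")

    # -- glycerol ----------------------------------------------------------
    R("GLYK", "glycerol kinase",
      {"glyc_c": -1, "atp_c": -1, "glyc3p_c": 1, "adp_c": 1, "h_c": 1}, lb=0,
      gpr="gGUT1", subsystem="glycerol metabolism")
    R("G3PD", "glycerol-3-phosphate dehydrogenase (NAD, lipogenic direction)",
      {"dhap_c": -1, "nadh_c": -1, "h_c": -1, "glyc3p_c": 1, "nad_c": 1}, lb=0,
      gpr="gGPD1", subsystem="glycerol metabolism")

    # -- anaplerosis and shuttles ------------------------------------------
    R("PYC", "pyruvate carboxylase",
      {"pyr_c": -1, "co2_c": -1, "atp_c": -1, "h2o_c": -1,
       "oaa_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 2}, lb=0,
      gpr="gPYC1", subsystem="anaplerosis")
    R("MDHc", "malate dehydrogenase, cytosolic",
      {"oaa_c": -1, "nadh_c": -1, "h_c": -1, "mal_c": 1, "nad_c": 1},
      gpr="gMDH2", subsystem="anaplerosis")

    # -- TCA cycle ---------------------------------------------------------
    R("PDH", "pyruvate dehydrogenase complex",
      {"pyr_m": -1, "coa_m": -1, "nad_m": -1, "accoa_m": 1, "co2_m": 1, "nadh_m": 1},
      lb=0, gpr="gPDA1 and gPDB1", subsystem="TCA cycle")
    R("CS", "citrate synthase",
      {"accoa_m": -1, "oaa_m": -1, "h2o_m": -1, "cit_m": 1, "coa_m": 1, "h_m": 1},
      lb=0, gpr="gCIT1", subsystem="TCA cycle")
    R("ACONT", "aconitase", {"cit_m": -1, "icit_m": 1},
      gpr="gACO1", subsystem="TCA cycle")
    R("ICDH", "isocitrate dehydrogenase (NAD)",
      {"icit_m": -1, "nad_m": -1, "akg_m": 1, "co2_m": 1, "nadh_m": 1}, lb=0,
      gpr="gIDH1 and gIDH2", subsystem="TCA cycle")
    R("AKGDH", "2-oxoglutarate dehydrogenase",
      {"akg_m": -1, "coa_m": -1, "nad_m": -1, "succoa_m": 1, "co2_m": 1, "nadh_m": 1},
      lb=0, gpr="gKGD1 and gKGD2", subsystem="TCA cycle")
    R("SUCOAS", "succinyl-CoA synthetase (GTP)",
      {"succoa_m": -1, "gdp_m": -1, "pi_m": -1, "succ_m": 1, "gtp_m": 1, "coa_m": 1},
      gpr="gLSC1 and gLSC2", subsystem="TCA cycle")
    R("SUCD", "succinate dehydrogenase",
      {"succ_m": -1, "fad_m": -1, "fum_m": 1, "fadh2_m": 1}, lb=0,
      gpr="gSDH1 and gSDH2", subsystem="TCA cycle")
    R("FUM", "fumarase", {"fum_m": -1, "h2o_m": -1, "mal_m": 1},
      gpr="gFUM1", subsystem="TCA cycle")
    R("MDHm", "malate dehydrogenase, mitochondrial",
      {"mal_m": -1, "nad_m": -1, "oaa_m": 1, "nadh_m": 1, "h_m": 1},
      gpr="gMDH1", subsystem="TCA cycle")

    # -- oxidative phosphorylation (lumped) --------------------------------
    R("NADHOR", "NADH:O2 oxidoreductase + ATP synthase (lumped, P/O 1.5)",
      {"nadh_m": -1, "o2_m": -0.5, "adp_m": -PO_NADH, "pi_m": -PO_NADH,
       "h_m": -(1 + PO_NADH), "nad_m": 1, "atp_m": PO_NADH,
       "h2o_m": 1 + PO_NADH}, lb=0,
      gpr="gNDI1 and gATP1", subsystem="oxidative phosphorylation")
    R("FADHOR", "FADH2:O2 oxidoreductase + ATP synthase (lumped, P/O 0.5)",
      {"fadh2_m": -1, "o2_m": -0.5, "adp_m": -PO_FADH2, "pi_m": -PO_FADH2,
       "h_m": -PO_FADH2, "fad_m": 1, "atp_m": PO_FADH2,
       "h2o_m": 1 + PO_FADH2}, lb=0,
      gpr="gSDH1 and gATP1", subsystem="oxidative phosphorylation")

    # -- mitochondrial acetate activation ----------------------------------
    R("ACSm", "acetyl-CoA synthetase, mitochondrial",
      {"ac_m": -1, "atp_m": -1, "coa_m": -1, "accoa_m": 1, "amp_m": 1, "ppi_m": 1},
      lb=0, gpr="gACS2", subsystem="acetate metabolism")
    R("ADK1m", "adenylate kinase, mitochondrial",
      {"amp_m": -1, "atp_m": -1, "adp_m": 2}, gpr="gADK1", subsystem="nucleotides")
    R("PPAm", "inorganic pyrophosphatase, mitochondrial",
      {"ppi_m": -1, "h2o_m": -1, "pi_m": 2, "h_m": 1}, lb=0,
      gpr="gIPP1", subsystem="nucleotides")
    R("NDPKg", "nucleoside-diphosphate kinase (GDP)",
      {"atp_m": -1, "gdp_m": -1, "adp_m": 1, "gtp_m": 1},
      gpr="gYNK1", subsystem="nucleotides")

    # -- lipid synthesis ---------------------------------------------------
    R("ACL", "ATP-citrate lyase",
      {"cit_c": -1, "atp_c": -1, "coa_c": -1,
       "accoa_c": 1, "oaa_c": 1, "adp_c": 1, "pi_c": 1}, lb=0,
      gpr="gACL1", subsystem="lipid synthesis")
    R("ACC", "acetyl-CoA carboxylase",
      {"accoa_c": -1, "atp_c": -1, "co2_c": -1, "h2o_c": -1,
       "malcoa_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 2}, lb=0,
      gpr="gACC1", subsystem="lipid synthesis")
    R("FAS", "fatty-acid synthase (lumped, to palmitoyl-CoA)",
      {"accoa_c": -1, "malcoa_c": -7, "nadph_c": -14, "h_c": -21,
       "pmtcoa_c": 1, "nadp_c": 14, "coa_c": 7, "co2_c": 7, "h2o_c": 7}, lb=0,
      gpr="gFAS1 and gFAS2", subsystem="lipid synthesis")
    R("ELONG", "fatty-acyl elongase (C16->C18)",
      {"pmtcoa_c": -1, "malcoa_c": -1, "nadph_c": -2, "h_c": -3,
       "stcoa_c": 1, "co2_c": 1, "coa_c": 1, "nadp_c": 2, "h2o_c": 1}, lb=0,
      gpr="gELO1", subsystem="lipid synthesis")
    R("DESAT9", "Δ9 fatty-acid desaturase (C18:0 -> C18:1)",
      {"stcoa_c": -1, "nadh_c": -1, "o2_c": -1, "h_c": -1,
       "odecoa_c": 1, "nad_c": 1, "h2o_c": 2}, lb=0,
      gpr="gOLE1", subsystem="lipid synthesis")
    R("DESAT12", "Δ12 fatty-acid desaturase (C18:1 -> C18:2)",
      {"odecoa_c": -1, "nadh_c": -1, "o2_c": -1, "h_c": -1,
       "lnlccoa_c": 1, "nad_c": 1, "h2o_c": 2}, lb=0,
      gpr="gFAD12", subsystem="lipid synthesis")
    pool = acyl_pool_reaction()
    model.add_reaction(pool)
    lumped.append(pool.id)
    # 1 mmol pool carries sum(pool coefficients) mmol of CoA thioester; acyl
    # transfers must release exactly that much CoA or the conserved CoA pool
    # would grow and steady state would forbid any lipid flux.
    pool_coa = sum(ACYL_POOL_COEFFICIENTS.values())
    R("GPAT", "glycerol-3-phosphate acyltransferase (lumped diacylation)",
      {"glyc3p_c": -1, "acylcoa_pool_c": -2, "pa_c": 1, "coa_c": 2 * pool_coa}, lb=0,
      gpr="gSCT1", subsystem="lipid synthesis", lump=True)
    R("PAP", "phosphatidate phosphatase",
      {"pa_c": -1, "h2o_c": -1, "dag_c": 1, "pi_c": 1}, lb=0,
      gpr="gPAH1", subsystem="lipid synthesis", lump=True)
    R("DGAT", "diacylglycerol acyltransferase",
      {"dag_c": -1, "acylcoa_pool_c": -1, "tag_c": 1, "coa_c": pool_coa}, lb=0,
      gpr="gDGA1", subsystem="lipid synthesis", lump=True)
    R("CDS", "phosphatidate cytidylyltransferase",
      {"pa_c": -1, "ctp_c": -1, "h_c": -1, "cdpdag_c": 1, "ppi_c": 1}, lb=0,
      gpr="gCDS1", subsystem="lipid synthesis", lump=True)
    R("PSS", "phosphatidylserine synthase (serine synthesis lumped in)",
      {"cdpdag_c": -1, "3pg_c": -1, "nh4_c": -1, "nadh_c": -1,
       "ps_c": 1, "cmp_c": 1, "nad_c": 1, "pi_c": 1, "h2o_c": 1}, lb=0,
      gpr="gCHO1", subsystem="lipid synthesis", lump=True)
    R("PSD", "phosphatidylserine decarboxylase",
      {"ps_c": -1, "h_c": -1, "pe_c": 1, "co2_c": 1}, lb=0,
      gpr="gPSD1", subsystem="lipid synthesis", lump=True)
    R("PCSYN", "PE N-methyltransferase (C1 metabolism lumped)",
      {"pe_c": -1, "co2_c": -3, "nadph_c": -9, "atp_c": -3,
       "pc_c": 1, "nadp_c": 9, "adp_c": 3, "pi_c": 3}, lb=0,
      gpr="gCHO2 and gOPI3", subsystem="lipid synthesis", lump=True)

    # -- lipid body assembly and export ------------------------------------
    for b in ("tag", "ps", "pe", "pc"):
        R(f"{b.upper()}tl", f"{b} transport to lipid body",
          {f"{b}_c": -1, f"{b}_l": 1}, lb=0, subsystem="lipid body")
    pool_lipid = Reaction(
        id="POOL_lipid",
        name="lipid body content (90% TAG, 10% phospholipid, PS/PE/PC equal)",
        stoichiometry={
            "tag_l": -0.9 / mws["tag"],
            "ps_l": -(0.1 / 3) / mws["ps"],
            "pe_l": -(0.1 / 3) / mws["pe"],
            "pc_l": -(0.1 / 3) / mws["pc"],
            "lipid_l": 1.0,
        },
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="lipid body",
        pseudo=True,
    )
    model.add_reaction(pool_lipid)
    lumped.append(pool_lipid.id)
    R("LIPIDtle", "lipid body export", {"lipid_l": -1, "lipid_e": 1}, lb=0,
      subsystem="lipid body")

    # -- carbohydrate storage ----------------------------------------------
    R("PGMT", "phosphoglucomutase", {"g1p_c": -1, "g6p_c": 1},
      gpr="gPGM1", subsystem="carbohydrate synthesis")
    R("GALU", "UTP:glucose-1-phosphate uridylyltransferase",
      {"g1p_c": -1, "utp_c": -1, "h_c": -1, "udpg_c": 1, "ppi_c": 1}, lb=0,
      gpr="gUGP1", subsystem="carbohydrate synthesis")
    R("GLYCS", "glycogen synthase (anhydroglucose chain)",
      {"udpg_c": -1, "carbohydrate_c": 1, "udp_c": 1, "h_c": 1}, lb=0,
      gpr="gGSY1", subsystem="carbohydrate synthesis")
    R("PPA", "inorganic pyrophosphatase",
      {"ppi_c": -1, "h2o_c": -1, "pi_c": 2, "h_c": 1}, lb=0,
      gpr="gIPP1", subsystem="nucleotides")
    R("NDPKu", "nucleoside-diphosphate kinase (UDP)",
      {"atp_c": -1, "udp_c": -1, "adp_c": 1, "utp_c": 1},
      gpr="gYNK1", subsystem="nucleotides")
    R("NDPKc", "nucleoside-diphosphate kinase (CDP)",
      {"atp_c": -1, "cdp_c": -1, "adp_c": 1, "ctp_c": 1},
      gpr="gYNK1", subsystem="nucleotides")
    R("CMPK", "cytidylate kinase",
      {"atp_c": -1, "cmp_c": -1, "adp_c": 1, "cdp_c": 1},
      gpr="gURA6", subsystem="nucleotides")
    R("ADK1", "adenylate kinase", {"amp_c": -1, "atp_c": -1, "adp_c": 2},
      gpr="gADK1", subsystem="nucleotides")

    # -- nitrogen ----------------------------------------------------------
    # Overflow nitrogen metabolism: excess ammonium (uptake rates are pinned
    # in the protocols) is assimilated onto pyruvate and secreted as alanine,
    # the usual amino-acid overflow route of yeasts under N excess.
    R("ALADH", "alanine dehydrogenase (overflow N assimilation, lumped)",
      {"pyr_c": -1, "nh4_c": -1, "nadh_c": -1, "h_c": -1,
       "ala_c": 1, "h2o_c": 1, "nad_c": 1}, lb=0,
      gpr="gALT1", subsystem="nitrogen metabolism")
    R("ALAt", "alanine secretion", {"ala_c": -1, "ala_e": 1}, lb=0,
      subsystem="transport")
    R("UREASE", "urease",
      {"urea_c": -1, "h2o_c": -1, "h_c": -2, "co2_c": 1, "nh4_c": 2}, lb=0,
      gpr="gURE1", subsystem="nitrogen metabolism")

    # -- lumped macromolecule synthesis ------------------------------------
    R("PROTSYN", "protein synthesis (amino-acid metabolism lumped)",
      {"pyr_c": -1.2, "oaa_c": -0.4, "akg_c": -0.3, "nh4_c": -1.4,
       "so4_c": -0.03, "atp_c": -4.3, "h2o_c": -4.3, "nadph_c": -1.5,
       "protein_c": 1, "co2_c": 1.8, "adp_c": 4.3, "pi_c": 4.3, "h_c": 4.3,
       "nadp_c": 1.5}, lb=0,
      gpr="gAAS1", subsystem="amino-acid metabolism", lump=True)
    R("OTHERSYN", "nucleic acid / cofactor / mineral synthesis (lumped)",
      {"r5p_c": -0.2, "oaa_c": -0.1, "nh4_c": -0.3, "so4_c": -0.01,
       "fe2_c": -0.01, "k_c": -0.01, "na_c": -0.01,
       "atp_c": -2, "h2o_c": -2,
       "other_c": 1, "adp_c": 2, "pi_c": 2, "h_c": 2}, lb=0,
      subsystem="other biomass", lump=True)

    # -- maintenance -------------------------------------------------------
    ngam = Reaction(
        id="NGAM",
        name="non-growth-associated maintenance ATPase",
        stoichiometry={"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
        lower_bound=1.0,
        upper_bound=1.0,
        subsystem="maintenance",
        pseudo=True,
    )
    model.add_reaction(ngam)

    # -- optional ethanol assimilation -------------------------------------
    if include_ethanol_assimilation:
        R("ADH", "alcohol dehydrogenase",
          {"etoh_c": -1, "nad_c": -1, "acald_c": 1, "nadh_c": 1, "h_c": 1},
          gpr="gADH1", subsystem="ethanol assimilation")
        R("ALDH", "acetaldehyde dehydrogenase",
          {"acald_c": -1, "nad_c": -1, "h2o_c": -1,
           "ac_c": 1, "nadh_c": 1, "h_c": 2}, lb=0,
          gpr="gALD4", subsystem="ethanol assimilation")
        R("ICL", "isocitrate lyase",
          {"icit_m": -1, "glx_m": 1, "succ_m": 1}, lb=0,
          gpr="gICL1", subsystem="glyoxylate cycle")
        R("MALS", "malate synthase",
          {"accoa_m": -1, "glx_m": -1, "h2o_m": -1,
           "mal_m": 1, "coa_m": 1, "h_m": 1}, lb=0,
          gpr="gMLS1", subsystem="glyoxylate cycle")
        R("PEPCK", "PEP carboxykinase",
          {"oaa_c": -1, "atp_c": -1, "pep_c": 1, "adp_c": 1, "co2_c": 1}, lb=0,
          gpr="gPCK1", subsystem="gluconeogenesis")

    # -- biomass (static replete default; protocols install dynamic one) ---
    install_biomass(model, compose_biomass(0.0, mode="replete"), gam=gam)

    if bound_jitter and seed is not None:
        rng = np.random.default_rng(seed)
        for rxn in model.reactions.values():
            if model.category(rxn) in ("metabolic", "transport") and rxn.upper_bound > 0:
                rxn.upper_bound *= 1.0 + bound_jitter * rng.random()

    model.validate()

    from .model import classify_reactions

    manifest = ToyModelManifest(
        category_counts=dict(classify_reactions(model)),
        lumped_reactions=sorted(lumped),
        essential_genes=["gACL1", "gACC1", "gFAS1", "gFAS2", "gOLE1", "gFAD12"],
        acl_gene="gACL1",
        carbon_sources={
            "glucose": {"exchange": "EX_glc_e", "carbon_atoms": 6},
            "fructose": {"exchange": "EX_fru_e", "carbon_atoms": 6},
            "sucrose": {"exchange": "EX_sucr_e", "carbon_atoms": 12},
            "xylose": {"exchange": "EX_xyl_e", "carbon_atoms": 5},
            "glycerol": {"exchange": "EX_glyc_e", "carbon_atoms": 3},
            "ethanol": {"exchange": "EX_etoh_e", "carbon_atoms": 2},
        },
        nitrogen_sources={
            "nh4": {"exchange": "EX_nh4_e", "nitrogen_atoms": 1},
            "urea": {"exchange": "EX_urea_e", "nitrogen_atoms": 2},
        },
        pathways={
            "glycolysis": ["HEX1", "HEXf", "PGI", "PFK", "FBA", "TPI", "GAPD",
                           "PGK", "PGM", "ENO", "PYK"],
            "pentose phosphate pathway": ["G6PDH", "PGL", "GND", "RPI", "RPE",
                                          "TKT1", "TAL", "TKT2"],
            "phosphoketolase": ["XPK", "ACK"],
            "TCA": ["PDH", "CS", "ACONT", "ICDH", "AKGDH", "SUCOAS", "SUCD",
                    "FUM", "MDHm"],
            "lipid synthesis": ["ACL", "ACC", "FAS", "ELONG", "DESAT9",
                                "DESAT12", "POOL_acylcoa", "GPAT", "PAP",
                                "DGAT", "CDS", "PSS", "PSD", "PCSYN"],
            "amino-acid metabolism": ["PROTSYN"],
        },
        tracked_reactions={
            "citrate_transport": "CITtm",
            "acl": "ACL",
            "acyl_pool": "POOL_acylcoa",
            "lipid_exchange": "EX_lipid_e",
        },
        options={
            "include_ethanol_assimilation": include_ethanol_assimilation,
            "gam": gam,
            "po_nadh": PO_NADH,
            "po_fadh2": PO_FADH2,
        },
    )
    return model, manifest
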