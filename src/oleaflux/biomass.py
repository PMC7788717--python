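"""Condition-specific biomass objective function for oleaginous yeast.

Under nitrogen starvation the macromolecular composition of
*Cutaneotrichosporon oleaginosus* shifts with the carbon-to-nitrogen (C/N)
ratio of the medium: carbohydrate stays at 11% of dry cell weight (DCW),
5% is nucleic acids/minerals/cofactors ("other"), and protein plus total
lipid fill the remaining 84%, with the lipid weight percentage given by the
empirical quadratic

    lipid % DCW = -0.002 * x**2 + 0.59 * x + 1.9,    x = C/N in g/g,

clamped to [0, 79] so the protein fraction stays non-negative.  The lipid
fraction itself has a fixed profile: 90% triacylglycerol (TAG) and 10%
phospholipids split equally among phosphatidylserine (PS),
phosphatidylethanolamine (PE) and phosphatidylcholine (PC); fatty acids are
25% C16:0, 10% C18:0, 57% C18:1 and 7% C18:2 by weight.

The assembled biomass pseudo-reaction is standardized so the implied biomass
molecular weight is exactly 1 g/mmol: each component's stoichiometric
coefficient is its weight fraction divided by its molecular weight (g/mmol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .elements import ATOMIC_MASS, molecular_weight
from .model import MetabolicModel, Reaction

# -- empirical lipid-content model (C/N in g/g -> % DCW) --------------------
QUAD_A = -0.002
QUAD_B = 0.59
QUAD_C = 1.9
#: Upper clamp on lipid % DCW: with 11% carbohydrate and 5% other, protein
#: would go negative above 79%.
LIPID_PERCENT_MAX = 79.0
#: Vertex of the quadratic: the global maximum of the fitted lipid content.
LIPID_CN_VERTEX = -QUAD_B / (2 * QUAD_A)  # 147.5 g/g

# -- fixed composition constants -------------------------------------------
CARBOHYDRATE_FRACTION_STARVATION = 0.11
OTHER_FRACTION = 0.05
TAG_FRACTION_OF_LIPID = 0.90
PHOSPHOLIPID_FRACTION_OF_LIPID = 0.10  # split equally among PS, PE, PC

#: Fatty-acid weight percentages as printed (sum to 0.99).
FATTY_ACID_WEIGHT_FRACTIONS = {
    "C16:0": 0.25,
    "C18:0": 0.10,
    "C18:1": 0.57,
    "C18:2": 0.07,
}

#: Acyl-CoA pool coefficients, used exactly as stated; they represent the
#: fatty-acid weight percentages and sum to 0.966525.  Normalizing by their
#: own sum recovers the 25/10/57/7 shares.
ACYL_POOL_COEFFICIENTS = {
    "C16:0": 0.24952,
    "C18:0": 0.096712,
    "C18:1": 0.55233,
    "C18:2": 0.067963,
}

#: Default growth-associated maintenance, mmol ATP per g biomass.
DEFAULT_GAM = 60.0

#: Pseudo-species molecular weights (g/mmol) for components whose composition
#: is adopted rather than derived: averaged amino-acid residue and
#: anhydro-glucose residue; "other" is assigned 1 g/mmol.
PROTEIN_RESIDUE_MW = 0.110
CARBOHYDRATE_RESIDUE_MW = 0.162142  # C6H10O5
OTHER_MW = 1.0

C_OVER_N_MASS = ATOMIC_MASS["C"] / ATOMIC_MASS["N"]  # 12.011 / 14.007


class CompositionError(ValueError):
    """Raised when a biomass composition cannot be formed or is invalid."""


# ---------------------------------------------------------------------------
# Media and C/N ratios
# ---------------------------------------------------------------------------

#: Compounds the medium reader can resolve by name.
COMPOUND_REGISTRY: dict[str, str] = {
    "glycerol": "C3H8O3",
    "glucose": "C6H12O6",
    "fructose": "C6H12O6",
    "sucrose": "C12H22O11",
    "xylose": "C5H10O5",
    "ethanol": "C2H6O",
    "urea": "CH4N2O",
    "nh4cl": "NH4Cl",
}


@dataclass
class MediumComponent:
    """One medium compound: either a concentration (g/l) or an uptake rate
    (mmol·gDCW⁻¹·h⁻¹, negative = uptake by sign convention, stored as
    magnitude)."""

    id: str
    formula: str
    concentration_g_l: Optional[float] = None
    uptake_mmol: Optional[float] = None
    role: str = "other"  # carbon | nitrogen | other

    @property
    def mw(self) -> float:
        """g/mmol."""
        return molecular_weight(self.formula)

    @property
    def mmol(self) -> float:
        """mmol per liter (from concentration) or mmol flux magnitude."""
        if self.concentration_g_l is not None:
            return self.concentration_g_l / self.mw  # (g/l) / (g/mmol) = mmol/l
        if self.uptake_mmol is not None:
            return abs(self.uptake_mmol)
        raise CompositionError(f"component {self.id}: no concentration or uptake")

    def atoms(self, element: str) -> int:
        from .elements import parse_formula

        return parse_formula(self.formula).get(element, 0)


@dataclass
class MediumSpec:
    """A medium as a list of components with elemental composition."""

    components: list[MediumComponent] = field(default_factory=list)
    name: str = "medium"

    def total_mol(self, element: str) -> float:
        """Total mmol of ``element`` per liter (or per flux basis)."""
        return sum(c.mmol * c.atoms(element) for c in self.components)


@dataclass(frozen=True)
class CNRatio:
    """Carbon-to-nitrogen ratio in molar (mol C / mol N) and mass (g C / g N)."""

    molar: float
    mass: float

    @classmethod
    def from_molar(cls, molar: float) -> "CNRatio":
        return cls(molar=molar, mass=cn_molar_to_mass(molar))

    @classmethod
    def from_mass(cls, mass: float) -> "CNRatio":
        if mass < 0:
            raise ValueError(f"C/N (g/g) must be >= 0, got {mass}")
        return cls(molar=mass / C_OVER_N_MASS, mass=mass)


def cn_molar_to_mass(x: float) -> float:
    """Convert C/N from mol/mol to g/g (× 12.011/14.007); 12.83 → 11.0."""
    if x < 0:
        raise ValueError(f"C/N must be >= 0, got {x}")
    return x * C_OVER_N_MASS


def cn_ratio_from_medium(medium: MediumSpec) -> CNRatio:
    """C/N ratio of a medium (or of a pair of uptake rates).

    Molar ratio = total mol C / total mol N over all components; the per-hour
    basis of uptake rates cancels.  A nitrogen-free medium yields +inf.
    """
    mol_c = medium.total_mol("C")
    mol_n = medium.total_mol("N")
    if mol_c <= 0:
        raise CompositionError("medium has no carbon")
    if mol_n <= 0:
        return CNRatio(molar=math.inf, mass=math.inf)
    return CNRatio.from_molar(mol_c / mol_n)


def cn_from_uptakes(
    carbon_atoms: int, carbon_uptake: float, nitrogen_atoms: int, nitrogen_uptake: float
) -> CNRatio:
    """C/N ratio between carbon- and nitrogen-source uptake rates.

    Uptake magnitudes are used, so the sign convention (uptake negative) does
    not matter.
    """
    mol_c = abs(carbon_uptake) * carbon_atoms
    mol_n = abs(nitrogen_uptake) * nitrogen_atoms
    if mol_n <= 0:
        return CNRatio(molar=math.inf, mass=math.inf)
    return CNRatio.from_molar(mol_c / mol_n)


# ---------------------------------------------------------------------------
# Lipid content and biomass composition
# ---------------------------------------------------------------------------

def lipid_weight_percent(cn_gg: float) -> float:
    """Total lipid content in % of DCW at a given C/N (g/g), clamped to [0, 79].

    Monotone non-decreasing up to the vertex at C/N = 147.5 g/g, decreasing
    beyond it as the fitted quadratic dictates (no plateau is imposed).
    """
    if cn_gg < 0:
        raise ValueError(f"C/N (g/g) must be >= 0, got {cn_gg}")
    y = QUAD_A * cn_gg**2 + QUAD_B * cn_gg + QUAD_C
    return min(max(y, 0.0), LIPID_PERCENT_MAX)


@dataclass
class BiomassComposition:
    """Macromolecule weight fractions of dry cell weight.

    ``mode`` is ``"starvation"`` (nitrogen-limited, condition-specific) or
    ``"replete"`` (static default composition).  Fractions sum to 1.
    """

    w_carbohydrate: float
    w_protein: float
    w_lipid: float
    w_other: float
    mode: str = "starvation"
    cn_gg: Optional[float] = None
    tag_fraction: float = TAG_FRACTION_OF_LIPID
    phospholipid_fraction: float = PHOSPHOLIPID_FRACTION_OF_LIPID

    def __post_init__(self) -> None:
        fractions = [self.w_carbohydrate, self.w_protein, self.w_lipid, self.w_other]
        if any(f < -1e-12 or f > 1 for f in fractions):
            raise CompositionError(f"fractions outside [0,1]: {fractions}")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise CompositionError(f"fractions sum to {sum(fractions)}, not 1")

    def lipid_masses(self) -> dict[str, float]:
        """Mass share of DCW per lipid component (TAG, PS, PE, PC)."""
        pl = self.w_lipid * self.phospholipid_fraction / 3.0
        return {
            "tag": self.w_lipid * self.tag_fraction,
            "ps": pl,
            "pe": pl,
            "pc": pl,
        }


#: Static composition used in nitrogen-replete ("standard biomass") mode.
REPLETE_COMPOSITION = dict(
    w_carbohydrate=0.40, w_protein=0.45, w_lipid=0.10, w_other=0.05
)


def compose_biomass(cn_gg: float, mode: str = "starvation") -> BiomassComposition:
    """Biomass composition at a given C/N ratio (g/g).

    Starvation mode: carbohydrate 11%, other 5%, lipid from the quadratic,
    protein = 0.95 - 0.11 - lipid.  Replete mode ignores ``cn_gg`` and uses a
    static default composition.
    """
    if mode == "replete":
        return BiomassComposition(mode="replete", cn_gg=cn_gg, **REPLETE_COMPOSITION)
    if mode != "starvation":
        raise ValueError(f"unknown biomass mode {mode!r}")
    w_tl = lipid_weight_percent(cn_gg) / 100.0
    w_p = 0.95 - CARBOHYDRATE_FRACTION_STARVATION - w_tl
    if w_p < -1e-12:
        raise CompositionError(f"protein fraction negative at C/N {cn_gg}")
    return BiomassComposition(
        w_carbohydrate=CARBOHYDRATE_FRACTION_STARVATION,
        w_protein=max(w_p, 0.0),
        w_lipid=w_tl,
        w_other=OTHER_FRACTION,
        mode="starvation",
        cn_gg=cn_gg,
    )


# ---------------------------------------------------------------------------
# Acyl-CoA pool and biomass reaction assembly
# ---------------------------------------------------------------------------

#: Metabolite ids of the fatty-acyl-CoA species in the cytosol, keyed by chain.
ACYL_COA_IDS = {
    "C16:0": "pmtcoa_c",
    "C18:0": "stcoa_c",
    "C18:1": "odecoa_c",
    "C18:2": "lnlccoa_c",
}


def acyl_pool_fractions() -> dict[str, float]:
    """Pool coefficients normalized by their own sum (0.966525) → weight shares."""
    total = sum(ACYL_POOL_COEFFICIENTS.values())
    return {k: v / total for k, v in ACYL_POOL_COEFFICIENTS.items()}


def acyl_pool_reaction(pool_id: str = "acylcoa_pool_c") -> Reaction:
    """The artificial acyl-CoA pool reaction.

    0.24952 C16:0-CoA + 0.096712 C18:0-CoA + 0.55233 C18:1-CoA +
    0.067963 C18:2-CoA → acyl-CoA pool.  Coefficients are the fatty-acid
    weight percentages and are used exactly as stated.
    """
    stoich = {
        ACYL_COA_IDS[chain]: -coeff for chain, coeff in ACYL_POOL_COEFFICIENTS.items()
    }
    stoich[pool_id] = 1.0
    return Reaction(
        id="POOL_acylcoa",
        name="acyl-CoA pool (lumped fatty-acyl weight-fraction pool)",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="lipid synthesis",
        pseudo=True,
    )


#: Biomass component -> cytosolic pseudo-species id.
BIOMASS_COMPONENT_IDS = {
    "carbohydrate": "carbohydrate_c",
    "protein": "protein_c",
    "tag": "tag_c",
    "ps": "ps_c",
    "pe": "pe_c",
    "pc": "pc_c",
    "other": "other_c",
}

_GAM_SPECIES = {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0}


def assemble_biomass_reaction(
    composition: BiomassComposition,
    model: MetabolicModel,
    gam: float = DEFAULT_GAM,
    reaction_id: str = "BIOMASS",
) -> Reaction:
    """Assemble a mass-normalized biomass reaction for ``composition``.

    Each component's coefficient is its weight fraction divided by the
    component molecular weight (g/mmol), so the summed coefficient×MW product
    — the implied biomass molecular weight — is exactly 1 g/mmol.  A GAM ATP
    hydrolysis term (``gam`` mmol ATP per g biomass) is included.
    """
    masses = {
        "carbohydrate": composition.w_carbohydrate,
        "protein": composition.w_protein,
        "other": composition.w_other,
        **composition.lipid_masses(),
    }
    missing = [
        mid for mid in BIOMASS_COMPONENT_IDS.values() if mid not in model.metabolites
    ]
    if missing:
        raise CompositionError(f"model lacks biomass pseudo-species: {missing}")
    stoich: dict[str, float] = {}
    for comp, mass in masses.items():
        mid = BIOMASS_COMPONENT_IDS[comp]
        mw = model.metabolites[mid].mw
        if mw is None or mw <= 0:
            raise CompositionError(f"biomass component {mid} lacks a molecular weight")
        if mass > 0:
            stoich[mid] = -mass / mw
    for mid, sign in _GAM_SPECIES.items():
        stoich[mid] = stoich.get(mid, 0.0) + sign * gam
    name = f"biomass ({composition.mode}"
    if composition.cn_gg is not None:
        name += f", C/N {composition.cn_gg:g} g/g"
    name += ")"
    return Reaction(
        id=reaction_id,
        name=name,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="biomass",
        pseudo=True,
    )


def biomass_molecular_weight(rxn: Reaction, model: MetabolicModel) -> float:
    """Implied biomass MW: Σ |coeff| × component MW over biomass components (g/mmol)."""
    component_ids = set(BIOMASS_COMPONENT_IDS.values())
    return sum(
        -coeff * model.metabolites[mid].mw
        for mid, coeff in rxn.stoichiometry.items()
        if mid in component_ids
    )


def composition_from_reaction(rxn: Reaction, model: MetabolicModel) -> dict[str, float]:
    """Recover component weight fractions from an assembled biomass reaction."""
    inverse = {v: k for k, v in BIOMASS_COMPONENT_IDS.items()}
    masses: dict[str, float] = {}
    for mid, coeff in rxn.stoichiometry.items():
        if mid in inverse:
            masses[inverse[mid]] = -coeff * model.metabolites[mid].mw
    return masses


def install_biomass(
    model: MetabolicModel,
    composition: BiomassComposition,
    gam: float = DEFAULT_GAM,
    reaction_id: str = "BIOMASS",
) -> Reaction:
    """Replace/register the model's biomass reaction and set it as objective."""
    rxn = assemble_biomass_reaction(composition, model, gam=gam, reaction_id=reaction_id)
    if reaction_id in model.reactions:
        model.reactions[reaction_id] = rxn
    else:
        model.add_reaction(rxn)
    model.objective_reaction_id = reaction_id
    return rxn
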