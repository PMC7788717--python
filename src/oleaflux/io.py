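"""Readers and writers: SBML L3+FBC, native JSON dialect, media, flux tables.

The native dialect is canonically ordered JSON with an explicit schema
version; loading and saving it is lossless and bit-stable, which makes exact
diffs possible in tests.  SBML import/export covers the FBC v2 subset used by
genome-scale models (flux bounds, objective, gene-product associations,
formulas/charges); unsupported constructs are ignored with a warning, never
fatal.  Media files are YAML mappings or two-column TSV, with compound names
resolved through a small registry (glycerol, glucose, fructose, sucrose,
xylose, ethanol, urea, NH4Cl).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import libsbml
import pandas as pd
import yaml

from .biomass import COMPOUND_REGISTRY, MediumComponent, MediumSpec
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    gpr_from_string,
)

JSON_SCHEMA_VERSION = 1


@dataclass
class ModelDocument:
    """A model together with its source metadata."""

    model: MetabolicModel
    format: str = "json"
    source: Optional[str] = None
    level: Optional[int] = None
    version: Optional[int] = None


# ---------------------------------------------------------------------------
# Native JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema_version": JSON_SCHEMA_VERSION,
        "id": model.id,
        "name": model.name,
        "compartments": dict(sorted(model.compartments.items())),
        "objective": model.objective_reaction_id,
        "annotations": dict(sorted(model.annotations.items())),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
                "mw": m.mw,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gene_rule() or None,
                "subsystem": r.subsystem,
                "pseudo": r.pseudo,
            }
            for r in model.reactions.values()
        ],
    }


def model_from_dict(data: dict) -> MetabolicModel:
    if data.get("schema_version") != JSON_SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {data.get('schema_version')}")
    model = MetabolicModel(data["id"], data.get("name", ""), data["compartments"])
    model.annotations = dict(data.get("annotations", {}))
    for m in data["metabolites"]:
        model.add_metabolite(
            Metabolite(
                m["id"],
                name=m.get("name", ""),
                compartment=m["compartment"],
                formula=m.get("formula"),
                charge=m.get("charge"),
                mw=m.get("mw"),
            )
        )
    for r in data["reactions"]:
        model.add_reaction(
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry=dict(r["stoichiometry"]),
                lower_bound=r.get("lower_bound", -DEFAULT_BOUND),
                upper_bound=r.get("upper_bound", DEFAULT_BOUND),
                gpr=gpr_from_string(r["gpr"]) if r.get("gpr") else None,
                subsystem=r.get("subsystem", ""),
                pseudo=r.get("pseudo", False),
            )
        )
    model.objective_reaction_id = data.get("objective")
    model.validate()
    return model


def write_json(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Write the canonical JSON dialect (deterministic byte-for-byte)."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=False)
        fh.write("\n")


def read_json(path: Union[str, Path]) -> ModelDocument:
    with open(path) as fh:
        model = model_from_dict(json.load(fh))
    return ModelDocument(model=model, format="json", source=str(path))


# ---------------------------------------------------------------------------
# SBML L3V1 + FBC v2
# ---------------------------------------------------------------------------

def _sid(raw: str) -> str:
    """Make an SBML-safe SId (prefix leading digits, replace separators)."""
    out = raw.replace(":", "__58__").replace("-", "__45__").replace(".", "__46__")
    if out and (out[0].isdigit()):
        out = "_" + out
    return out


def _unsid(raw: str) -> str:
    out = raw
    if out.startswith("_") and len(out) > 1 and out[1].isdigit():
        out = out[1:]
    return out.replace("__58__", ":").replace("__45__", "-").replace("__46__", ".")


def write_sbml(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Export as SBML Level 3 Version 1 with the FBC v2 package."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sid(model.id))
    sm.setName(model.name)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)
    if model.annotations:
        sm.setNotes(
            "<body xmlns='http://www.w3.org/1999/xhtml'><p>ANNOTATIONS: "
            + json.dumps(model.annotations, sort_keys=True)
            + "</p></body>"
        )

    for code, name in model.compartments.items():
        comp = sm.createCompartment()
        comp.setId(_sid(code))
        comp.setName(name)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_sid(met.id))
        sp.setName(met.name)
        sp.setCompartment(_sid(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))
        if met.formula is None and met.mw is not None:
            sp.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'><p>MW_G_PER_MMOL: "
                f"{met.mw!r}</p></body>"
            )

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sid(gene))
        gp.setLabel(gene)

    bounds_seen: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bounds_seen:
            pid = f"fb_{len(bounds_seen)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bounds_seen[value] = pid
        return bounds_seen[value]

    def set_association(node, expr):
        if expr.op == "gene":
            ref = node.createGeneProductRef()
            ref.setGeneProduct(_sid(expr.gene))
        elif expr.op == "and":
            sub = node.createAnd()
            for child in expr.children:
                set_association(sub, child)
        else:
            sub = node.createOr()
            for child in expr.children:
                set_association(sub, child)

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(_sid(rxn.id))
        sr.setName(rxn.name)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        if rxn.subsystem or rxn.pseudo:
            sr.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {rxn.subsystem}</p><p>PSEUDO: {rxn.pseudo}</p></body>"
            )
        for mid, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(_sid(mid))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            assoc = rplug.createGeneProductAssociation()
            set_association(assoc, rxn.gpr)

    if model.objective_reaction_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sid(model.objective_reaction_id))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _notes_fields(notes: Optional[str]) -> dict[str, str]:
    import html

    out: dict[str, str] = {}
    if not notes:
        return out
    notes = html.unescape(notes)
    for line in notes.replace("<p>", "\n").replace("</p>", "\n").splitlines():
        if ":" in line:
            key, _, value = line.partition(":")
            key = key.strip().lstrip("<>/ ")
            if key.isupper():
                out[key] = value.strip()
    return out


def _gpr_from_association(assoc) -> Optional[str]:
    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        return _unsid(assoc.getGeneProduct())
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_gpr_from_association(assoc.getAssociation(i))
                 for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(p for p in parts if p) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_gpr_from_association(assoc.getAssociation(i))
                 for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(p for p in parts if p) + ")"
    return None


def read_sbml(path: Union[str, Path]) -> ModelDocument:
    """Read SBML (Level 3 + FBC preferred); bounds default with a warning."""
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(
            f"SBML parse error in {path}: "
            f"{doc.getError(0).getMessage() if doc.getNumErrors() else 'unknown'}"
        )
    sm = doc.getModel()
    if sm is None:
        raise ValueError(f"no model element in {path}")
    compartments = {
        _unsid(sm.getCompartment(i).getId()): sm.getCompartment(i).getName() or
        _unsid(sm.getCompartment(i).getId())
        for i in range(sm.getNumCompartments())
    }
    model = MetabolicModel(_unsid(sm.getId()) or "model", sm.getName() or "", compartments)
    mfields = _notes_fields(sm.getNotesString() if sm.isSetNotes() else None)
    if "ANNOTATIONS" in mfields:
        try:
            model.annotations = json.loads(mfields["ANNOTATIONS"])
        except json.JSONDecodeError:
            pass
    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula() or None
            if splug.isSetCharge():
                charge = splug.getCharge()
        mw = None
        fields = _notes_fields(sp.getNotesString() if sp.isSetNotes() else None)
        if "MW_G_PER_MMOL" in fields:
            mw = float(fields["MW_G_PER_MMOL"])
        model.add_metabolite(
            Metabolite(
                _unsid(sp.getId()),
                name=sp.getName() or "",
                compartment=_unsid(sp.getCompartment()),
                formula=formula,
                charge=charge,
                mw=mw,
            )
        )
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _unsid(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _unsid(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb = ub = None
        gpr = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound())
            if rplug.isSetGeneProductAssociation():
                gpr = _gpr_from_association(
                    rplug.getGeneProductAssociation().getAssociation()
                )
        if lb is None or ub is None:
            warnings.warn(
                f"reaction {sr.getId()}: missing flux bounds, using defaults"
            )
            lb = -DEFAULT_BOUND if sr.getReversible() else 0.0
            ub = DEFAULT_BOUND
        fields = _notes_fields(sr.getNotesString() if sr.isSetNotes() else None)
        model.add_reaction(
            Reaction(
                id=_unsid(sr.getId()),
                name=sr.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr_from_string(gpr) if gpr else None,
                subsystem=fields.get("SUBSYSTEM", ""),
                pseudo=fields.get("PSEUDO", "False") == "True",
            )
        )
    mplug = sm.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_reaction_id = _unsid(obj.getFluxObjective(0).getReaction())
    model.validate()
    return ModelDocument(
        model=model,
        format="sbml",
        source=str(path),
        level=sm.getLevel(),
        version=sm.getVersion(),
    )


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------

def _component_from_entry(cid: str, entry) -> MediumComponent:
    from .elements import parse_formula

    if isinstance(entry, dict):
        formula = entry.get("formula") or COMPOUND_REGISTRY.get(cid.lower())
        conc = entry.get("concentration_g_l", entry.get("g_l"))
        uptake = entry.get("uptake_mmol", entry.get("uptake"))
    else:
        formula = COMPOUND_REGISTRY.get(cid.lower())
        conc = float(entry)
        uptake = None
    if formula is None:
        raise ValueError(f"medium compound {cid!r}: unknown and no formula given")
    counts = parse_formula(formula)
    if counts.get("N", 0) > 0:
        role = "nitrogen"
    elif counts.get("C", 0) > 0:
        role = "carbon"
    else:
        role = "other"
    return MediumComponent(
        id=cid,
        formula=formula,
        concentration_g_l=conc,
        uptake_mmol=uptake,
        role=role,
    )


def read_medium(path: Union[str, Path]) -> MediumSpec:
    """Read a medium file (YAML mapping or two-column TSV: compound, g/l)."""
    path = Path(path)
    components: list[MediumComponent] = []
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text()) or {}
        for cid, entry in data.items():
            components.append(_component_from_entry(str(cid), entry))
    else:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cid, value = line.split("\t")[:2]
            components.append(_component_from_entry(cid, float(value)))
    return MediumSpec(components=components, name=path.stem)


# ---------------------------------------------------------------------------
# Tabular results
# ---------------------------------------------------------------------------

def write_flux_table(
    table: pd.DataFrame, path: Union[str, Path], index_label: str = "reaction"
) -> None:
    """Write a result table as TSV, floats at 6 significant digits."""
    table.to_csv(path, sep="\t", float_format="%.6g", index_label=index_label)


def flux_solution_table(solution, model: MetabolicModel) -> pd.DataFrame:
    """One-column flux table (reaction, subsystem, flux) from an FBA solution."""
    if solution.fluxes is None:
        raise ValueError("solution has no flux vector")
    return pd.DataFrame(
        {
            "subsystem": [model.reactions[r].subsystem for r in solution.fluxes.index],
            "flux": solution.fluxes,
        }
    )
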