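"""In-memory representation of a compartmentalized genome-scale metabolic model.

The model is a plain container of metabolites and reactions with signed
stoichiometries (negative = consumed), flux bounds in mmol·gDCW⁻¹·h⁻¹, and
boolean gene–protein–reaction (GPR) rules.  Exchange reactions are written so
that positive flux means production/secretion and negative flux means uptake.

Reaction categories (exchange / transport / metabolic / biomass / pseudo) are
*derived* from structure rather than trusted from annotations: an exchange
involves exactly one extracellular species, a transport spans at least two
compartments, biomass and pool/maintenance pseudo-reactions are flagged by id
prefix or an explicit flag, and everything else is metabolic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .elements import ATOMIC_MASS, molecular_weight, parse_formula

#: Default flux bound magnitude when none is specified.
DEFAULT_BOUND = 1000.0

#: Compartment code of the extracellular space.
EXTRACELLULAR = "e"

#: Reaction-id prefixes that mark pseudo reactions (pools, sinks, dissipation,
#: maintenance).  Biomass reactions use the ``BIOMASS`` prefix.
PSEUDO_PREFIXES = ("POOL_", "DISS_", "NGAM", "SK_", "DM_")


class StructuralIntegrityError(ValueError):
    """A reaction references an undeclared metabolite or violates invariants."""


class GprParseError(ValueError):
    """A GPR expression string or tree is malformed."""


# ---------------------------------------------------------------------------
# GPR expression trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprExpression:
    """Boolean AND/OR tree over gene identifiers.

    ``op`` is one of ``"and"``, ``"or"`` or ``"gene"``.  Leaves carry the gene
    id in ``gene`` and have no children.
    """

    op: str
    gene: Optional[str] = None
    children: tuple["GprExpression", ...] = ()

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene or self.children:
                raise GprParseError("gene leaf must carry a gene id and no children")
        elif self.op in ("and", "or"):
            if len(self.children) < 2 or self.gene is not None:
                raise GprParseError(f"{self.op} node needs >=2 children and no gene id")
        else:
            raise GprParseError(f"unknown GPR node type {self.op!r}")

    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset([self.gene])
        return frozenset().union(*(c.genes() for c in self.children))

    def evaluate(self, deleted: Iterable[str] = ()) -> bool:
        """True when the reaction retains catalysis with ``deleted`` knocked out."""
        deleted = frozenset(deleted)
        if self.op == "gene":
            return self.gene not in deleted
        if self.op == "and":
            return all(c.evaluate(deleted) for c in self.children)
        return any(c.evaluate(deleted) for c in self.children)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op != "gene" and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


def gpr_from_string(rule: str) -> Optional[GprExpression]:
    """Parse a rule like ``"g1 and (g2 or g3)"`` into a :class:`GprExpression`.

    Returns ``None`` for an empty rule.  ``and`` binds tighter than ``or``.
    """
    tokens = rule.replace("(", " ( ").replace(")", " ) ").split()
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprExpression:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return GprExpression("or", children=tuple(terms))

    def parse_and() -> GprExpression:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        if len(terms) == 1:
            return terms[0]
        return GprExpression("and", children=tuple(terms))

    def parse_atom() -> GprExpression:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR rule {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GprParseError(f"unbalanced parentheses in {rule!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r} in {rule!r}")
        return GprExpression("gene", gene=take())

    node = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in GPR rule {rule!r}")
    return node


def evaluate_gpr(gpr: Optional[GprExpression], deleted: Iterable[str] = ()) -> bool:
    """Evaluate a GPR against a set of deleted genes.

    Reactions without a GPR (``None``) are unaffected by any deletion.
    """
    if gpr is None:
        return True
    return gpr.evaluate(deleted)


# ---------------------------------------------------------------------------
# Metabolites and reactions
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``mw`` is the molecular weight in g/mmol.  It is derived from ``formula``
    when a formula is given; pseudo-species (no formula) may carry an annotated
    ``mw`` instead.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None
    mw: Optional[float] = None

    def __post_init__(self) -> None:
        if self.formula is not None:
            derived = molecular_weight(self.formula)
            if self.mw is None:
                self.mw = derived
        if self.mw is not None and self.mw <= 0:
            raise ValueError(f"metabolite {self.id}: mw must be > 0, got {self.mw}")

    @property
    def elements(self) -> dict[str, int]:
        return parse_formula(self.formula) if self.formula else {}


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  ``pseudo`` marks lumped artificial reactions (pools, sinks,
    maintenance, dissipation) that are exempt from elemental balance.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: Optional[GprExpression] = None
    subsystem: str = ""
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.id.startswith(PSEUDO_PREFIXES) or self.id.startswith("BIOMASS"):
            self.pseudo = True

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def gene_rule(self) -> str:
        return self.gpr.to_string() if self.gpr is not None else ""


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

class MetabolicModel:
    """Container of metabolites, reactions, genes and compartments.

    Metabolite and reaction order is insertion order and is the row/column
    order used by :func:`stoichiometric_matrix`.
    """

    def __init__(
        self,
        model_id: str = "model",
        name: str = "",
        compartments: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.id = model_id
        self.name = name or model_id
        self.compartments: dict[str, str] = dict(compartments or {})
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.genes: set[str] = set()
        self.objective_reaction_id: Optional[str] = None
        self.annotations: dict[str, str] = {}

    # -- construction ------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise StructuralIntegrityError(f"duplicate metabolite id {met.id!r}")
        if met.compartment not in self.compartments:
            raise StructuralIntegrityError(
                f"metabolite {met.id}: undeclared compartment {met.compartment!r}"
            )
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise StructuralIntegrityError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise StructuralIntegrityError(
                    f"reaction {rxn.id}: undeclared metabolite {mid!r}"
                )
        self.reactions[rxn.id] = rxn
        if rxn.gpr is not None:
            self.genes |= rxn.gpr.genes()
        return rxn

    def remove_reaction(self, rxn_id: str) -> None:
        self.reactions.pop(rxn_id)

    def copy(self) -> "MetabolicModel":
        import copy as _copy

        return _copy.deepcopy(self)

    # -- categories --------------------------------------------------------
    def compartments_of(self, rxn: Reaction) -> set[str]:
        return {self.metabolites[m].compartment for m in rxn.stoichiometry}

    def is_exchange(self, rxn: Reaction) -> bool:
        if len(rxn.stoichiometry) != 1:
            return False
        (mid,) = rxn.stoichiometry
        return self.metabolites[mid].compartment == EXTRACELLULAR

    def category(self, rxn: Reaction) -> str:
        """Structural category: biomass, pseudo, exchange, transport or metabolic."""
        if rxn.id.startswith("BIOMASS"):
            return "biomass"
        if rxn.pseudo:
            return "pseudo"
        if self.is_exchange(rxn):
            return "exchange"
        if len(self.compartments_of(rxn)) >= 2:
            return "transport"
        return "metabolic"

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if self.category(r) == "exchange"]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`StructuralIntegrityError` on any invariant violation."""
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise StructuralIntegrityError(
                    f"metabolite {met.id}: undeclared compartment {met.compartment!r}"
                )
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise StructuralIntegrityError(f"reaction {rxn.id}: lb > ub")
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise StructuralIntegrityError(
                        f"reaction {rxn.id}: undeclared metabolite {mid!r}"
                    )
        if (
            self.objective_reaction_id is not None
            and self.objective_reaction_id not in self.reactions
        ):
            raise StructuralIntegrityError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )


# ---------------------------------------------------------------------------
# Structural operations
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: MetabolicModel) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense stoichiometric matrix S (metabolites × reactions).

    Returns ``(S, metabolite_ids, reaction_ids)`` where row/column order is
    the model's insertion order.  ``S[i, j]`` is reaction j's signed
    coefficient for metabolite i, zero where the metabolite does not
    participate.
    """
    model.validate()
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            S[met_index[mid], j] = coeff
    return S, met_ids, rxn_ids


def classify_reactions(model: MetabolicModel) -> Counter:
    """Counts per structural category; the counts partition the reaction set."""
    return Counter(model.category(r) for r in model.reactions.values())


def mass_balance_report(model: MetabolicModel, tol: float = 1e-6) -> pd.DataFrame:
    """Per-reaction elemental imbalance table.

    For each non-pseudo reaction whose participants all carry formulas the
    imbalance per element is ``sum(coeff * element_count)``; a reaction is
    balanced when every element's imbalance is within ``tol``.  Reactions
    touching formula-less (pseudo) species are flagged ``exempt`` and not
    judged; missing formulas are reported, never fatal.
    """
    rows = []
    for rxn in model.reactions.values():
        if model.category(rxn) in ("exchange", "biomass", "pseudo"):
            rows.append(
                {"reaction": rxn.id, "status": "exempt", "imbalance": {}, "missing": []}
            )
            continue
        missing = [
            mid for mid in rxn.stoichiometry if model.metabolites[mid].formula is None
        ]
        if missing:
            rows.append(
                {"reaction": rxn.id, "status": "exempt", "imbalance": {}, "missing": missing}
            )
            continue
        imbalance: dict[str, float] = {}
        for mid, coeff in rxn.stoichiometry.items():
            for el, n in model.metabolites[mid].elements.items():
                imbalance[el] = imbalance.get(el, 0.0) + coeff * n
        imbalance = {el: v for el, v in imbalance.items() if abs(v) > tol}
        status = "balanced" if not imbalance else "imbalanced"
        rows.append(
            {"reaction": rxn.id, "status": status, "imbalance": imbalance, "missing": []}
        )
    return pd.DataFrame(rows, columns=["reaction", "status", "imbalance", "missing"])


def knockout_bounds(model: MetabolicModel, deleted: Iterable[str]) -> MetabolicModel:
    """Copy of ``model`` with reactions losing catalysis closed to [0, 0].

    Unknown gene ids raise ``KeyError``; genes absent from every GPR are an
    error by the same rule.
    """
    deleted = set(deleted)
    unknown = deleted - model.genes
    if unknown:
        raise KeyError(f"unknown gene id(s): {sorted(unknown)}")
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.gpr is not None and not evaluate_gpr(rxn.gpr, deleted):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out
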