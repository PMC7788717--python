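"""Detection of thermodynamically infeasible energy-generating cycles.

A curated model must not be able to produce energy carriers from nothing.
The audit adds one dissipation pseudo-reaction per carrier (ATP, CTP, GTP,
UTP, NADH, NADPH, FADH2 and the transmembrane proton gradient), clamps every
other reaction to [-1, 1] (reversible) or [0, 1] (irreversible), closes all
exchange uptakes (secretion stays open), and maximizes each dissipation flux
in turn.  Any strictly positive maximum certifies an energy-generating cycle
and the non-zero fluxes of the optimal solution form the implicated support.

Dissipation stoichiometries (cytosolic unless noted):

* NTP + H2O -> NDP + Pi + H+  (ATP; CTP/UTP cytosolic, GTP mitochondrial)
* NAD(P)H -> NAD(P)+ + H+
* FADH2 -> FAD + 2 H+  (mitochondrial)
* H+(c) -> H+(e)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .fba import fba
from .model import MetabolicModel, Reaction

#: carrier -> (dissipation id, stoichiometry)
DISSIPATION_SPECS: dict[str, dict[str, float]] = {
    "ATP": {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
    "CTP": {"ctp_c": -1, "h2o_c": -1, "cdp_c": 1, "pi_c": 1, "h_c": 1},
    "GTP": {"gtp_m": -1, "h2o_m": -1, "gdp_m": 1, "pi_m": 1, "h_m": 1},
    "UTP": {"utp_c": -1, "h2o_c": -1, "udp_c": 1, "pi_c": 1, "h_c": 1},
    "NADH": {"nadh_c": -1, "nad_c": 1, "h_c": 1},
    "NADPH": {"nadph_c": -1, "nadp_c": 1, "h_c": 1},
    "FADH2": {"fadh2_m": -1, "fad_m": 1, "h_m": 2},
    "PROTON": {"h_c": -1, "h_e": 1},
}


@dataclass
class AuditReport:
    """Per-carrier maximal dissipation fluxes and implicated cycle supports."""

    maxima: dict[str, float] = field(default_factory=dict)
    supports: dict[str, list[str]] = field(default_factory=dict)
    statuses: dict[str, str] = field(default_factory=dict)
    tol: float = 1e-6

    @property
    def passed(self) -> bool:
        return all(v <= self.tol for v in self.maxima.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "carrier": c,
                "max_dissipation": self.maxima[c],
                "status": self.statuses.get(c, ""),
                "support": ";".join(self.supports.get(c, [])),
            }
            for c in self.maxima
        ]
        return pd.DataFrame(rows)


def add_dissipation_reactions(model: MetabolicModel, warn: bool = True) -> MetabolicModel:
    """Add the eight energy-dissipation pseudo-reactions in place (idempotent).

    Carriers whose metabolites are absent are skipped with a warning.  The
    added reactions are flagged pseudo (``DISS_`` prefix) and therefore do not
    count as metabolic reactions in the category census.
    """
    import warnings

    for carrier, stoich in DISSIPATION_SPECS.items():
        rid = f"DISS_{carrier}"
        if rid in model.reactions:
            continue
        missing = [m for m in stoich if m not in model.metabolites]
        if missing:
            if warn:
                warnings.warn(f"dissipation {carrier}: missing {missing}, skipped")
            continue
        model.add_reaction(
            Reaction(
                id=rid,
                name=f"{carrier} dissipation",
                stoichiometry=dict(stoich),
                lower_bound=0.0,
                upper_bound=1000.0,
                subsystem="energy audit",
                pseudo=True,
            )
        )
    return model


def detect_energy_cycles(model: MetabolicModel, tol: float = 1e-6) -> AuditReport:
    """Maximize each dissipation reaction on the clamped, uptake-free network.

    Non-dissipation reactions are clamped to [-1, 1] if reversible (lb < 0)
    or [0, 1] otherwise; every exchange lower bound is closed to 0.  The
    model passes when all maxima are (numerically) zero.
    """
    work = model.copy()
    add_dissipation_reactions(work, warn=False)
    diss_ids = [r for r in work.reactions if r.startswith("DISS_")]
    for rxn in work.reactions.values():
        if rxn.id in diss_ids:
            continue
        if work.category(rxn) == "exchange":
            # no uptake; secretion stays open (capped at 1)
            rxn.lower_bound, rxn.upper_bound = 0.0, 1.0
            continue
        if rxn.lower_bound < 0:
            rxn.lower_bound, rxn.upper_bound = -1.0, 1.0
        else:
            # forced fluxes (e.g. maintenance) are released for the audit
            rxn.lower_bound, rxn.upper_bound = 0.0, 1.0
    report = AuditReport(tol=tol)
    for rid in diss_ids:
        carrier = rid.removeprefix("DISS_")
        sol = fba(work, rid, sense="max")
        if not sol.optimal:
            report.maxima[carrier] = 0.0
            report.statuses[carrier] = sol.status
            continue
        report.maxima[carrier] = max(sol.objective, 0.0)
        report.statuses[carrier] = sol.status
        if sol.objective > tol:
            support = [
                r
                for r, v in sol.fluxes.items()
                if abs(v) > tol and r != rid
            ]
            report.supports[carrier] = support
    return report
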