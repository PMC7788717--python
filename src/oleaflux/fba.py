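"""Flux balance analysis and the lipid-production simulation protocols.

FBA solves ``max/min c·v  s.t.  S·v = 0, lb <= v <= ub`` with the HiGHS LP
solver.  On top of it sit the study protocols: minimal-medium setup,
equal-C-mol carbon-source screens, the fixed-biomass lipid-maximization
protocol (grow maximally, pin growth into a window, then maximize the
lipid-body exchange), and GPR-based gene knockouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .biomass import (
    DEFAULT_GAM,
    cn_from_uptakes,
    compose_biomass,
    install_biomass,
)
from .model import MetabolicModel, Reaction, knockout_bounds, stoichiometric_matrix

#: Exchanged species with unlimited uptake in the minimal medium.
MINIMAL_MEDIUM_OPEN = (
    "EX_co2_e",
    "EX_h2o_e",
    "EX_h_e",
    "EX_o2_e",
    "EX_fe2_e",
    "EX_pi_e",
    "EX_k_e",
    "EX_na_e",
    "EX_so4_e",
    "EX_nh4_e",
)


@dataclass
class ProtocolParams:
    """Tunable constants of the growth/lipid protocols.

    ``mu_max``: growth-rate ceiling (h⁻¹) past the critical C/N;
    ``window``: lower-bound factor for the pinned biomass window;
    ``ngam``: non-growth-associated maintenance (mmol ATP·gDCW⁻¹·h⁻¹);
    ``validation_uptake``: carbon uptake used in validation runs;
    ``growth_tol``: below this μ counts as "no growth".
    """

    mu_max: float = 0.20
    window: float = 0.9
    ngam: float = 1.0
    validation_uptake: float = 10.0
    growth_tol: float = 1e-6
    gam: float = DEFAULT_GAM

    def __post_init__(self) -> None:
        if min(self.mu_max, self.window, self.ngam, self.validation_uptake) <= 0:
            raise ValueError("all protocol parameters must be positive")


@dataclass
class LPProblem:
    """A bare LP over the flux polytope ``{v : S v = 0, lb <= v <= ub}``."""

    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    sense: str = "max"

    def __post_init__(self) -> None:
        n = self.S.shape[1]
        if not (len(self.lb) == len(self.ub) == len(self.c) == n):
            raise ValueError("inconsistent LP dimensions")


@dataclass
class FluxSolution:
    """Result of one FBA solve."""

    status: str  # optimal | infeasible | unbounded
    objective: Optional[float]
    fluxes: Optional[pd.Series]
    objective_reaction: Optional[str] = None
    max_violation: float = 0.0

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @property
    def mu(self) -> Optional[float]:
        """Growth rate when the objective is a biomass reaction."""
        return self.objective if self.optimal else None


def build_lp(
    model: MetabolicModel, objective_reaction: Optional[str] = None, sense: str = "max"
) -> tuple[LPProblem, list[str]]:
    S, _, rxn_ids = stoichiometric_matrix(model)
    obj = objective_reaction or model.objective_reaction_id
    if obj is None or obj not in model.reactions:
        raise KeyError(f"objective reaction {obj!r} not in model")
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(obj)] = 1.0
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    return LPProblem(S=S, lb=lb, ub=ub, c=c, sense=sense), rxn_ids


def solve_lp(problem: LPProblem) -> tuple[str, Optional[float], Optional[np.ndarray]]:
    """Solve an :class:`LPProblem` with HiGHS; returns (status, objective, v)."""
    sign = -1.0 if problem.sense == "max" else 1.0
    res = linprog(
        sign * problem.c,
        A_eq=problem.S if problem.S.size else None,
        b_eq=np.zeros(problem.S.shape[0]) if problem.S.size else None,
        bounds=list(zip(problem.lb, problem.ub)),
        method="highs",
    )
    if res.status == 0:
        return "optimal", sign * res.fun, res.x
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 3:
        return "unbounded", None, None
    return "failed", None, None


def fba(
    model: MetabolicModel,
    objective_reaction: Optional[str] = None,
    sense: str = "max",
    check_tol: float = 1e-6,
) -> FluxSolution:
    """Flux balance analysis: optimize one reaction's flux at steady state.

    Infeasibility/unboundedness is reported in ``status``, not raised.  An
    optimal solution is verified against ``‖S·v‖∞ <= check_tol`` and bounds.
    """
    problem, rxn_ids = build_lp(model, objective_reaction, sense)
    status, objective, v = solve_lp(problem)
    if status != "optimal":
        return FluxSolution(status=status, objective=None, fluxes=None,
                            objective_reaction=objective_reaction)
    residual = float(np.max(np.abs(problem.S @ v))) if problem.S.size else 0.0
    bound_violation = float(
        max(np.max(problem.lb - v, initial=0.0), np.max(v - problem.ub, initial=0.0))
    )
    if residual > check_tol or bound_violation > 1e-6:
        status = "failed"
    return FluxSolution(
        status=status,
        objective=float(objective),
        fluxes=pd.Series(v, index=rxn_ids),
        objective_reaction=objective_reaction or model.objective_reaction_id,
        max_violation=max(residual, bound_violation),
    )


def fva(
    model: MetabolicModel, reactions: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Flux variability analysis: min and max flux per reaction."""
    reactions = list(reactions or model.reactions)
    rows = []
    for rid in reactions:
        lo = fba(model, rid, sense="min")
        hi = fba(model, rid, sense="max")
        rows.append(
            {
                "reaction": rid,
                "minimum": lo.objective if lo.optimal else np.nan,
                "maximum": hi.objective if hi.optimal else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("reaction")


# ---------------------------------------------------------------------------
# Medium handling
# ---------------------------------------------------------------------------

def set_minimal_medium(model: MetabolicModel, warn: bool = True) -> MetabolicModel:
    """Configure the minimal defined medium in place and return the model.

    Exchanges for CO2, H2O, H+, O2, Fe2+, phosphate, potassium, sodium,
    sulphate and NH4 get lower bound -1000 (unlimited uptake); every other
    exchange is closed for uptake (lower bound 0).  Upper bounds are 1000 so
    secretion stays open.  Listed exchanges missing from the model are
    skipped with a warning.
    """
    import warnings

    for rxn in model.exchanges():
        rxn.lower_bound = 0.0
    for ex_id in MINIMAL_MEDIUM_OPEN:
        if ex_id in model.reactions:
            model.reactions[ex_id].lower_bound = -1000.0
            model.reactions[ex_id].upper_bound = 1000.0
        elif warn:
            warnings.warn(f"minimal medium: exchange {ex_id} missing, skipped")
    return model


def carbon_atoms_of_exchange(model: MetabolicModel, exchange_id: str) -> int:
    """Number of carbon atoms of the species moved by an exchange reaction."""
    rxn = model.reactions[exchange_id]
    (mid,) = rxn.stoichiometry
    met = model.metabolites[mid]
    if met.formula is None:
        raise ValueError(f"exchange {exchange_id}: species has no formula")
    return met.elements.get("C", 0)


def uptake_for_equal_cmol(
    source_atoms: int, reference_atoms: int, reference_uptake: float
) -> float:
    """Uptake rate delivering the same C-mol as a reference source.

    ``uptake = reference_uptake × C_ref / C_source`` (signs preserved).
    """
    if source_atoms <= 0:
        raise ValueError("carbon source must contain carbon")
    return reference_uptake * reference_atoms / source_atoms


def fix_exchange(model: MetabolicModel, exchange_id: str, uptake: float) -> None:
    """Pin an exchange to an exact uptake: lb = ub = -|uptake|."""
    rxn = model.reactions[exchange_id]
    rxn.lower_bound = -abs(uptake)
    rxn.upper_bound = -abs(uptake)


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def _install_condition_biomass(
    model: MetabolicModel,
    cn_gg: float,
    biomass_mode: str,
    params: ProtocolParams,
) -> None:
    mode = "starvation" if biomass_mode == "dynamic" else "replete"
    composition = compose_biomass(cn_gg, mode=mode)
    install_biomass(model, composition, gam=params.gam)


@dataclass
class LipidProtocolResult:
    """Outcome of the fixed-biomass lipid-maximization protocol."""

    mu_star: float
    mu_bounds: tuple[float, float]
    lipid_flux: float
    cn_gg: float
    status: str
    no_growth: bool = False
    solution: Optional[FluxSolution] = None


def lipid_production_protocol(
    model: MetabolicModel,
    cn_gg: float,
    carbon_exchange: str,
    carbon_uptake: float,
    nitrogen_exchange: str,
    nitrogen_uptake: float,
    lipid_exchange: str = "EX_lipid_e",
    biomass_mode: str = "dynamic",
    params: Optional[ProtocolParams] = None,
) -> LipidProtocolResult:
    """Growth-then-lipid two-stage optimization at one (C, N) condition.

    The minimal medium is applied, carbon and nitrogen exchanges are pinned
    to the tested uptakes (both bounds), and a condition-specific (or static)
    biomass is installed.  Stage 1 maximizes growth (μ*).  Stage 2 pins the
    biomass flux to [0.9·0.2, 0.2] when μ* exceeds 0.2 h⁻¹, else to
    [0.9·μ*, μ*], and maximizes the lipid-body exchange.
    """
    params = params or ProtocolParams()
    work = model.copy()
    set_minimal_medium(work, warn=False)
    fix_exchange(work, carbon_exchange, carbon_uptake)
    fix_exchange(work, nitrogen_exchange, nitrogen_uptake)
    _install_condition_biomass(work, cn_gg, biomass_mode, params)

    growth = fba(work, "BIOMASS", sense="max")
    if not growth.optimal or growth.objective <= params.growth_tol:
        return LipidProtocolResult(
            mu_star=0.0,
            mu_bounds=(0.0, 0.0),
            lipid_flux=0.0,
            cn_gg=cn_gg,
            status=growth.status,
            no_growth=True,
        )
    mu_star = growth.objective
    if mu_star > params.mu_max:
        bounds = (params.window * params.mu_max, params.mu_max)
    else:
        bounds = (params.window * mu_star, mu_star)
    biomass = work.reactions["BIOMASS"]
    biomass.lower_bound, biomass.upper_bound = bounds
    lipid = fba(work, lipid_exchange, sense="max")
    flux = lipid.objective if lipid.optimal else 0.0
    return LipidProtocolResult(
        mu_star=mu_star,
        mu_bounds=bounds,
        lipid_flux=max(flux, 0.0),
        cn_gg=cn_gg,
        status=lipid.status,
        solution=lipid,
    )


def constrain_for_condition(
    model: MetabolicModel,
    cn_gg: float,
    carbon_exchange: str,
    carbon_uptake: float,
    nitrogen_exchange: str,
    nitrogen_uptake: float,
    biomass_mode: str = "dynamic",
    params: Optional[ProtocolParams] = None,
) -> tuple[MetabolicModel, LipidProtocolResult]:
    """Copy of ``model`` with the full lipid-protocol constraints applied.

    The returned model has minimal medium + pinned uptakes + the pinned
    biomass window installed; it is the polytope that flux sampling explores.
    """
    params = params or ProtocolParams()
    result = lipid_production_protocol(
        model,
        cn_gg,
        carbon_exchange,
        carbon_uptake,
        nitrogen_exchange,
        nitrogen_uptake,
        biomass_mode=biomass_mode,
        params=params,
    )
    work = model.copy()
    set_minimal_medium(work, warn=False)
    fix_exchange(work, carbon_exchange, carbon_uptake)
    fix_exchange(work, nitrogen_exchange, nitrogen_uptake)
    _install_condition_biomass(work, cn_gg, biomass_mode, params)
    if not result.no_growth:
        biomass = work.reactions["BIOMASS"]
        biomass.lower_bound, biomass.upper_bound = result.mu_bounds
    return work, result


def growth_screen(
    model: MetabolicModel,
    sources: dict[str, str],
    carbon_uptakes: Sequence[float],
    nitrogen_uptakes: Sequence[float],
    nitrogen_exchange: str = "EX_nh4_e",
    nitrogen_atoms: int = 1,
    biomass_mode: str = "dynamic",
    params: Optional[ProtocolParams] = None,
) -> pd.DataFrame:
    """Growth-rate table over a (source × C-uptake × N-uptake) grid.

    ``sources`` maps source name to its exchange reaction id.  In each cell
    both bounds of the carbon and nitrogen exchanges are pinned to the tested
    uptakes, the condition-specific biomass is rebuilt from the uptake-derived
    C/N ratio (g/g), and biomass is maximized.  Infeasible cells are recorded
    as μ = 0 with a flag.
    """
    params = params or ProtocolParams()
    rows = []
    for name, ex_id in sources.items():
        atoms = carbon_atoms_of_exchange(model, ex_id)
        for uc in carbon_uptakes:
            for un in nitrogen_uptakes:
                work = model.copy()
                set_minimal_medium(work, warn=False)
                fix_exchange(work, ex_id, uc)
                fix_exchange(work, nitrogen_exchange, un)
                cn = cn_from_uptakes(atoms, uc, nitrogen_atoms, un)
                _install_condition_biomass(work, cn.mass, biomass_mode, params)
                sol = fba(work, "BIOMASS", sense="max")
                mu = sol.objective if sol.optimal else 0.0
                rows.append(
                    {
                        "source": name,
                        "carbon_uptake": abs(uc),
                        "nitrogen_uptake": abs(un),
                        "cn_gg": cn.mass,
                        "mu": max(mu, 0.0),
                        "status": sol.status,
                        "infeasible": not sol.optimal,
                    }
                )
    return pd.DataFrame(rows)


def knockout_growth(
    model: MetabolicModel,
    genes: Iterable[str],
    cn_gg: float,
    carbon_exchange: str,
    carbon_uptake: float,
    nitrogen_exchange: str,
    nitrogen_uptake: float,
    biomass_mode: str = "dynamic",
    params: Optional[ProtocolParams] = None,
) -> LipidProtocolResult:
    """Gene-deletion variant of the lipid protocol.

    Reactions whose GPR evaluates false under the deletion get bounds [0, 0];
    the growth + lipid protocol then runs on the reduced network.
    """
    reduced = knockout_bounds(model, genes)
    return lipid_production_protocol(
        reduced,
        cn_gg,
        carbon_exchange,
        carbon_uptake,
        nitrogen_exchange,
        nitrogen_uptake,
        biomass_mode=biomass_mode,
        params=params,
    )
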