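"""Uniform sampling of the steady-state flux polytope and Z-score shifts.

The sampler is an artificial-centering hit-and-run (ACHR) chain over the
polytope ``{v : S v = 0, lb <= v <= ub}``.  Warmup points are the optimal
vertices of flux variability analysis (FVA); chain directions are differences
between stored points and the running center, which automatically lie in the
null space of S, so every iterate satisfies steady state exactly.  A
step-count budget replaces wall-clock limits so runs are reproducible.

Condition comparison follows the sampled-flux Z-score convention

    Z = (mean_cond - mean_ref) / sqrt(sd_ref**2 + sd_cond**2)

with Z > 0 meaning the reaction's flux increased relative to the reference
condition (the reference C/N ratio is 6 g/g in the scenario runners).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fba import fba, fva
from .model import MetabolicModel, stoichiometric_matrix

_EPS_DIR = 1e-10
_EPS_BOUND = 1e-9


class EmptyPolytopeError(RuntimeError):
    """The constrained flux polytope admits no feasible point."""


@dataclass
class SamplingResult:
    """Matrix of sampled flux vectors (n points × reactions)."""

    points: pd.DataFrame
    seed: Optional[int]
    n: int
    steps_per_point: int
    max_steady_state_violation: float
    max_bound_violation: float
    condition: str = ""

    def mean(self) -> pd.Series:
        return self.points.mean(axis=0)

    def sd(self) -> pd.Series:
        return self.points.std(axis=0, ddof=1)

    def se(self) -> pd.Series:
        return self.sd() / np.sqrt(len(self.points))


def _hit_and_run(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    warmup: np.ndarray,
    n: int,
    seed: Optional[int],
    steps_per_point: int,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n_dim = len(lb)
    stored = warmup.copy()
    center = stored.mean(axis=0)
    v = stored[rng.integers(len(stored))].copy()
    out = np.empty((n, n_dim))
    produced = 0
    step = 0
    while produced < n:
        ref = stored[rng.integers(len(stored))]
        d = ref - center
        norm = np.linalg.norm(d)
        if norm < _EPS_DIR:
            step += 1
            continue
        d /= norm
        # allowed step interval keeping lb <= v + t d <= ub
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (lb - v) / d
            t_hi = (ub - v) / d
        active = np.abs(d) > _EPS_DIR
        lows = np.where(d > 0, t_lo, t_hi)[active]
        highs = np.where(d > 0, t_hi, t_lo)[active]
        t_min = np.max(lows, initial=-np.inf)
        t_max = np.min(highs, initial=np.inf)
        if not np.isfinite(t_min) or not np.isfinite(t_max) or t_max - t_min < _EPS_DIR:
            step += 1
            continue
        t = rng.uniform(t_min, t_max)
        v = np.clip(v + t * d, lb, ub)
        step += 1
        center = center + (v - center) / (len(stored) + produced + 1)
        if step % steps_per_point == 0:
            out[produced] = v
            produced += 1
    return out


def sample_polytope(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    warmup: np.ndarray,
    n: int = 5000,
    seed: Optional[int] = None,
    steps_per_point: int = 25,
) -> np.ndarray:
    """ACHR samples of ``{v : S v = 0, lb <= v <= ub}`` from given warmup points."""
    if warmup.ndim != 2 or len(warmup) < 2:
        raise ValueError("need at least two warmup points")
    return _hit_and_run(S, np.asarray(lb, float), np.asarray(ub, float),
                        np.asarray(warmup, float), n, seed, steps_per_point)


def sample_fluxes(
    model: MetabolicModel,
    n: int = 5000,
    seed: Optional[int] = None,
    steps_per_point: int = 25,
    condition: str = "",
) -> SamplingResult:
    """Sample the model's steady-state flux polytope.

    Feasibility is verified by FBA first; an empty polytope raises
    :class:`EmptyPolytopeError` carrying the LP status.  Warmup points are the
    FVA optima of every reaction.  Every stored point is checked against
    ``‖S·v‖∞ <= 1e-6`` and the bounds.
    """
    S, _, rxn_ids = stoichiometric_matrix(model)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])

    probe = fba(model, rxn_ids[0], sense="max")
    if not probe.optimal:
        raise EmptyPolytopeError(f"flux polytope is empty (FBA status: {probe.status})")

    warmup = []
    for rid in rxn_ids:
        for sense in ("min", "max"):
            sol = fba(model, rid, sense=sense)
            if sol.optimal:
                warmup.append(sol.fluxes.to_numpy())
    warmup = np.array(warmup)
    points = _hit_and_run(S, lb, ub, warmup, n, seed, steps_per_point)

    sv = np.abs(S @ points.T).max() if S.size else 0.0
    bv = float(
        max(np.max(lb[None, :] - points, initial=0.0),
            np.max(points - ub[None, :], initial=0.0))
    )
    if sv > 1e-6 or bv > 1e-6:
        raise RuntimeError(
            f"sampled points violate constraints (Sv {sv:.2e}, bounds {bv:.2e})"
        )
    return SamplingResult(
        points=pd.DataFrame(points, columns=rxn_ids),
        seed=seed,
        n=n,
        steps_per_point=steps_per_point,
        max_steady_state_violation=float(sv),
        max_bound_violation=bv,
        condition=condition,
    )


def spawn_seed(base: Optional[int], *key: int) -> Optional[int]:
    """Deterministic child seed for a scenario cell (kept below 2**31)."""
    if base is None:
        return None
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ConditionResult:
    """One sampled condition of a C/N series."""

    carbon_level: float
    cn_gg: float
    sampling: Optional[SamplingResult]
    zscores: Optional[pd.DataFrame]
    feasible: bool
    lipid_flux: float = 0.0


def condition_series(
    model: MetabolicModel,
    cn_list: Sequence[float],
    carbon_levels: Sequence[float],
    carbon_exchange: str = "EX_glyc_e",
    carbon_atoms: int = 3,
    nitrogen_exchange: str = "EX_urea_e",
    nitrogen_atoms: int = 2,
    reference_cn: float = 6.0,
    n: int = 5000,
    seed: Optional[int] = None,
    steps_per_point: int = 25,
    biomass_mode: str = "dynamic",
) -> list[ConditionResult]:
    """Sample the lipid-protocol polytope along a C/N series.

    ``carbon_levels`` are carbon-source uptake rates (mmol substrate per gDCW
    per h); for each level and each C/N (g/g) the nitrogen uptake is derived
    from the target ratio, the condition-specific biomass and the
    pinned-growth lipid protocol are applied, the polytope is sampled, and
    Z-scores are computed against the reference C/N (6 g/g) at the same
    carbon level.  Infeasible conditions are recorded and skipped.
    """
    from .elements import ATOMIC_MASS
    from .fba import constrain_for_condition

    results: list[ConditionResult] = []
    for ci, level in enumerate(carbon_levels):
        carbon_uptake = level
        c_mmol = level * carbon_atoms
        reference: Optional[SamplingResult] = None
        for ri, cn in enumerate([reference_cn] + [x for x in cn_list if x != reference_cn]):
            c_gram = c_mmol * ATOMIC_MASS["C"] / 1000.0
            n_gram = c_gram / cn
            n_mmol = n_gram / (ATOMIC_MASS["N"] / 1000.0)
            nitrogen_uptake = n_mmol / nitrogen_atoms
            work, proto = constrain_for_condition(
                model, cn, carbon_exchange, carbon_uptake,
                nitrogen_exchange, nitrogen_uptake, biomass_mode=biomass_mode,
            )
            if proto.no_growth:
                results.append(ConditionResult(level, cn, None, None, False))
                continue
            try:
                sampling = sample_fluxes(
                    work, n=n, seed=spawn_seed(seed, ci, ri),
                    steps_per_point=steps_per_point,
                    condition=f"C={level:g},CN={cn:g}",
                )
            except EmptyPolytopeError:
                results.append(ConditionResult(level, cn, None, None, False))
                continue
            if cn == reference_cn and reference is None:
                reference = sampling
                results.append(
                    ConditionResult(level, cn, sampling, None, True, proto.lipid_flux)
                )
                continue
            z = zscore_compare(reference, sampling) if reference is not None else None
            results.append(
                ConditionResult(level, cn, sampling, z, True, proto.lipid_flux)
            )
    return results


def zscore_compare(ref: SamplingResult, cond: SamplingResult) -> pd.DataFrame:
    """Per-reaction flux-shift Z-scores of a condition versus the reference.

    ``Z = (mean_cond - mean_ref) / sqrt(sd_ref² + sd_cond²)``; Z is exactly 0
    when both the means and the spreads agree (identical distributions), and
    carries sign +inf/-inf when both spreads are zero but the means differ.
    """
    if list(ref.points.columns) != list(cond.points.columns):
        raise ValueError("sampling results do not share a reaction index")
    mean_ref, sd_ref = ref.mean(), ref.sd()
    mean_cond, sd_cond = cond.mean(), cond.sd()
    denom = np.sqrt(sd_ref**2 + sd_cond**2)
    delta = mean_cond - mean_ref
    with np.errstate(divide="ignore", invalid="ignore"):
        z = delta / denom
    z = z.where(denom > 0, other=np.sign(delta) * np.where(delta.abs() > 0, np.inf, 0.0))
    return pd.DataFrame(
        {
            "mean_ref": mean_ref,
            "sd_ref": sd_ref,
            "mean_cond": mean_cond,
            "sd_cond": sd_cond,
            "z": z,
        }
    )
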