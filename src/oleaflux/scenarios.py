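"""Scenario runners reproducing the study's figure-generating experiments.

Each scenario is a pure function of (model, config, seed) returning tidy
DataFrames, so runs are deterministic and resumable.  Default grids are
coarsened desk-scale versions of the full study grids; the full ranges are
available through the config parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biomass import cn_from_uptakes, compose_biomass, REPLETE_COMPOSITION
from .fba import (
    ProtocolParams,
    carbon_atoms_of_exchange,
    growth_screen,
    lipid_production_protocol,
    uptake_for_equal_cmol,
)
from .model import MetabolicModel
from .sampling import condition_series, spawn_seed
from .toy import ToyModelManifest

#: Default coarsened grids: the full study swept carbon over [1.5:0.05:8.5]
#: and nitrogen over [0.1:0.01:0.8] (mmol uptake here); defaults keep the
#: ranges but use ~8 levels each.
DEFAULT_CARBON_GRID = tuple(np.round(np.linspace(1.5, 8.5, 8), 3))
DEFAULT_NITROGEN_GRID = tuple(np.round(np.linspace(0.1, 0.8, 8), 3))

#: Default C/N (g/g) series of the sampling analyses (full study list).
CN_SERIES = (6, 8, 10, 12, 24, 30, 36, 48, 60, 90, 120, 180, 240)


@dataclass
class RunManifest:
    """Provenance record of one scenario run."""

    scenario: str
    seed: Optional[int]
    config: dict
    model_fingerprint: str
    outputs: list[str] = field(default_factory=list)

    @staticmethod
    def fingerprint(model: MetabolicModel) -> str:
        from .io import model_to_dict

        payload = json.dumps(model_to_dict(model), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def scenario_cn_grid(
    model: MetabolicModel,
    carbon_uptakes: Sequence[float] = DEFAULT_CARBON_GRID,
    nitrogen_uptakes: Sequence[float] = DEFAULT_NITROGEN_GRID,
    carbon_exchange: str = "EX_glc_e",
    nitrogen_exchange: str = "EX_urea_e",
    nitrogen_atoms: int = 2,
    modes: Sequence[str] = ("dynamic", "static"),
    params: Optional[ProtocolParams] = None,
) -> pd.DataFrame:
    """Lipid production over a (carbon, nitrogen) uptake grid, per biomass mode.

    Emits, per cell: the uptake-derived C/N (g/g), the unconstrained maximal
    growth rate μ*, the realized growth in the lipid stage, the lipid-body
    exchange flux, and the biomass-coupled specific lipid productivity
    μ·w_TL (g lipid·gDCW⁻¹·h⁻¹) — the readout through which the
    condition-specific biomass expresses the C/N response.
    """
    params = params or ProtocolParams()
    atoms = carbon_atoms_of_exchange(model, carbon_exchange)
    rows = []
    for mode in modes:
        for uc in carbon_uptakes:
            for un in nitrogen_uptakes:
                cn = cn_from_uptakes(atoms, uc, nitrogen_atoms, un)
                res = lipid_production_protocol(
                    model, cn.mass, carbon_exchange, uc, nitrogen_exchange, un,
                    biomass_mode=mode, params=params,
                )
                if mode == "dynamic":
                    w_tl = compose_biomass(cn.mass, "starvation").w_lipid
                else:
                    w_tl = REPLETE_COMPOSITION["w_lipid"]
                mu_used = 0.0
                if res.solution is not None and res.solution.fluxes is not None:
                    mu_used = float(res.solution.fluxes.get("BIOMASS", 0.0))
                rows.append(
                    {
                        "mode": mode,
                        "carbon_uptake": uc,
                        "nitrogen_uptake": un,
                        "cn_gg": cn.mass,
                        "mu_star": res.mu_star,
                        "mu_used": mu_used,
                        "lipid_exchange": res.lipid_flux,
                        "biomass_lipid_rate": mu_used * w_tl,
                        "total_lipid_rate": res.lipid_flux + mu_used * w_tl,
                        "no_growth": res.no_growth,
                    }
                )
    return pd.DataFrame(rows)


def scenario_carbon_sources(
    model: MetabolicModel,
    manifest: ToyModelManifest,
    reference_uptake: float = 10.0,
    nitrogen_uptakes: Sequence[float] = (0.5, 2.0, 5.0),
    nitrogen_source: str = "nh4",
    sources: Optional[Sequence[str]] = None,
    params: Optional[ProtocolParams] = None,
) -> pd.DataFrame:
    """Growth and lipid production per carbon source at equal C-mol supply.

    Uptake rates are adjusted per source so every column delivers the same
    C-mol as the reference source (glucose at ``reference_uptake``).
    """
    params = params or ProtocolParams()
    sources = list(sources or manifest.carbon_sources)
    n_info = manifest.nitrogen_sources[nitrogen_source]
    ref_atoms = manifest.carbon_sources["glucose"]["carbon_atoms"]
    rows = []
    for name in sources:
        info = manifest.carbon_sources[name]
        uptake = uptake_for_equal_cmol(
            info["carbon_atoms"], ref_atoms, reference_uptake
        )
        for un in nitrogen_uptakes:
            cn = cn_from_uptakes(
                info["carbon_atoms"], uptake, n_info["nitrogen_atoms"], un
            )
            res = lipid_production_protocol(
                model, cn.mass, info["exchange"], uptake,
                n_info["exchange"], un, params=params,
            )
            rows.append(
                {
                    "source": name,
                    "carbon_uptake": uptake,
                    "nitrogen_uptake": un,
                    "cn_gg": cn.mass,
                    "mu_star": res.mu_star,
                    "lipid_exchange": res.lipid_flux,
                    "no_growth": res.no_growth,
                }
            )
    return pd.DataFrame(rows)


def scenario_acetylcoa(
    model: MetabolicModel,
    manifest: ToyModelManifest,
    cn_list: Sequence[float] = (6, 8, 10, 12, 24, 36, 48, 60),
    urea_uptake: float = 2.5,
    carbon_source: str = "glycerol",
    n: int = 500,
    seed: Optional[int] = None,
    steps_per_point: int = 25,
    knockout_genes: Sequence[str] = (),
) -> pd.DataFrame:
    """Sampled flux trends of the acetyl-CoA supply route versus C/N.

    Nitrogen (urea) uptake is pinned; carbon is increased to realize each
    C/N ratio (g/g).  For the four tracked reactions (citrate export, ACL,
    acyl-CoA pool, lipid-body exchange) the sampled mean, sd and standard
    error are reported per condition.  The default urea uptake (2.5) is a
    desk-scale version of the study setting, keeping the implied carbon
    uptake within the model's ±1000 flux caps across the full C/N range.
    """
    from .elements import ATOMIC_MASS
    from .fba import constrain_for_condition
    from .model import knockout_bounds
    from .sampling import sample_fluxes, EmptyPolytopeError

    work_model = knockout_bounds(model, knockout_genes) if knockout_genes else model
    info = manifest.carbon_sources[carbon_source]
    tracked = manifest.tracked_reactions
    n_mmol = urea_uptake * manifest.nitrogen_sources["urea"]["nitrogen_atoms"]
    n_gram = n_mmol * ATOMIC_MASS["N"] / 1000.0
    rows = []
    for i, cn in enumerate(cn_list):
        c_gram = cn * n_gram
        c_mmol = c_gram / (ATOMIC_MASS["C"] / 1000.0)
        carbon_uptake = c_mmol / info["carbon_atoms"]
        constrained, proto = constrain_for_condition(
            work_model, cn, info["exchange"], carbon_uptake,
            "EX_urea_e", urea_uptake,
        )
        base = {"cn_gg": cn, "carbon_uptake": carbon_uptake, "feasible": True,
                "lipid_flux_max": proto.lipid_flux}
        if proto.no_growth:
            for label, rid in tracked.items():
                rows.append({**base, "feasible": False, "reaction": label,
                             "mean": 0.0, "sd": 0.0, "se": 0.0})
            continue
        try:
            sampling = sample_fluxes(
                constrained, n=n, seed=spawn_seed(seed, i),
                steps_per_point=steps_per_point,
            )
        except EmptyPolytopeError:
            for label, rid in tracked.items():
                rows.append({**base, "feasible": False, "reaction": label,
                             "mean": 0.0, "sd": 0.0, "se": 0.0})
            continue
        mean, sd, se = sampling.mean(), sampling.sd(), sampling.se()
        for label, rid in tracked.items():
            rows.append({**base, "reaction": label, "mean": mean[rid],
                         "sd": sd[rid], "se": se[rid]})
    return pd.DataFrame(rows)


def scenario_zscore_series(
    model: MetabolicModel,
    manifest: ToyModelManifest,
    cn_list: Sequence[float] = (6, 12, 60, 120),
    carbon_levels: Sequence[float] = (16.0, 24.0, 32.0),
    carbon_source: str = "glycerol",
    n: int = 500,
    seed: Optional[int] = None,
    steps_per_point: int = 25,
):
    """C/N flux-shift series: sample each condition and Z-score it against
    the C/N = 6 g/g reference at the same carbon level (glycerol carbon)."""
    info = manifest.carbon_sources[carbon_source]
    return condition_series(
        model,
        cn_list=cn_list,
        carbon_levels=carbon_levels,
        carbon_exchange=info["exchange"],
        carbon_atoms=info["carbon_atoms"],
        nitrogen_exchange="EX_urea_e",
        nitrogen_atoms=2,
        n=n,
        seed=seed,
        steps_per_point=steps_per_point,
    )
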