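"""Run orchestration: drivers -> annual forcing -> yearly pool integration.

The year loop follows a fixed order: land-cover transitions first (pool
mixing), then the annual inputs/outputs, then the daily pool dynamics.
State is kept internally in mgP (kg soil)^-1 with a leading batch axis so
that an entire ensemble advances through the daily stepping in single
vectorised calls; outputs are converted to kgP ha^-1 at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import drivers as drv
from .core import (
    FLUXES,
    POOLS,
    AnnualForcing,
    ClimateRecord,
    PoolState,
    UnitContext,
    integrate_year,
)
from .lucc import LANDUSE_CATEGORIES, apply_lucc, natural_pool_state
from .parameterization import (
    FluxParameters,
    NaturalPools,
    ParamConfig,
    SoilProperties,
    build_flux_parameters,
    steady_state_fractions,
)
from .synthetic import World

__all__ = ["RunConfig", "ForcingBase", "SimulationResult", "build_forcing_base",
           "assemble_forcing", "build_parameters", "run_simulation"]

LU_INDEX = {"crop": 0, "grass": 1}


@dataclass
class RunConfig:
    """Settings of one simulation run."""

    mineralization_preset: str = "v1.1"
    p_c_inf: float = 0.1
    k_weathering: float = 2.7e-7
    n_days: int = 365
    manure_mode: str = "mean"      # mean | estimate1 | estimate2
    npp_mode: str = "mean"         # mean | kastner | sun_scaled
    store_annual: bool = True

    def param_config(self) -> ParamConfig:
        return ParamConfig(
            p_c_inf=self.p_c_inf,
            mineralization_preset=self.mineralization_preset,
            k_weathering=self.k_weathering,
        )

    def validate(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.manure_mode not in ("mean", "estimate1", "estimate2"):
            raise ValueError(f"unknown manure_mode {self.manure_mode!r}")
        if self.npp_mode not in ("mean", "kastner", "sun_scaled"):
            raise ValueError(f"unknown npp_mode {self.npp_mode!r}")
        self.param_config().mineralization_rates()


@dataclass
class ForcingBase:
    """Driver quantities precomputed once per world (member-independent).

    The uncertainty machinery perturbs these with cheap array operations;
    everything is in kgP ha^-1 yr^-1 except the erosion fraction (yr^-1).
    """

    manure_e1: np.ndarray          # (years, 2, cells)
    manure_e2: np.ndarray
    chem_crop: np.ndarray          # (years, cells)
    chem_grass: np.ndarray
    grass_npp_e1: np.ndarray       # (years, cells) kgC ha-1 yr-1
    grass_npp_e2: np.ndarray
    crop_uptake: np.ndarray        # (years, cells)
    crop_residues: np.ndarray
    depo_ilab: np.ndarray          # (years, cells)
    depo_iprim: np.ndarray
    sludge_crop: np.ndarray        # (years, cells)
    erosion_frac: np.ndarray       # (2, cells) yr^-1


def build_forcing_base(world: World) -> ForcingBase:
    """Evaluate every driver recipe on the world's mean inputs."""
    fr = world.landuse.fractions
    frac_crop = fr[:, LANDUSE_CATEGORIES.index("crop"), :]
    frac_grass = fr[:, LANDUSE_CATEGORIES.index("grass"), :]

    manure_e1 = drv.manure_forcing(world.n_manure, world.country_id, mode="estimate1")
    manure_e2 = drv.manure_forcing(
        world.n_manure, world.country_id, mode="estimate2",
        country_table=world.country_table,
        landuse_frac=fr[:, :2, :], land_area=world.land_area, years=world.years,
    )
    chem_crop, chem_grass = drv.fertilizer_forcing(
        world.n_chem_grass, world.p_chem_total, frac_crop, frac_grass
    )

    crop_uptake = np.zeros((world.n_years, world.n_cells))
    crop_residues = np.zeros_like(crop_uptake)
    yields, areas = {}, {}
    for crop in world.crops:
        y, a = drv.crop_yield_area_series(
            world.crop_yield_map_2000[crop.name],
            world.crop_area_map_2000[crop.name],
            world.country_crop_yield[crop.name],
            world.country_crop_area[crop.name],
            world.population,
            world.country_id,
            world.years,
        )
        yields[crop.name] = y
        areas[crop.name] = a
    crop_uptake, crop_residues = drv.cropland_plant_forcing(yields, areas, world.crops)

    depo_ilab, depo_iprim = drv.deposition_forcing(
        world.deposition, world.years,
        anth_emissions_a=world.anth_emissions_a,
        anth_emissions_b=world.anth_emissions_b,
    )

    sludge_country = drv.sludge_forcing(
        world.population, world.sludge_excretion, world.sludge_treat_fractions,
        world.crop_area_country_series(), world.years,
    )
    sludge_crop = np.zeros((world.n_years, world.n_cells))
    for cid, flux in sludge_country.items():
        sludge_crop[:, world.country_id == cid] = flux[:, None]

    erosion_frac = drv.erosion_fraction(world.erosion_loss, world.soil)

    return ForcingBase(
        manure_e1=manure_e1,
        manure_e2=manure_e2,
        chem_crop=chem_crop,
        chem_grass=chem_grass,
        grass_npp_e1=world.npp_tot,
        grass_npp_e2=world.npp_tot * drv.NPP_SCALE_FIELD_TO_MODEL,
        crop_uptake=crop_uptake,
        crop_residues=crop_residues,
        depo_ilab=depo_ilab,
        depo_iprim=depo_iprim,
        sludge_crop=sludge_crop,
        erosion_frac=erosion_frac,
    )


def assemble_forcing(
    world: World,
    base: ForcingBase,
    config: RunConfig,
    sample: dict | None = None,
) -> dict:
    """Combine the precomputed driver base (optionally perturbed by a
    Monte-Carlo ``sample``) into per-field forcing arrays (years, 2, cells).

    Recognised sample keys: ``manure`` (years, 2, cells, replaces the
    manure field), ``chem_grass_factor``, ``crop_uptake_factor``,
    ``sludge_factor``, ``depo_factor`` (years, cells), ``grass_npp``
    (years, cells, replaces NPP), ``grass_p_pct_above`` (scalar),
    ``residue_fracs`` ((2,) composition), ``erosion_factor`` (cells,).
    """
    sample = sample or {}
    Y, C = world.n_years, world.n_cells
    comp = world.composition

    if "manure" in sample:
        manure = np.maximum(sample["manure"], 0.0)
    elif config.manure_mode == "estimate1":
        manure = base.manure_e1
    elif config.manure_mode == "estimate2":
        manure = base.manure_e2
    else:
        manure = 0.5 * (base.manure_e1 + base.manure_e2)

    chem = np.stack([base.chem_crop,
                     base.chem_grass * sample.get("chem_grass_factor", 1.0)], axis=1)
    chem = np.maximum(chem, 0.0)

    npp = sample.get(
        "grass_npp",
        base.grass_npp_e1 if config.npp_mode == "kastner"
        else base.grass_npp_e2 if config.npp_mode == "sun_scaled"
        else 0.5 * (base.grass_npp_e1 + base.grass_npp_e2),
    )
    grass_uptake, grass_residues = drv.grassland_plant_forcing(
        np.maximum(npp, 0.0), world.gi, world.grass_params,
        npp_mode="kastner",  # npp selection handled above
        p_pct_above=sample.get("grass_p_pct_above"),
    )

    crop_factor = sample.get("crop_uptake_factor", 1.0)
    uptake = np.stack([np.maximum(base.crop_uptake * crop_factor, 0.0), grass_uptake], axis=1)
    residues_total = np.stack(
        [np.maximum(base.crop_residues * crop_factor, 0.0), grass_residues], axis=1
    )

    if "residue_fracs" in sample:
        f_ilab, f_olab = np.clip(np.asarray(sample["residue_fracs"], dtype=float), 0.0, None)
        s = f_ilab + f_olab
        if s > 1.0:  # keep the split a valid partition
            f_ilab, f_olab = f_ilab / s, f_olab / s
        resi_fracs = (float(f_ilab), float(f_olab), 1.0 - float(f_ilab) - float(f_olab))
    else:
        resi_fracs = comp.residues

    manure_split = drv.split_composition(manure, comp.manure)
    resi_split = drv.split_composition(residues_total, resi_fracs)

    depo_factor = sample.get("depo_factor", 1.0)
    depo_ilab = np.maximum(base.depo_ilab * depo_factor, 0.0)[:, None, :]
    depo_iprim = np.maximum(base.depo_iprim * depo_factor, 0.0)[:, None, :]
    depo_ilab = np.broadcast_to(depo_ilab, (Y, 2, C)).copy()
    depo_iprim = np.broadcast_to(depo_iprim, (Y, 2, C)).copy()

    sludge = np.zeros((Y, 2, C))
    sludge[:, 0, :] = np.maximum(base.sludge_crop * sample.get("sludge_factor", 1.0), 0.0)
    sludge_split = drv.split_composition(sludge, comp.sludge)

    erosion = np.clip(base.erosion_frac * sample.get("erosion_factor", 1.0), 0.0, 1.0)

    return {
        "chem_to_ilab": chem,
        "manure_to_ilab": manure_split[0],
        "manure_to_olab": manure_split[1],
        "manure_to_osta": manure_split[2],
        "residues_to_ilab": resi_split[0],
        "residues_to_olab": resi_split[1],
        "residues_to_osta": resi_split[2],
        "sludge_to_ilab": sludge_split[0],
        "sludge_to_olab": sludge_split[1],
        "sludge_to_osta": sludge_split[2],
        "depo_to_ilab": depo_ilab,
        "depo_to_iprim": depo_iprim,
        "uptake_from_ilab": uptake,
        "erosion_frac_loss": np.broadcast_to(erosion, (2, C)).copy(),
    }


def build_parameters(
    world: World,
    config: RunConfig,
    natural: NaturalPools | None = None,
    soil: SoilProperties | None = None,
    climate: dict | None = None,
) -> tuple[FluxParameters, np.ndarray]:
    """Flux parameters (and the long-term mean water content) for a world,
    optionally with perturbed natural pools / soil / climate."""
    natural = natural if natural is not None else world.natural
    soil = soil if soil is not None else world.soil
    climate = climate if climate is not None else world.climate
    w_abs_mean = np.mean(climate["w_abs"], axis=0)
    t_air_mean = np.mean(climate["t_air"], axis=0)
    frac = steady_state_fractions(natural, w_abs_mean, config.p_c_inf)
    params = build_flux_parameters(soil, frac, t_air_mean, w_abs_mean,
                                   config.param_config())
    return params, w_abs_mean


@dataclass
class SimulationResult:
    years: np.ndarray
    #: end-of-run pools, kgP ha^-1: dict pool -> (..., 2, cells)
    final_pools: dict
    #: annual pools if stored: dict pool -> (years, ..., 2, cells)
    annual_pools: dict | None
    #: annual gross internal-flux totals if stored, kgP ha^-1 yr^-1:
    #: dict flux name -> (years, ..., 2, cells)
    annual_fluxes: dict | None
    #: annual unsatisfied uptake, kgP ha^-1 yr^-1 (years, ..., 2, cells)
    upns: np.ndarray
    #: per-year mass-balance residual, kgP ha^-1 (years, ..., 2, cells)
    balance_residual: np.ndarray

    def total(self, which="final") -> np.ndarray:
        src = self.final_pools if which == "final" else self.annual_pools
        return sum(src[p] for p in POOLS)


def run_simulation(
    world: World,
    config: RunConfig | None = None,
    sample: dict | None = None,
    batch: dict | None = None,
) -> SimulationResult:
    """Integrate the world over its full period.

    ``sample`` perturbs a single run (see :func:`assemble_forcing` and the
    BIOG/CLIM/SPRO keys ``natural``, ``soil``, ``climate``).  ``batch``
    may carry pre-stacked member-axis arrays built by the uncertainty
    module: keys ``forcing`` (field -> (years, members, 2, cells)),
    ``params`` (FluxParameters with (members, cells) fields), ``natural``
    ((members, cells) NaturalPools), ``climate``, ``w_abs_mean``.
    """
    config = config or RunConfig()
    config.validate()
    sample = sample or {}

    if batch is None:
        base = build_forcing_base(world)
        forcing = assemble_forcing(world, base, config, sample)
        params, w_abs_mean = build_parameters(
            world, config,
            natural=sample.get("natural"),
            soil=sample.get("soil"),
            climate=sample.get("climate"),
        )
        climate = sample.get("climate", world.climate)
        natural = sample.get("natural") or world.natural
        member_shape = ()
    else:
        forcing = batch["forcing"]
        params = batch["params"]
        w_abs_mean = batch["w_abs_mean"]
        climate = batch["climate"]
        natural = batch["natural"]
        member_shape = (np.shape(params.b)[0],)

    Y, C = world.n_years, world.n_cells
    unit_ctx = UnitContext(world.soil.bulk_density, world.soil.coarse_frag_frac,
                           world.soil.depth)

    # natural (boundary) pools for LUCC injection, internal units
    nat_state = natural_pool_state(natural, config.p_c_inf, w_abs_mean)

    # state shape (*member, 2, cells)
    state_shape = member_shape + (2, C)
    state = PoolState.zeros(state_shape)
    for p in POOLS:
        getattr(state, p)[...] = getattr(nat_state, p)[..., None, :]

    params_b = FluxParameters(**{
        f: np.asarray(getattr(params, f))[..., None, :]
        for f in ("b", "k_lab_to_sol", "k_sol_to_lab", "k_sol_to_sec",
                  "k_sec_to_sol", "k_sec_to_occ", "k_occ_to_sec",
                  "k_weathering", "k_min_stable", "k_min_labile",
                  "p_c_inf", "w_abs_mean")
    })

    annual = (
        {p: np.empty((Y,) + state_shape) for p in POOLS}
        if config.store_annual else None
    )
    annual_fluxes = (
        {name: np.empty((Y,) + state_shape) for name, _, _ in FLUXES}
        if config.store_annual else None
    )
    upns = np.empty((Y,) + state_shape)
    residual = np.empty((Y,) + state_shape)

    fr = world.landuse.fractions
    tr = world.landuse.transitions
    conv = unit_ctx.conc_to_areal

    for k in range(Y):
        if k > 0 and np.any(tr[k - 1]):
            pools_by_lu = {
                "crop": PoolState(**{p: getattr(state, p)[..., 0, :] for p in POOLS}),
                "grass": PoolState(**{p: getattr(state, p)[..., 1, :] for p in POOLS}),
            }
            mixed = apply_lucc(pools_by_lu, fr[k - 1], fr[k], tr[k - 1], nat_state)
            for i, lu in enumerate(("crop", "grass")):
                for p in POOLS:
                    getattr(state, p)[..., i, :] = getattr(mixed[lu], p)

        clim_y = ClimateRecord(
            t_soil=np.asarray(climate["t_soil"][k])[..., None, :],
            w_rel=np.asarray(climate["w_rel"][k])[..., None, :],
            w_abs=np.asarray(climate["w_abs"][k])[..., None, :],
            t_air=np.asarray(climate["t_air"][k])[..., None, :],
        )
        forcing_y = AnnualForcing(**{f: forcing[f][k] if f != "erosion_frac_loss"
                                     else forcing[f] for f in forcing})
        state, diag = integrate_year(
            state, params_b, clim_y, forcing_y, unit_ctx, n_days=config.n_days
        )
        upns[k] = diag.uptake_unsatisfied
        residual[k] = diag.mass_balance_residual()
        if annual is not None:
            for p in POOLS:
                annual[p][k] = getattr(state, p) * conv
            for name, s in diag.flux_sums.items():
                annual_fluxes[name][k] = s * conv

    final = {p: getattr(state, p) * conv for p in POOLS}
    return SimulationResult(
        years=world.years,
        final_pools=final,
        annual_pools=annual,
        annual_fluxes=annual_fluxes,
        upns=upns,
        balance_residual=residual,
    )
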