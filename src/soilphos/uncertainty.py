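"""Monte-Carlo propagation of driver uncertainty.

Each uncertain driver variable carries a sampling family:

* ``normal_4sigma`` -- two estimates E1 <= E2 bound the plausible range; a
  normal centred on their midpoint with sigma = (E2 - E1)/4 puts ~95% of
  draws between the estimates;
* ``uniform`` -- both estimates equally credible, U(E1, E2);
* ``relative_normal`` -- one estimate E with sigma = (x/2) * E for
  x in {0.30, 0.50} (i.e. a 15% or 25% relative standard deviation).

Draws are truncated by re-drawing (never clipping, to avoid probability
mass at the bounds): at zero for P inputs/outputs, and at the spatial
min/max of the mean field for state-like drivers (natural pools, climate,
soil properties).  Cells and years are sampled independently.  An ensemble
run re-draws every non-frozen driver per member and summarises spread as
the per-cell coefficient of variation (population SD over mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core import POOLS
from .parameterization import NaturalPools, SoilProperties
from .simulate import RunConfig, assemble_forcing, build_forcing_base, build_parameters, run_simulation
from .synthetic import World

__all__ = [
    "DRIVERS",
    "UncertaintySpec",
    "sample_driver_value",
    "default_uncertainty_specs",
    "run_ensemble",
    "EnsembleResult",
    "coefficient_of_variation",
]

logger = logging.getLogger(__name__)

DRIVERS = ("BIOG", "FARM", "DEPO", "SLUD", "LOSS", "CLIM", "SPRO")

_MAX_REDRAWS = 100


@dataclass
class UncertaintySpec:
    """Sampling recipe for one driver variable."""

    variable: str
    driver: str
    family: str                 # normal_4sigma | uniform | relative_normal
    e1: np.ndarray | float = 1.0
    e2: np.ndarray | float | None = None
    x: float = 0.30             # relative_normal half-width
    lower: np.ndarray | float | None = None
    upper: np.ndarray | float | None = None

    def __post_init__(self):
        if self.driver not in DRIVERS:
            raise ValueError(f"unknown driver {self.driver!r}")
        if self.family not in ("normal_4sigma", "uniform", "relative_normal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "relative_normal" and self.x not in (0.30, 0.50):
            raise ValueError("x must be 0.30 or 0.50")
        if self.family in ("normal_4sigma", "uniform"):
            if self.e2 is None:
                raise ValueError(f"{self.family} needs two estimates")
            if np.any(np.asarray(self.e1) > np.asarray(self.e2)):
                raise ValueError("E1 must not exceed E2")

    def mean(self):
        if self.family == "relative_normal":
            return np.asarray(self.e1, dtype=float)
        return 0.5 * (np.asarray(self.e1, dtype=float) + np.asarray(self.e2, dtype=float))


def _truncate_redraw(draw_fn, lower, upper, rng, shape):
    value = draw_fn(shape)
    if lower is None and upper is None:
        return value
    lo = -np.inf if lower is None else lower
    hi = np.inf if upper is None else upper
    bad = (value < lo) | (value > hi)
    for _ in range(_MAX_REDRAWS):
        if not np.any(bad):
            return value
        fresh = draw_fn(shape)
        value = np.where(bad, fresh, value)
        bad = (value < lo) | (value > hi)
    if np.any(bad):
        logger.warning("truncation re-draw budget exhausted; clipping %d value(s)",
                       int(np.sum(bad)))
        value = np.clip(value, lo, hi)
    return value


def sample_driver_value(spec: UncertaintySpec, rng: np.random.Generator, shape=None):
    """One random realisation of the variable (or its mean-shaped array)."""
    if spec.family == "uniform":
        e1 = np.asarray(spec.e1, dtype=float)
        e2 = np.asarray(spec.e2, dtype=float)
        base_shape = np.broadcast_shapes(e1.shape, e2.shape)
        shape = shape or (base_shape if base_shape else None)
        value = rng.uniform(e1, e2, size=shape)
        return value

    if spec.family == "normal_4sigma":
        e1 = np.asarray(spec.e1, dtype=float)
        e2 = np.asarray(spec.e2, dtype=float)
        mid = 0.5 * (e1 + e2)
        sd = (e2 - e1) / 4.0
    else:
        mid = np.asarray(spec.e1, dtype=float)
        sd = (spec.x / 2.0) * mid
    base_shape = np.shape(mid)
    shape = shape or (base_shape if base_shape else None)

    def draw(s):
        return rng.normal(mid, np.abs(sd), size=s)

    return _truncate_redraw(draw, spec.lower, spec.upper, rng, shape)


def _spatial_bounds(field):
    return float(np.min(field)), float(np.max(field))


def default_uncertainty_specs(world: World, base) -> dict:
    """Default family assignment per uncertain driver variable.

    Two-estimate variables use normal_4sigma (grass NPP, grass P
    concentration) or uniform (manure, residue composition); single-estimate
    variables use relative_normal with x = 0.30, except sludge (0.50).
    Returns ``{variable: UncertaintySpec}``.
    """
    specs = {}
    specs["manure"] = UncertaintySpec(
        "manure", "FARM", "uniform",
        e1=np.minimum(base.manure_e1, base.manure_e2),
        e2=np.maximum(base.manure_e1, base.manure_e2),
        lower=0.0,
    )
    specs["residue_frac_ilab"] = UncertaintySpec(
        "residue_frac_ilab", "FARM", "uniform",
        e1=0.5 * world.composition.residues_i_lab,
        e2=1.5 * world.composition.residues_i_lab,
        lower=0.0, upper=1.0,
    )
    specs["residue_frac_olab"] = UncertaintySpec(
        "residue_frac_olab", "FARM", "uniform",
        e1=0.5 * world.composition.residues_o_lab,
        e2=1.5 * world.composition.residues_o_lab,
        lower=0.0, upper=1.0,
    )
    specs["grass_npp"] = UncertaintySpec(
        "grass_npp", "FARM", "normal_4sigma",
        e1=np.minimum(base.grass_npp_e1, base.grass_npp_e2),
        e2=np.maximum(base.grass_npp_e1, base.grass_npp_e2),
        lower=0.0,
    )
    lo, hi = world.grass_params.p_pct_above_bounds
    specs["grass_p_pct_above"] = UncertaintySpec(
        "grass_p_pct_above", "FARM", "normal_4sigma", e1=lo, e2=hi, lower=0.0,
    )
    specs["chem_grass_factor"] = UncertaintySpec(
        "chem_grass_factor", "FARM", "relative_normal", e1=1.0, x=0.30, lower=0.0,
    )
    specs["crop_uptake_factor"] = UncertaintySpec(
        "crop_uptake_factor", "FARM", "relative_normal", e1=1.0, x=0.30, lower=0.0,
    )
    specs["sludge_factor"] = UncertaintySpec(
        "sludge_factor", "SLUD", "relative_normal", e1=1.0, x=0.50, lower=0.0,
    )
    specs["depo_factor"] = UncertaintySpec(
        "depo_factor", "DEPO", "relative_normal", e1=1.0, x=0.30, lower=0.0,
    )
    specs["erosion_factor"] = UncertaintySpec(
        "erosion_factor", "LOSS", "relative_normal", e1=1.0, x=0.30, lower=0.0,
    )
    for pool in ("i_lab", "i_sec", "i_prim", "o_lab", "o_sta", "x_occ"):
        fieldv = getattr(world.natural, pool)
        lo, hi = _spatial_bounds(fieldv)
        specs[f"natural_{pool}"] = UncertaintySpec(
            f"natural_{pool}", "BIOG", "relative_normal", e1=fieldv, x=0.30,
            lower=lo, upper=hi,
        )
    for var in ("t_soil", "w_rel", "w_abs", "t_air"):
        fieldv = world.climate[var]
        lo, hi = _spatial_bounds(fieldv)
        specs[f"climate_{var}"] = UncertaintySpec(
            f"climate_{var}", "CLIM", "relative_normal", e1=fieldv, x=0.30,
            lower=lo, upper=hi,
        )
    for var in ("ph_water", "soil_carbon", "sand_pct", "clay_pct", "silt_pct"):
        fieldv = getattr(world.soil, var)
        lo, hi = _spatial_bounds(fieldv)
        specs[f"soil_{var}"] = UncertaintySpec(
            f"soil_{var}", "SPRO", "relative_normal", e1=fieldv, x=0.30,
            lower=lo, upper=hi,
        )
    return specs


def draw_member_sample(specs: dict, world: World, rng, frozen=frozenset()) -> dict:
    """One member's perturbed drivers; frozen drivers keep their means."""

    def get(name, per_year_shape=None):
        spec = specs[name]
        if spec.driver in frozen:
            v = spec.mean()
            if per_year_shape is not None:
                v = np.broadcast_to(v, per_year_shape).copy()
            return v
        return sample_driver_value(spec, rng, shape=per_year_shape)

    Y, C = world.n_years, world.n_cells
    sample = {}
    sample["manure"] = get("manure")
    sample["grass_npp"] = get("grass_npp")
    sample["grass_p_pct_above"] = float(np.asarray(get("grass_p_pct_above")))
    sample["residue_fracs"] = (
        float(np.asarray(get("residue_frac_ilab"))),
        float(np.asarray(get("residue_frac_olab"))),
    )
    sample["chem_grass_factor"] = get("chem_grass_factor", (Y, C))
    sample["crop_uptake_factor"] = get("crop_uptake_factor", (Y, C))
    sample["sludge_factor"] = get("sludge_factor", (Y, C))
    sample["depo_factor"] = get("depo_factor", (Y, C))
    sample["erosion_factor"] = get("erosion_factor", (C,))

    sample["natural"] = NaturalPools(**{
        pool: get(f"natural_{pool}")
        for pool in ("i_lab", "i_sec", "i_prim", "o_lab", "o_sta", "x_occ")
    })
    sample["climate"] = {
        var: np.maximum(get(f"climate_{var}"), 1e-6)
        if var in ("w_abs",) else get(f"climate_{var}")
        for var in ("t_soil", "w_rel", "w_abs", "t_air")
    }
    sample["climate"]["w_rel"] = np.maximum(sample["climate"]["w_rel"], 0.0)

    sand = get("soil_sand_pct")
    clay = get("soil_clay_pct")
    silt = get("soil_silt_pct")
    tex = sand + clay + silt  # renormalise so the texture partition holds
    sample["soil"] = SoilProperties(
        sand_pct=100.0 * sand / tex,
        clay_pct=100.0 * clay / tex,
        silt_pct=100.0 * silt / tex,
        ph_water=np.clip(get("soil_ph_water"), 2.0, 12.0),
        soil_carbon=get("soil_soil_carbon"),
        bulk_density=world.soil.bulk_density,
        coarse_frag_frac=world.soil.coarse_frag_frac,
    )
    return sample


@dataclass
class EnsembleResult:
    """Per-member end states plus the mean run and its CV summary."""

    member_final_pools: dict     # pool -> (members, 2, cells), kgP ha^-1
    mean_run: object             # SimulationResult of the all-mean run
    n_members: int
    seed: int

    def cv(self, pool="i_lab"):
        return coefficient_of_variation(self.member_final_pools[pool])

    def cv_total(self):
        total = sum(self.member_final_pools[p] for p in POOLS)
        return coefficient_of_variation(total)


def run_ensemble(
    world: World,
    n: int = 100,
    seed: int = 0,
    frozen_drivers=frozenset(),
    config: RunConfig | None = None,
) -> EnsembleResult:
    """Propagate driver uncertainty through ``n`` member simulations.

    Member driver values are drawn up front (one independent stream) and
    the members are advanced together through the daily dynamics as one
    batched state.  A separate mean run uses the mean value of every
    driver.  Results are bit-reproducible for a given seed.
    """
    config = config or RunConfig(store_annual=False)
    frozen = frozenset(frozen_drivers)
    unknown = frozen - set(DRIVERS)
    if unknown:
        raise ValueError(f"unknown frozen drivers {sorted(unknown)}")

    base = build_forcing_base(world)
    specs = default_uncertainty_specs(world, base)
    rng = np.random.default_rng(seed)

    forcing_fields = None
    params_list, natural_list, climate_list, w_mean_list = [], [], [], []
    for _ in range(n):
        sample = draw_member_sample(specs, world, rng, frozen)
        forcing = assemble_forcing(world, base, config, sample)
        if forcing_fields is None:
            forcing_fields = {
                f: np.empty((world.n_years, n) + (2, world.n_cells))
                if f != "erosion_frac_loss" else np.empty((n, 2, world.n_cells))
                for f in forcing
            }
        for f, arr in forcing.items():
            if f == "erosion_frac_loss":
                forcing_fields[f][len(params_list)] = arr
            else:
                forcing_fields[f][:, len(params_list)] = arr
        params, w_abs_mean = build_parameters(
            world, config,
            natural=sample["natural"], soil=sample["soil"], climate=sample["climate"],
        )
        params_list.append(params)
        natural_list.append(sample["natural"])
        climate_list.append(sample["climate"])
        w_mean_list.append(w_abs_mean)

    from .parameterization import FluxParameters

    params_stack = FluxParameters(**{
        f: np.stack([np.asarray(getattr(p, f), dtype=float) for p in params_list])
        for f in ("b", "k_lab_to_sol", "k_sol_to_lab", "k_sol_to_sec",
                  "k_sec_to_sol", "k_sec_to_occ", "k_occ_to_sec",
                  "k_weathering", "k_min_stable", "k_min_labile",
                  "p_c_inf", "w_abs_mean")
    })
    natural_stack = NaturalPools(**{
        pool: np.stack([getattr(nt, pool) for nt in natural_list])
        for pool in ("i_lab", "i_sec", "i_prim", "o_lab", "o_sta", "x_occ")
    })
    climate_stack = {
        var: np.stack([c[var] for c in climate_list], axis=1)  # (years, members, cells)
        for var in ("t_soil", "w_rel", "w_abs", "t_air")
    }
    w_mean_stack = np.stack(w_mean_list)

    member_cfg = replace(config, store_annual=False)
    result = run_simulation(
        world, member_cfg,
        batch={
            "forcing": forcing_fields,
            "params": params_stack,
            "natural": natural_stack,
            "climate": climate_stack,
            "w_abs_mean": w_mean_stack,
        },
    )
    mean_run = run_simulation(world, config)
    return EnsembleResult(
        member_final_pools=result.final_pools,
        mean_run=mean_run,
        n_members=n,
        seed=seed,
    )


def coefficient_of_variation(members: np.ndarray, axis: int = 0):
    """Population-SD over mean across the member axis.

    Returns a masked array: entries with non-positive mean are masked
    rather than propagated as NaN/inf.
    """
    members = np.asarray(members, dtype=float)
    if members.shape[axis] < 2:
        raise ValueError("need at least two ensemble members")
    mean = members.mean(axis=axis)
    sd = members.std(axis=axis)  # population (ddof=0)
    mask = mean <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mask, 0.0, sd / np.where(mask, 1.0, mean))
    return np.ma.masked_array(cv, mask=mask)
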