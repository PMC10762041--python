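"""Configuration files, NetCDF/CSV persistence and structured run output.

NetCDF files are written through xarray's scipy backend (NetCDF-3 classic)
with CF-style ``units`` attributes: pools in "kgP ha-1", fluxes in
"kgP ha-1 yr-1".  A synthetic world can be persisted to the same layouts
the real-data path reads (grids in NetCDF, country tables in long-format
CSV), so the fixture files double as format documentation.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .core import POOLS
from .drivers import CountryTable, CropParameters, GrassParameters
from .lucc import LANDUSE_CATEGORIES, LandUseState
from .parameterization import NaturalPools, SoilProperties
from .simulate import RunConfig, SimulationResult
from .synthetic import World, WorldConfig

__all__ = [
    "FullConfig",
    "load_config",
    "archive_config",
    "write_outputs",
    "read_outputs",
    "write_world",
    "read_world",
]

logger = logging.getLogger(__name__)

_ENGINE = "scipy"  # NetCDF-3; no optional backend needed

_CLIMATE_VARS = ("t_soil", "w_rel", "w_abs", "t_air")
_DEPO_COMPONENTS = ("dust", "seasalt", "pbap", "natcomb", "anthcomb")


@dataclasses.dataclass
class FullConfig:
    """World + run + ensemble settings from one YAML file."""

    world: WorldConfig
    world_seed: int
    run: RunConfig
    ensemble_n: int = 100
    ensemble_seed: int = 0
    frozen_drivers: tuple = ()

    def to_dict(self) -> dict:
        return {
            "world": {**dataclasses.asdict(self.world), "seed": self.world_seed},
            "run": dataclasses.asdict(self.run),
            "ensemble": {
                "n": self.ensemble_n,
                "seed": self.ensemble_seed,
                "frozen_drivers": list(self.frozen_drivers),
            },
        }


def load_config(path) -> FullConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    wd = dict(raw.get("world", {}))
    world_seed = int(wd.pop("seed", 0))
    if "grass_p_bounds" in wd:
        wd["grass_p_bounds"] = tuple(wd["grass_p_bounds"])
    ens = raw.get("ensemble", {})
    cfg = FullConfig(
        world=WorldConfig(**wd),
        world_seed=world_seed,
        run=RunConfig(**raw.get("run", {})),
        ensemble_n=int(ens.get("n", 100)),
        ensemble_seed=int(ens.get("seed", 0)),
        frozen_drivers=tuple(ens.get("frozen_drivers", ())),
    )
    cfg.run.validate()
    return cfg


def archive_config(config: FullConfig, out_dir) -> Path:
    """Write the fully-resolved configuration next to the outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "config_resolved.yml"
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# simulation outputs

def _result_dataset(result: SimulationResult, world: World) -> xr.Dataset:
    coords = {
        "year": world.years,
        "landuse": list(("crop", "grass")),
        "cell": np.arange(world.n_cells),
    }
    data = {}
    if result.annual_pools is None:
        raise ValueError("annual pools were not stored; rerun with store_annual")
    for p in POOLS:
        data[f"p_{p}"] = xr.DataArray(
            result.annual_pools[p], dims=("year", "landuse", "cell"),
            attrs={"units": "kgP ha-1", "long_name": f"soil P pool {p}, 0-0.3 m"},
        )
    if result.annual_fluxes is not None:
        for name, arr in result.annual_fluxes.items():
            data[f"flux_{name}"] = xr.DataArray(
                arr, dims=("year", "landuse", "cell"),
                attrs={"units": "kgP ha-1 yr-1",
                       "long_name": f"annual gross {name.replace('_', ' ')} flux"},
            )
    data["fp_upns"] = xr.DataArray(
        result.upns, dims=("year", "landuse", "cell"),
        attrs={"units": "kgP ha-1 yr-1",
               "long_name": "prescribed plant uptake not satisfied by the pools"},
    )
    data["land_area"] = xr.DataArray(
        world.land_area, dims=("cell",), attrs={"units": "ha"},
    )
    data["landuse_fraction"] = xr.DataArray(
        world.landuse.fractions[:, :2, :], dims=("year", "landuse", "cell"),
        attrs={"units": "1"},
    )
    return xr.Dataset(data, coords=coords)


def write_outputs(result: SimulationResult, world: World, out_dir, cv: dict | None = None):
    """Write the mean-run NetCDF (pools, unsatisfied uptake, land area) and,
    if provided, a CV file mirroring its layout.  Round-trips bit-exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = _result_dataset(result, world)
    mean_path = out / "soil_p_mean.nc"
    ds.to_netcdf(mean_path, engine=_ENGINE)
    paths = [mean_path]
    if cv is not None:
        cv_data = {
            f"cv_p_{p}": xr.DataArray(
                np.asarray(cv[p]), dims=("landuse", "cell"),
                attrs={"units": "1", "long_name": f"coefficient of variation of {p}"},
            )
            for p in cv
        }
        cv_ds = xr.Dataset(
            cv_data,
            coords={"landuse": ["crop", "grass"], "cell": np.arange(world.n_cells)},
        )
        cv_path = out / "soil_p_cv.nc"
        cv_ds.to_netcdf(cv_path, engine=_ENGINE)
        paths.append(cv_path)
    return paths


def read_outputs(path) -> xr.Dataset:
    return xr.load_dataset(path, engine=_ENGINE)


# ---------------------------------------------------------------------------
# world persistence

def write_world(world: World, out_dir):
    """Persist a world to the grid/table layouts the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    coords = {
        "year": world.years,
        "year_t": world.years[:-1],
        "lu": list(LANDUSE_CATEGORIES),
        "lu2": ["crop", "grass"],
        "cell": np.arange(world.n_cells),
    }
    data = {
        "country_id": (("cell",), world.country_id),
        "land_area": (("cell",), world.land_area),
        "landuse_fractions": (("year", "lu", "cell"), world.landuse.fractions),
        "n_manure": (("year", "lu2", "cell"), world.n_manure),
        "n_chem_grass": (("year", "cell"), world.n_chem_grass),
        "p_chem_total": (("year", "cell"), world.p_chem_total),
        "npp_tot": (("year", "cell"), world.npp_tot),
        "gi": (("year", "cell"), world.gi),
        "erosion_loss": (("lu2", "cell"), world.erosion_loss),
    }
    for f in dataclasses.fields(SoilProperties):
        if f.name != "depth":
            data[f"soil_{f.name}"] = (("cell",), getattr(world.soil, f.name))
    for f in dataclasses.fields(NaturalPools):
        data[f"natural_{f.name}"] = (("cell",), getattr(world.natural, f.name))
    for v in _CLIMATE_VARS:
        data[f"climate_{v}"] = (("year", "cell"), world.climate[v])
    for comp in _DEPO_COMPONENTS:
        data[f"depo_{comp}"] = (("cell",), world.deposition[comp])
    for crop in world.crops:
        data[f"yield2000_{crop.name}"] = (("cell",), world.crop_yield_map_2000[crop.name])
        data[f"area2000_{crop.name}"] = (("cell",), world.crop_area_map_2000[crop.name])
    ds = xr.Dataset(data, coords=coords, attrs={
        "seed": world.seed,
        **{f"config_{k}": (list(v) if isinstance(v, tuple) else v)
           for k, v in dataclasses.asdict(world.config).items()},
    })
    # a transition matrix needs two distinct land-use axes
    ds["landuse_transitions"] = xr.DataArray(
        world.landuse.transitions, dims=("year_t", "lu_to", "lu_from", "cell"),
        coords={"lu_to": list(LANDUSE_CATEGORIES), "lu_from": list(LANDUSE_CATEGORIES)},
    )
    ds.to_netcdf(out / "grids.nc", engine=_ENGINE)

    rows = [world.country_table.frame]
    for crop in world.crops:
        for cid, s in world.country_crop_yield[crop.name].items():
            rows.append(pd.DataFrame({"country": cid, "year": s.index,
                                      "variable": f"yield_{crop.name}", "value": s.values}))
        for cid, s in world.country_crop_area[crop.name].items():
            rows.append(pd.DataFrame({"country": cid, "year": s.index,
                                      "variable": f"area_{crop.name}", "value": s.values}))
    for cid, s in world.population.items():
        rows.append(pd.DataFrame({"country": cid, "year": s.index,
                                  "variable": "population", "value": s.values}))
    for cid, (yrs, vals) in world.sludge_excretion.items():
        rows.append(pd.DataFrame({"country": cid, "year": list(yrs),
                                  "variable": "sludge_excretion", "value": list(vals)}))
    for cid, (yrs, fr) in world.sludge_treat_fractions.items():
        fr = np.asarray(fr)
        for t in range(3):
            rows.append(pd.DataFrame({"country": cid, "year": list(yrs),
                                      "variable": f"sludge_treat_frac_{t + 1}",
                                      "value": fr[:, t]}))
    pd.concat(rows, ignore_index=True).to_csv(out / "country_tables.csv", index=False)

    crop_rows = []
    for crop in world.crops:
        crop_rows.append({
            "name": crop.name,
            "p_pct_harvest": crop.p_pct_harvest,
            "p_pct_abov_ex_harvest": crop.p_pct_abov_ex_harvest,
            "harvest_index": crop.harvest_index,
            "frac_above": crop.frac_above,
            "is_forage": crop.is_forage,
            "is_root_crop": crop.is_root_crop,
        })
    pd.DataFrame(crop_rows).to_csv(out / "crop_parameters.csv", index=False)

    em = pd.concat([
        pd.DataFrame({"series": "a", "year": world.anth_emissions_a.index,
                      "value": world.anth_emissions_a.values}),
        pd.DataFrame({"series": "b", "year": world.anth_emissions_b.index,
                      "value": world.anth_emissions_b.values}),
    ])
    em.to_csv(out / "anthropogenic_emissions.csv", index=False)
    return out


def read_world(in_dir) -> World:
    """Reconstruct a :class:`World` from the files ``write_world`` wrote."""
    src = Path(in_dir)
    ds = xr.load_dataset(src / "grids.nc", engine=_ENGINE)
    cfg_kwargs = {}
    for f in dataclasses.fields(WorldConfig):
        v = ds.attrs.get(f"config_{f.name}")
        if v is not None:
            cfg_kwargs[f.name] = tuple(v) if f.name == "grass_p_bounds" else v
    config = WorldConfig(**cfg_kwargs)

    soil = SoilProperties(**{
        f.name: ds[f"soil_{f.name}"].values
        for f in dataclasses.fields(SoilProperties) if f.name != "depth"
    })
    natural = NaturalPools(**{
        f.name: ds[f"natural_{f.name}"].values
        for f in dataclasses.fields(NaturalPools)
    })
    climate = {v: ds[f"climate_{v}"].values for v in _CLIMATE_VARS}
    landuse = LandUseState(
        fractions=ds["landuse_fractions"].values,
        transitions=ds["landuse_transitions"].values,
    )

    table = pd.read_csv(src / "country_tables.csv")
    crops_df = pd.read_csv(src / "crop_parameters.csv")
    crops = tuple(
        CropParameters(
            name=r["name"],
            p_pct_harvest=r["p_pct_harvest"],
            p_pct_abov_ex_harvest=r["p_pct_abov_ex_harvest"],
            harvest_index=r["harvest_index"],
            frac_above=r["frac_above"],
            is_forage=bool(r["is_forage"]),
            is_root_crop=bool(r["is_root_crop"]),
        )
        for _, r in crops_df.iterrows()
    )

    def series_map(variable):
        sel = table[table["variable"] == variable]
        return {
            cid: grp.set_index("year")["value"].sort_index()
            for cid, grp in sel.groupby("country")
        }

    country_crop_yield = {c.name: series_map(f"yield_{c.name}") for c in crops}
    country_crop_area = {c.name: series_map(f"area_{c.name}") for c in crops}
    population = series_map("population")
    sludge_excretion = {
        cid: (tuple(s.index), tuple(s.values))
        for cid, s in series_map("sludge_excretion").items()
    }
    treat = {t: series_map(f"sludge_treat_frac_{t}") for t in (1, 2, 3)}
    sludge_treat_fractions = {}
    for cid in population:
        yrs = tuple(treat[1][cid].index)
        vals = np.stack([treat[t][cid].values for t in (1, 2, 3)], axis=1)
        sludge_treat_fractions[cid] = (yrs, vals)

    em = pd.read_csv(src / "anthropogenic_emissions.csv")
    em_a = em[em["series"] == "a"].set_index("year")["value"].sort_index()
    em_b = em[em["series"] == "b"].set_index("year")["value"].sort_index()

    world = World(
        config=config,
        seed=int(ds.attrs.get("seed", -1)),
        years=ds["year"].values,
        country_id=ds["country_id"].values.astype(int),
        land_area=ds["land_area"].values,
        soil=soil,
        natural=natural,
        climate=climate,
        landuse=landuse,
        n_manure=ds["n_manure"].values,
        n_chem_grass=ds["n_chem_grass"].values,
        p_chem_total=ds["p_chem_total"].values,
        npp_tot=ds["npp_tot"].values,
        gi=ds["gi"].values,
        deposition={c: ds[f"depo_{c}"].values for c in _DEPO_COMPONENTS},
        anth_emissions_a=em_a,
        anth_emissions_b=em_b,
        erosion_loss=ds["erosion_loss"].values,
        crops=crops,
        crop_yield_map_2000={c.name: ds[f"yield2000_{c.name}"].values for c in crops},
        crop_area_map_2000={c.name: ds[f"area2000_{c.name}"].values for c in crops},
        country_table=CountryTable(
            table[table["variable"] == "manure_p"].reset_index(drop=True)
        ),
        country_crop_yield=country_crop_yield,
        country_crop_area=country_crop_area,
        population=population,
        sludge_excretion=sludge_excretion,
        sludge_treat_fractions=sludge_treat_fractions,
        grass_params=GrassParameters(
            p_pct_above=float(np.mean(config.grass_p_bounds)),
            p_pct_above_bounds=tuple(config.grass_p_bounds),
        ),
    )
    world.validate()
    return world
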