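"""Self-consistent synthetic worlds for exercising the full pipeline.

A :class:`World` bundles everything a simulation consumes: a small grid of
cells grouped into contiguous countries, static soil properties and
natural-soil P pools, annual climate, land-cover fractions with a
consistent transition history, and every annual driver (manure and
fertilizer nitrogen/phosphorus fields, grassland NPP and grazing intensity,
per-crop yield and area maps with country time series, atmospheric
deposition components, sewage-sludge country tables, gross erosion rates).
Uncertain drivers carry two estimates so the Monte-Carlo machinery can be
exercised end to end without any external data.

Magnitudes are drawn from agronomically plausible ranges (chemical
fertilizer 0-40 kgP ha-1 yr-1, natural total P of order 100-3000 kgP ha-1,
grassland NPP of a few tonnes C ha-1 yr-1); the spatial fields are white
noise, i.e. no attempt is made at realistic spatial covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drivers import CompositionFractions, CountryTable, CropParameters, GrassParameters
from .lucc import LANDUSE_CATEGORIES, LandUseState
from .parameterization import NaturalPools, SoilProperties

__all__ = ["World", "WorldConfig", "make_world", "make_steady_world"]


@dataclass
class WorldConfig:
    nx: int = 10
    ny: int = 10
    n_countries: int = 4
    year_start: int = 1950
    year_end: int = 2018
    #: grass P concentration bounds, gP (100 gFM)^-1
    grass_p_bounds: tuple = (2.5e-2, 1.5e-1)

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell")
        if self.n_countries < 1 or self.n_countries > self.nx * self.ny:
            raise ValueError("invalid number of countries")
        if self.year_end <= self.year_start:
            raise ValueError("year_end must exceed year_start")


DEFAULT_CROPS = (
    CropParameters("cereal", p_pct_harvest=0.30, p_pct_abov_ex_harvest=0.10,
                   harvest_index=0.45, frac_above=0.85),
    CropParameters("forage", p_pct_harvest=0.15, p_pct_abov_ex_harvest=0.15,
                   harvest_index=0.80, frac_above=0.80, is_forage=True),
    CropParameters("tuber", p_pct_harvest=0.06, p_pct_abov_ex_harvest=0.25,
                   harvest_index=0.85, frac_above=0.60, is_root_crop=True),
)


@dataclass
class World:
    """Everything one simulation consumes; see the module docstring."""

    config: WorldConfig
    seed: int
    years: np.ndarray
    country_id: np.ndarray          # (cells,)
    land_area: np.ndarray           # ha per cell
    soil: SoilProperties
    natural: NaturalPools           # mgP per kg soil
    climate: dict                   # t_soil/w_rel/w_abs/t_air -> (years, cells)
    landuse: LandUseState
    n_manure: np.ndarray            # (years, 2, cells) kgN ha-1 yr-1
    n_chem_grass: np.ndarray        # (years, cells) kgN ha-1 yr-1
    p_chem_total: np.ndarray        # (years, cells) kgP ha-1 yr-1
    npp_tot: np.ndarray             # (years, cells) kgC ha-1 yr-1
    gi: np.ndarray                  # (years, cells)
    deposition: dict                # component -> (cells,) kgP ha-1 yr-1
    anth_emissions_a: pd.Series
    anth_emissions_b: pd.Series
    erosion_loss: np.ndarray        # (2, cells) kg soil ha-1 yr-1
    crops: tuple
    crop_yield_map_2000: dict       # crop -> (cells,) kgFM ha-1
    crop_area_map_2000: dict        # crop -> (cells,) ha
    country_table: CountryTable     # variable "manure_p", kgP yr-1
    country_crop_yield: dict        # crop -> {country -> pd.Series}
    country_crop_area: dict
    population: dict                # country -> pd.Series
    sludge_excretion: dict          # country -> (anchor_years, values)
    sludge_treat_fractions: dict    # country -> (anchor_years, (n, 3))
    grass_params: GrassParameters = field(default_factory=GrassParameters)
    composition: CompositionFractions = field(default_factory=CompositionFractions)

    @property
    def n_cells(self) -> int:
        return self.country_id.shape[0]

    @property
    def n_years(self) -> int:
        return len(self.years)

    def frac(self, lu: str) -> np.ndarray:
        return self.landuse.fractions[:, LANDUSE_CATEGORIES.index(lu), :]

    def crop_area_country_series(self) -> dict:
        """country -> pd.Series of national cropland area (ha) per year."""
        out = {}
        area = self.frac("crop") * self.land_area
        for cid in np.unique(self.country_id):
            cells = self.country_id == cid
            out[cid] = pd.Series(area[:, cells].sum(axis=1), index=self.years)
        return out

    def validate(self) -> None:
        self.soil.validate()
        self.landuse.validate()
        if self.landuse.fractions.shape != (self.n_years, 4, self.n_cells):
            raise ValueError("land-use fractions do not span the run period")
        for k, v in self.climate.items():
            if v.shape != (self.n_years, self.n_cells):
                raise ValueError(f"climate field {k} has wrong shape")
        if np.any(self.climate["w_abs"] <= 0):
            raise ValueError("w_abs must be positive")
        for name in ("n_manure", "n_chem_grass", "p_chem_total", "npp_tot", "gi",
                     "erosion_loss"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"negative driver field {name}")
        if np.any((self.gi < 0) | (self.gi > 1)):
            raise ValueError("grazing intensity outside [0, 1]")
        if np.any(self.country_id < 0):
            raise ValueError("cell without country")


def _landuse_series(rng, n_years, n_cells):
    frac0 = np.empty((4, n_cells))
    frac0[0] = rng.uniform(0.10, 0.40, n_cells)   # crop
    frac0[1] = rng.uniform(0.10, 0.40, n_cells)   # grass
    frac0[3] = rng.uniform(0.00, 0.05, n_cells)   # urban
    frac0[2] = 1.0 - frac0[[0, 1, 3]].sum(axis=0)  # nonagri remainder

    fractions = np.empty((n_years, 4, n_cells))
    transitions = np.zeros((n_years - 1, 4, 4, n_cells))
    fractions[0] = frac0
    for y in range(n_years - 1):
        f = fractions[y]
        d = np.zeros((4, 4, n_cells))
        for j in range(4):
            if j == 3:  # urban land never converts away
                continue
            budget = f[j].copy()
            for i in range(4):
                if i == j:
                    continue
                delta = rng.uniform(0.0, 0.01, n_cells) * budget
                d[i, j] = delta
                budget = budget - delta
        transitions[y] = d
        outgoing = d.sum(axis=0)
        incoming = d.sum(axis=1)
        fractions[y + 1] = f - outgoing + incoming
    return LandUseState(fractions=fractions, transitions=transitions)


def _country_series(rng, years, base, growth, noise):
    trend = base * (1.0 + growth) ** (years - years[0])
    values = trend * rng.uniform(1.0 - noise, 1.0 + noise, len(years))
    return pd.Series(np.maximum(values, 0.0), index=years)


def make_world(config: WorldConfig | None = None, seed: int = 0) -> World:
    """Generate a reproducible synthetic world; same seed, same world."""
    if config is None:
        config = WorldConfig()
    rng = np.random.default_rng(seed)
    n_cells = config.nx * config.ny
    years = np.arange(config.year_start, config.year_end + 1)
    n_years = len(years)

    # contiguous blocks of cells per country, uniform cell areas
    bounds = np.linspace(0, n_cells, config.n_countries + 1).astype(int)
    country_id = np.zeros(n_cells, dtype=int)
    for c in range(config.n_countries):
        country_id[bounds[c]:bounds[c + 1]] = c
    land_area = np.full(n_cells, 2.5e5)  # ha, ~half-degree-cell order

    sand = rng.uniform(10, 80, n_cells)
    clay = rng.uniform(5, np.minimum(60, 95 - sand))
    silt = 100.0 - sand - clay
    soil = SoilProperties(
        sand_pct=sand, clay_pct=clay, silt_pct=silt,
        ph_water=rng.uniform(4.5, 8.5, n_cells),
        soil_carbon=rng.uniform(5, 40, n_cells),
        bulk_density=rng.uniform(1100, 1600, n_cells),
        coarse_frag_frac=rng.uniform(0.0, 0.3, n_cells),
    )

    natural = NaturalPools(
        i_lab=rng.uniform(20, 200, n_cells),
        i_sec=rng.uniform(30, 300, n_cells),
        i_prim=rng.uniform(50, 400, n_cells),
        o_lab=rng.uniform(20, 150, n_cells),
        o_sta=rng.uniform(50, 300, n_cells),
        x_occ=rng.uniform(50, 400, n_cells),
    )

    t_base = rng.uniform(2, 22, n_cells)
    w_fc = rng.uniform(0.20, 0.45, n_cells)
    w_rel_base = rng.uniform(0.35, 0.85, n_cells)
    t_soil = t_base + rng.normal(0, 0.5, (n_years, n_cells))
    w_rel = np.clip(w_rel_base + rng.normal(0, 0.05, (n_years, n_cells)), 0.05, 1.0)
    climate = {
        "t_soil": t_soil,
        "w_rel": w_rel,
        "w_abs": w_rel * w_fc,
        "t_air": t_soil + rng.uniform(-2, 2, n_cells),
    }

    landuse = _landuse_series(rng, n_years, n_cells)

    growth = 1.0 + 0.012 * (years - years[0])  # mild shared upward trend
    n_manure = np.empty((n_years, 2, n_cells))
    n_manure[:, 0, :] = rng.uniform(0, 50, n_cells) * growth[:, None] \
        * rng.uniform(0.8, 1.2, (n_years, n_cells))
    n_manure[:, 1, :] = rng.uniform(0, 20, n_cells) * growth[:, None] \
        * rng.uniform(0.8, 1.2, (n_years, n_cells))
    n_chem_grass = rng.uniform(0, 20, n_cells) * growth[:, None] \
        * rng.uniform(0.8, 1.2, (n_years, n_cells))
    p_chem_total = rng.uniform(0, 40, n_cells) * growth[:, None] \
        * rng.uniform(0.8, 1.2, (n_years, n_cells))

    npp_tot = rng.uniform(2000, 8000, n_cells) * rng.uniform(0.9, 1.1, (n_years, n_cells))
    gi = np.clip(rng.uniform(0.02, 0.5, n_cells) * rng.uniform(0.8, 1.2, (n_years, n_cells)), 0, 1)

    deposition = {
        "dust": rng.uniform(0.02, 0.20, n_cells),
        "seasalt": rng.uniform(0.0, 0.05, n_cells),
        "pbap": rng.uniform(0.0, 0.05, n_cells),
        "natcomb": rng.uniform(0.0, 0.05, n_cells),
        "anthcomb": rng.uniform(0.0, 0.10, n_cells),
    }
    em_years_a = np.arange(min(years[0], 1960), 2008)
    anth_emissions_a = pd.Series(
        np.linspace(1.0, 3.0, len(em_years_a)) * rng.uniform(0.9, 1.1, len(em_years_a)),
        index=em_years_a,
    )
    em_years_b = np.arange(1997, max(years[-1], 2013) + 1)
    anth_emissions_b = pd.Series(
        np.linspace(2.0, 4.5, len(em_years_b)) * rng.uniform(0.9, 1.1, len(em_years_b)),
        index=em_years_b,
    )

    erosion_loss = np.stack([
        rng.uniform(100, 5000, n_cells),   # cropland erodes more
        rng.uniform(50, 2000, n_cells),
    ])

    crops = DEFAULT_CROPS
    yield_ranges = {"cereal": (2000, 8000), "forage": (10000, 30000),
                    "tuber": (15000, 45000)}
    crop_yield_map_2000 = {}
    crop_area_map_2000 = {}
    crop_share = rng.dirichlet(np.ones(len(crops)), n_cells).T  # (crop, cells)
    idx2000 = int(np.searchsorted(years, 2000)) if 2000 in years else n_years - 1
    crop_area_total = landuse.fractions[idx2000, 0, :] * land_area
    for k, crop in enumerate(crops):
        lo, hi = yield_ranges.get(crop.name, (2000, 10000))
        crop_yield_map_2000[crop.name] = rng.uniform(lo, hi, n_cells)
        crop_area_map_2000[crop.name] = crop_share[k] * crop_area_total

    country_ids = np.unique(country_id)
    rows = []
    country_crop_yield = {c.name: {} for c in crops}
    country_crop_area = {c.name: {} for c in crops}
    population = {}
    sludge_excretion = {}
    sludge_treat_fractions = {}
    table_years = np.arange(min(config.year_start, 1950), config.year_end + 1)
    for cid in country_ids:
        cells = country_id == cid
        # national manure production loosely tied to the gridded estimate
        est1_scale = float(
            (0.20 * n_manure[:, :, cells]
             * landuse.fractions[:, :2, cells] * land_area[cells]).sum(axis=(1, 2)).mean()
        )
        manure_series = _country_series(
            rng, table_years, est1_scale * rng.uniform(0.6, 1.8), 0.005, 0.1
        )
        for y, v in manure_series.items():
            rows.append((cid, int(y), "manure_p", float(v)))
        for crop in crops:
            country_crop_yield[crop.name][cid] = _country_series(
                rng, table_years,
                float(np.mean(crop_yield_map_2000[crop.name][cells])) * rng.uniform(0.8, 1.2),
                0.008, 0.05,
            )
            country_crop_area[crop.name][cid] = _country_series(
                rng, table_years,
                float(np.sum(crop_area_map_2000[crop.name][cells])) * rng.uniform(0.8, 1.2),
                0.002, 0.05,
            )
        population[cid] = _country_series(rng, table_years, rng.uniform(1e6, 5e7), 0.015, 0.01)
        sludge_excretion[cid] = ((1970, 2010),
                                 (rng.uniform(0.3, 0.5), rng.uniform(0.45, 0.65)))
        anchors = (1970, 1990, 2000, 2010)
        fr = np.cumsum(rng.uniform(0.02, 0.12, (len(anchors), 3)), axis=0)
        sludge_treat_fractions[cid] = (anchors, np.clip(fr, 0, 1 / 3))

    world = World(
        config=config,
        seed=seed,
        years=years,
        country_id=country_id,
        land_area=land_area,
        soil=soil,
        natural=natural,
        climate=climate,
        landuse=landuse,
        n_manure=n_manure,
        n_chem_grass=n_chem_grass,
        p_chem_total=p_chem_total,
        npp_tot=npp_tot,
        gi=gi,
        deposition=deposition,
        anth_emissions_a=anth_emissions_a,
        anth_emissions_b=anth_emissions_b,
        erosion_loss=erosion_loss,
        crops=crops,
        crop_yield_map_2000=crop_yield_map_2000,
        crop_area_map_2000=crop_area_map_2000,
        country_table=CountryTable(
            pd.DataFrame(rows, columns=["country", "year", "variable", "value"])
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


def make_steady_world(config: WorldConfig | None = None, seed: int = 0) -> World:
    """A quiescent variant: zero inputs/outputs, constant climate, frozen
    land use.  Pools initialised at the natural values then satisfy the
    occlusion/de-occlusion balance exactly at t = 0, and the organic pools
    decay at their mineralization e-folding rates."""
    world = make_world(config, seed)
    n_years, n_cells = world.n_years, world.n_cells
    for k in world.climate:
        world.climate[k] = np.broadcast_to(
            world.climate[k][0], (n_years, n_cells)
        ).copy()
    world.landuse = LandUseState(
        fractions=np.broadcast_to(
            world.landuse.fractions[0], (n_years, 4, n_cells)
        ).copy(),
        transitions=np.zeros((n_years - 1, 4, 4, n_cells)),
    )
    world.n_manure = np.zeros_like(world.n_manure)
    world.n_chem_grass = np.zeros_like(world.n_chem_grass)
    world.p_chem_total = np.zeros_like(world.p_chem_total)
    world.npp_tot = np.zeros_like(world.npp_tot)
    world.gi = np.zeros_like(world.gi)
    world.deposition = {k: np.zeros(n_cells) for k in world.deposition}
    world.erosion_loss = np.zeros_like(world.erosion_loss)
    world.country_table = CountryTable(
        world.country_table.frame.assign(
            value=np.where(
                world.country_table.frame["variable"] == "manure_p",
                0.0,
                world.country_table.frame["value"],
            )
        )
    )
    for crop in world.crops:
        world.crop_yield_map_2000[crop.name] = np.zeros(n_cells)
        world.crop_area_map_2000[crop.name] = np.zeros(n_cells)
    for cid in np.unique(world.country_id):
        world.sludge_excretion[cid] = ((1970, 2010), (0.0, 0.0))
    world.validate()
    return world
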