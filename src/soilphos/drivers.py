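"""Annual P input/output reconstruction from driver data.

Each function turns one driver (manure, chemical fertilizer, plant uptake
and residues, atmospheric deposition, sewage sludge, water erosion) into
per-cell annual P fluxes in kgP ha^-1 yr^-1 on the cropland or grassland
fraction.  Country-scale bookkeeping (manure rescaling, FAO-style yield and
area series, sludge budgets) follows the same recipes as the gridded global
reconstruction the package emulates: gridded proxy fields give the spatial
pattern, country tables pin the national totals, and fixed stoichiometric
ratios convert nitrogen or biomass to phosphorus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameterization import SoilProperties

__all__ = [
    "CountryTable",
    "GrassParameters",
    "CropParameters",
    "CompositionFractions",
    "manure_forcing",
    "fertilizer_forcing",
    "grassland_plant_forcing",
    "crop_yield_area_series",
    "cropland_plant_forcing",
    "split_composition",
    "deposition_forcing",
    "sludge_forcing",
    "erosion_fraction",
    "MANURE_P_TO_N",
    "FERTILIZER_P_TO_N",
    "NPP_SCALE_FIELD_TO_MODEL",
    "SLUDGE_REMOVAL_EFFICIENCY",
]

logger = logging.getLogger(__name__)

#: P:N mass ratio of manure reaching the soil (kgP kgN^-1).
MANURE_P_TO_N = 0.20
#: P:N mass ratio of chemical fertilizer applied to grassland.
FERTILIZER_P_TO_N = 0.22
#: Global-mean grassland NPP ratio, field-derived over model-derived
#: (979 / 460 gC m^-2 yr^-1); the "sun_scaled" NPP estimate.
NPP_SCALE_FIELD_TO_MODEL = 979.0 / 460.0
#: P removal efficiency of wastewater-treatment installation types 1-3.
SLUDGE_REMOVAL_EFFICIENCY = (0.10, 0.45, 0.90)


class CountryTable:
    """Long-format country time series: (country, year, variable, value)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"country", "year", "variable", "value"}
        if not required.issubset(frame.columns):
            raise ValueError(f"country table needs columns {sorted(required)}")
        if (frame["value"] < 0).any():
            raise ValueError("country table values must be non-negative")
        self.frame = frame.reset_index(drop=True)

    def series(self, country, variable) -> pd.Series:
        sel = self.frame[
            (self.frame["country"] == country) & (self.frame["variable"] == variable)
        ]
        return sel.set_index("year")["value"].sort_index()

    def value(self, country, variable, year) -> float:
        s = self.series(country, variable)
        if year not in s.index:
            raise KeyError(f"{variable!r} missing for country {country} year {year}")
        return float(s.loc[year])

    def countries(self):
        return sorted(self.frame["country"].unique())


@dataclass
class GrassParameters:
    """Stoichiometric and turnover constants of the grassland P budget."""

    gamma: float = 0.45          # kgC per kgDM
    dry: float = 0.20            # kgDM per kgFM
    p_pct_above: float = 8.8e-2  # gP per 100 gFM, mean of the two bounds
    p_pct_above_bounds: tuple = (2.5e-2, 1.5e-1)
    lifespan_above: float = 0.8  # yr
    lifespan_below: float = 0.7  # yr
    season_length: float = 1.0   # yr
    npp_below_share: float = 0.54

    @property
    def p_pct_below(self) -> float:
        return 0.5 * self.p_pct_above


@dataclass
class CropParameters:
    """Per-crop constants; concentrations in gP (100 gFM)^-1."""

    name: str
    p_pct_harvest: float
    p_pct_abov_ex_harvest: float
    harvest_index: float
    frac_above: float
    is_forage: bool = False
    is_root_crop: bool = False

    def __post_init__(self):
        if not (0.0 < self.harvest_index <= 1.0):
            raise ValueError("harvest index must be positive and <= 1")
        if not (0.0 < self.frac_above <= 1.0):
            raise ValueError("frac_above must be in (0, 1]")

    @property
    def p_pct_root(self) -> float:
        return 0.75 * self.p_pct_abov_ex_harvest

    @property
    def root_shoot_ratio(self) -> float:
        return 1.0 / self.frac_above - 1.0

    @property
    def frac_resid(self) -> float:
        return 0.0 if self.is_forage else 0.5


@dataclass
class CompositionFractions:
    """Pool split of manure, residue and sludge P inputs."""

    manure_i_lab: float = 0.8
    manure_o_lab: float = 0.1
    residues_i_lab: float = 0.4
    residues_o_lab: float = 0.4

    def __post_init__(self):
        for a, b in ((self.manure_i_lab, self.manure_o_lab),
                     (self.residues_i_lab, self.residues_o_lab)):
            if min(a, b) < 0 or a + b > 1.0:
                raise ValueError("composition fractions must lie in [0,1] and sum <= 1")

    @property
    def manure(self):
        return (self.manure_i_lab, self.manure_o_lab,
                1.0 - self.manure_i_lab - self.manure_o_lab)

    @property
    def residues(self):
        return (self.residues_i_lab, self.residues_o_lab,
                1.0 - self.residues_i_lab - self.residues_o_lab)

    @property
    def sludge(self):
        return self.manure


# ---------------------------------------------------------------------------
# manure and fertilizer

def manure_forcing(
    n_manure,
    country_id,
    mode="estimate1",
    pn_ratio=MANURE_P_TO_N,
    country_table: CountryTable | None = None,
    landuse_frac=None,
    land_area=None,
    years=None,
    window=(1950, 2017),
):
    """P in manure reaching the soil, kgP ha^-1 yr^-1.

    Parameters
    ----------
    n_manure : array (year, lu, cell)
        N in manure reaching the soil (kgN ha^-1 yr^-1) for cropland and
        grassland.
    country_id : int array (cell,)
        Country of each cell; every cell must be assigned (>= 0).
    mode : "estimate1" | "estimate2"
        estimate1 converts N with the fixed P:N ratio; estimate2 rescales
        estimate1 so that its country mean over ``window`` matches the
        country-scale manure production table (variable "manure_p", kgP
        yr^-1, cropland+grassland pooled).
    landuse_frac, land_area, years
        Needed for estimate2: cover fractions (year, lu, cell), cell land
        area (ha) and the year labels of axis 0.
    """
    n_manure = np.asarray(n_manure, dtype=float)
    country_id = np.asarray(country_id)
    if np.any(country_id < 0):
        raise ValueError("cell without country assignment")
    est1 = pn_ratio * n_manure
    if mode == "estimate1":
        return est1
    if mode != "estimate2":
        raise ValueError(f"unknown manure mode {mode!r}")
    if country_table is None or landuse_frac is None or land_area is None or years is None:
        raise ValueError("estimate2 needs country_table, landuse_frac, land_area, years")

    years = np.asarray(years)
    in_window = (years >= window[0]) & (years <= window[1])
    if not np.any(in_window):
        logger.warning(
            "rescaling window %s does not overlap the run years; using all years",
            window,
        )
        in_window = np.ones(len(years), dtype=bool)
    landuse_frac = np.asarray(landuse_frac, dtype=float)
    land_area = np.asarray(land_area, dtype=float)
    # country totals of estimate1 (kgP yr^-1), cropland+grassland pooled
    per_cell = (est1[in_window] * landuse_frac[in_window] * land_area).sum(axis=1)
    out = est1.copy()
    for cid in np.unique(country_id):
        cells = country_id == cid
        est1_mean = per_cell[:, cells].sum(axis=1).mean()
        table_mean = (
            country_table.series(cid, "manure_p")
            .loc[window[0]: window[1]]
            .mean()
        )
        if est1_mean <= 0:
            if table_mean > 0:
                logger.warning(
                    "country %s has zero estimate-1 manure over the rescaling "
                    "window; estimate 2 set to 0", cid
                )
            out[:, :, cells] = 0.0
        else:
            out[:, :, cells] *= table_mean / est1_mean
    return out


def fertilizer_forcing(n_chem_grass, p_chem_total, frac_crop, frac_grass):
    """Chemical-fertilizer P split between grassland and cropland.

    Grassland P is the fixed P:N ratio times grassland N fertilizer; the
    total-P field (which books all chemical P to cropland) is corrected by
    subtracting the grassland share, per unit cropland area.  Returns
    ``(chem_crop, chem_grass)`` in kgP ha^-1 yr^-1.
    """
    n_chem_grass = np.asarray(n_chem_grass, dtype=float)
    p_chem_total = np.asarray(p_chem_total, dtype=float)
    frac_crop = np.asarray(frac_crop, dtype=float)
    frac_grass = np.asarray(frac_grass, dtype=float)
    chem_grass = FERTILIZER_P_TO_N * n_chem_grass
    with np.errstate(divide="ignore", invalid="ignore"):
        crop = (p_chem_total * frac_crop - chem_grass * frac_grass) / frac_crop
    chem_crop = np.where(frac_crop > 0, np.maximum(crop, 0.0), 0.0)
    return chem_crop, chem_grass


# ---------------------------------------------------------------------------
# grassland plant budget

def grassland_plant_forcing(
    npp_tot, gi, params: GrassParameters | None = None, npp_mode="kastner",
    p_pct_above=None,
):
    """Grassland P uptake and residue return from NPP and grazing intensity.

    ``npp_tot`` is total (above+below) NPP in kgC ha^-1 yr^-1; ``gi`` the
    human-appropriated share of it.  Returns ``(uptake, residues_total)``
    in kgP ha^-1 yr^-1 with ``residues = (1 - gi) * uptake``.
    """
    if params is None:
        params = GrassParameters()
    npp_tot = np.asarray(npp_tot, dtype=float)
    gi = np.asarray(gi, dtype=float)
    if np.any((gi < 0) | (gi > 1)):
        raise ValueError("grazing intensity must lie in [0, 1]")
    if npp_mode == "sun_scaled":
        npp_tot = npp_tot * NPP_SCALE_FIELD_TO_MODEL
    elif npp_mode != "kastner":
        raise ValueError(f"unknown npp_mode {npp_mode!r}")
    p_above = params.p_pct_above if p_pct_above is None else p_pct_above
    npp_below = params.npp_below_share * npp_tot
    npp_above = (1.0 - params.npp_below_share) * npp_tot
    uptake = (1.0 / params.gamma) * (1.0 / params.dry) * (
        (np.asarray(p_above) / 100.0)
        * (params.lifespan_above / params.season_length)
        * npp_above
        + (0.5 * np.asarray(p_above) / 100.0)
        * (params.lifespan_below / params.season_length)
        * npp_below
    )
    residues = (1.0 - gi) * uptake
    return uptake, residues


# ---------------------------------------------------------------------------
# cropland plant budget

def crop_yield_area_series(
    yield_map_2000,
    area_map_2000,
    country_yield,
    country_area,
    population,
    country_id,
    years,
    ref_year=2000,
    pop_anchor_year=1961,
):
    """Extend year-2000 per-crop yield/area maps through time.

    The reference-year map carries the spatial pattern; the country series
    carries the temporal evolution relative to the reference year.  Before
    ``pop_anchor_year`` the yield follows the national population and the
    harvested area is frozen at the anchor-year value.

    Parameters
    ----------
    yield_map_2000, area_map_2000 : array (cell,)
    country_yield, country_area, population : pd.Series per country
        Mappings ``country -> pd.Series(year -> value)``.
    Returns ``(yield_series, area_series)`` arrays of shape (year, cell).
    """
    years = np.asarray(years)
    yield_map_2000 = np.asarray(yield_map_2000, dtype=float)
    area_map_2000 = np.asarray(area_map_2000, dtype=float)
    country_id = np.asarray(country_id)
    n_cells = yield_map_2000.shape[-1]
    out_yield = np.zeros((len(years), n_cells))
    out_area = np.zeros((len(years), n_cells))

    for cid in np.unique(country_id):
        cells = country_id == cid
        ys = country_yield[cid]
        ar = country_area[cid]
        pop = population[cid]
        for s, label in ((ys, "yield"), (ar, "area")):
            if ref_year not in s.index:
                raise KeyError(f"reference year {ref_year} missing in {label} series of country {cid}")
        y_ref = float(ys.loc[ref_year])
        a_ref = float(ar.loc[ref_year])
        if y_ref == 0 or a_ref == 0:
            logger.warning(
                "country %s has zero reference-year yield/area; series set to 0", cid
            )
            continue
        y_anchor = float(ys.loc[pop_anchor_year]) if pop_anchor_year in ys.index else None
        a_anchor = float(ar.loc[pop_anchor_year]) if pop_anchor_year in ar.index else None
        pop_anchor = float(pop.loc[pop_anchor_year]) if pop_anchor_year in pop.index else None
        for k, y in enumerate(years):
            if y >= pop_anchor_year:
                yv = float(ys.loc[y])
                av = float(ar.loc[y])
            else:
                if y_anchor is None or pop_anchor is None or a_anchor is None:
                    raise KeyError(
                        f"anchor year {pop_anchor_year} missing for country {cid}"
                    )
                yv = y_anchor * float(pop.loc[y]) / pop_anchor
                av = a_anchor
            out_yield[k, cells] = yield_map_2000[cells] * yv / y_ref
            out_area[k, cells] = area_map_2000[cells] * av / a_ref
    return out_yield, out_area


def _per_crop_uptake_residues(yield_fm, crop: CropParameters):
    """P uptake and residue return of one crop, kgP ha^-1 yr^-1.

    At harvest all organs share the same dry-matter proportion, so the dry
    ratios cancel.  For a root crop the harvested organ is the root: the
    harvest index applies to root biomass, the residue fraction to the
    aboveground biomass, and the non-harvested root stays in the soil.
    """
    y = np.asarray(yield_fm, dtype=float) / 100.0
    hi = crop.harvest_index
    rsr = crop.root_shoot_ratio
    if crop.is_root_crop:
        if rsr <= 0:
            raise ValueError(f"root crop {crop.name} needs frac_above < 1")
        above_per_harvest = 1.0 / (hi * rsr)
        root_left_per_harvest = 1.0 / hi - 1.0
        uptake = y * (
            crop.p_pct_abov_ex_harvest * above_per_harvest
            + crop.p_pct_root * root_left_per_harvest
            + crop.p_pct_harvest
        )
        residues = y * (
            crop.p_pct_root * root_left_per_harvest
            + crop.frac_resid * crop.p_pct_abov_ex_harvest * above_per_harvest
        )
    else:
        uptake = y * (
            crop.p_pct_root * rsr / hi
            + crop.p_pct_abov_ex_harvest * (1.0 / hi - 1.0)
            + crop.p_pct_harvest
        )
        residues = y * (
            crop.p_pct_root * rsr / hi
            + crop.frac_resid * crop.p_pct_abov_ex_harvest * (1.0 / hi - 1.0)
        )
    return uptake, residues


def cropland_plant_forcing(yields, areas, crops):
    """Area-weighted aggregate P uptake and residues over crops.

    ``yields``/``areas`` map crop name -> array (..., cell); cells (or
    cell-years) with zero total harvested area get zero forcing.
    Returns ``(uptake, residues_total)``.
    """
    if not crops:
        raise ValueError("need at least one crop")
    total_area = sum(np.asarray(areas[c.name], dtype=float) for c in crops)
    up_w = 0.0
    re_w = 0.0
    for crop in crops:
        u, r = _per_crop_uptake_residues(yields[crop.name], crop)
        a = np.asarray(areas[crop.name], dtype=float)
        up_w = up_w + a * u
        re_w = re_w + a * r
    with np.errstate(divide="ignore", invalid="ignore"):
        uptake = np.where(total_area > 0, up_w / np.where(total_area > 0, total_area, 1.0), 0.0)
        residues = np.where(total_area > 0, re_w / np.where(total_area > 0, total_area, 1.0), 0.0)
    return uptake, residues


# ---------------------------------------------------------------------------
# composition, deposition, sludge, erosion

def split_composition(total, fractions):
    """Split a source total into (i_lab, o_lab, o_sta) pool inputs; the
    three parts sum exactly to the total."""
    total = np.asarray(total, dtype=float)
    f_ilab, f_olab, _ = fractions
    to_ilab = f_ilab * total
    to_olab = f_olab * total
    # remainder keeps the sum exact; guard the 1-ulp negative when the two
    # sampled fractions add to ~1
    to_osta = np.maximum(total - to_ilab - to_olab, 0.0)
    return to_ilab, to_olab, to_osta


def deposition_forcing(
    components: dict,
    years,
    anth_emissions_a: pd.Series | None = None,
    anth_emissions_b: pd.Series | None = None,
    frac_lab_dust=0.1,
    frac_lab_other=0.5,
):
    """Atmospheric P deposition split into labile and primary-pool inputs.

    ``components`` maps {"dust", "seasalt", "pbap", "natcomb", "anthcomb"}
    to static per-cell deposition (kgP ha^-1 yr^-1).  Only the
    anthropogenic-combustion part varies in time: it is scaled each year by
    the emission series normalised to its own mean; a second, later series
    is spliced on with a single multiplicative correction so that the two
    agree on average over their overlap years.  Returns arrays
    ``(to_ilab, to_iprim)`` of shape (year, cell).
    """
    years = np.asarray(years)
    comp = {k: np.asarray(v, dtype=float) for k, v in components.items()}
    for k, v in comp.items():
        if np.any(v < 0):
            raise ValueError(f"negative deposition component {k}")
    anth = comp.get("anthcomb", 0.0)
    static_other = sum(
        comp.get(k, 0.0) for k in ("seasalt", "pbap", "natcomb")
    )
    dust = comp.get("dust", 0.0)

    if anth_emissions_a is not None:
        ea = anth_emissions_a.sort_index()
        scale_a = ea / ea.mean()
        if anth_emissions_b is not None:
            eb = anth_emissions_b.sort_index()
            overlap = ea.index.intersection(eb.index)
            if len(overlap) == 0:
                raise ValueError("emission series share no overlap years for the splice")
            eb = eb * (ea.loc[overlap].mean() / eb.loc[overlap].mean())
            scale_b = eb / ea.mean()
        else:
            scale_b = None
        scales = np.empty(len(years))
        for k, y in enumerate(years):
            if y in scale_a.index:
                scales[k] = scale_a.loc[y]
            elif scale_b is not None and y in scale_b.index:
                scales[k] = scale_b.loc[y]
            elif y < scale_a.index[0]:
                scales[k] = scale_a.iloc[0]
            else:
                src = scale_b if scale_b is not None else scale_a
                scales[k] = src.iloc[-1]
    else:
        scales = np.ones(len(years))

    cell_shape = np.broadcast_shapes(
        *(np.shape(v) for v in comp.values())
    ) if comp else ()
    to_ilab = np.empty((len(years),) + cell_shape)
    to_iprim = np.empty((len(years),) + cell_shape)
    for k in range(len(years)):
        anth_y = anth * scales[k]
        other = static_other + anth_y
        to_ilab[k] = frac_lab_dust * dust + frac_lab_other * other
        to_iprim[k] = (1.0 - frac_lab_dust) * dust + (1.0 - frac_lab_other) * other
    return to_ilab, to_iprim


def _interp_held(years, anchor_years, anchor_values):
    """Linear interpolation between anchors, constant outside their span."""
    return np.interp(np.asarray(years, dtype=float),
                     np.asarray(anchor_years, dtype=float),
                     np.asarray(anchor_values, dtype=float))


def sludge_forcing(
    population,
    excretion_rate,
    treat_fractions,
    crop_area_country,
    years,
    removal=SLUDGE_REMOVAL_EFFICIENCY,
):
    """P in treated sewage sludge spread on cropland, kgP ha^-1 yr^-1.

    Per country and year: sum over installation types of
    ``frac_treat * NR`` times the per-capita excretion times the population,
    divided by the national cropland area.  Excretion rates and treatment
    fractions are given at anchor years (1970/2010-style) and linearly
    interpolated, held constant outside.  Returns a dict country -> array
    over ``years``.
    """
    years = np.asarray(years)
    out = {}
    for cid, pop in population.items():
        exc_anchor_years, exc_anchor_vals = excretion_rate[cid]
        exc = _interp_held(years, exc_anchor_years, exc_anchor_vals)
        fr_years, fr_vals = treat_fractions[cid]  # fr_vals shape (n_anchor, 3)
        fr_vals = np.asarray(fr_vals, dtype=float)
        if np.any((fr_vals < 0) | (fr_vals > 1)):
            raise ValueError("treatment fractions must lie in [0, 1]")
        eff = np.zeros(len(years))
        for t in range(3):
            eff += _interp_held(years, fr_years, fr_vals[:, t]) * removal[t]
        area = np.asarray([crop_area_country[cid](y) if callable(crop_area_country[cid])
                           else crop_area_country[cid].loc[y] for y in years], dtype=float)
        popv = np.asarray([pop.loc[y] for y in years], dtype=float)
        total = eff * exc * popv
        flux = np.zeros(len(years))
        ok = area > 0
        flux[ok] = total[ok] / area[ok]
        if np.any(~ok & (total > 0)):
            logger.warning(
                "country %s has sludge P but zero cropland area; forcing set to 0", cid
            )
        out[cid] = flux
    return out


def erosion_fraction(gross_loss, soil: SoilProperties):
    """Fraction of the 0-0.3 m soil mass lost to water erosion per year.

    ``gross_loss`` in kg soil ha^-1 yr^-1; capped at 1 yr^-1.
    """
    gross_loss = np.asarray(gross_loss, dtype=float)
    if np.any(gross_loss < 0):
        raise ValueError("gross soil loss must be >= 0")
    mass = soil.bulk_density * (1.0 - soil.coarse_frag_frac) * soil.depth * 1e4
    return np.minimum(gross_loss / mass, 1.0)
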