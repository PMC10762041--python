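"""Unit conversions and rank-based map comparison utilities.

Simulated pools live in kgP ha^-1 for the 0-0.3 m layer while soil-test
datasets report concentrations (mgP per kg soil) from assorted extraction
protocols; these helpers convert between the two, translate Olsen-P into
Colwell-P equivalents, and compare spatial fields on the rank scale
(decile maps plus Spearman correlation), which is robust to the protocol
differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ArealConversionContext",
    "concentration_to_areal",
    "areal_to_concentration",
    "olsen_colwell_convert",
    "decile_rank_compare",
    "grid_average_sites",
]

#: Olsen-P -> Colwell-P linear forms (slope, intercept) per soil class.
OLSEN_TO_COLWELL = {
    "non_calcareous": (2.869, -2.93),
    "calcareous": (1.376, 8.80),
}


@dataclass
class ArealConversionContext:
    """Soil-mass bookkeeping of the 0-0.3 m layer for one or many cells."""

    bulk_density: np.ndarray   # kg fine earth m^-3
    coarse_frag_frac: np.ndarray
    depth: float = 0.3

    def __post_init__(self):
        self.bulk_density = np.asarray(self.bulk_density, dtype=float)
        self.coarse_frag_frac = np.asarray(self.coarse_frag_frac, dtype=float)
        if np.any(self.bulk_density <= 0):
            raise ValueError("bulk density must be positive")
        if np.any((self.coarse_frag_frac < 0) | (self.coarse_frag_frac >= 1)):
            raise ValueError("coarse fragment fraction must be in [0, 1)")

    @property
    def factor(self) -> np.ndarray:
        """mgP kg^-1 -> kgP ha^-1 multiplier."""
        return self.bulk_density * (1.0 - self.coarse_frag_frac) * self.depth * 1e4 * 1e-6


def concentration_to_areal(conc_mg_per_kg, ctx: ArealConversionContext):
    """mgP (kg soil)^-1 -> kgP ha^-1 over the context's layer."""
    conc = np.asarray(conc_mg_per_kg, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be >= 0")
    return conc * ctx.factor


def areal_to_concentration(areal_kg_per_ha, ctx: ArealConversionContext):
    """Exact inverse of :func:`concentration_to_areal`."""
    areal = np.asarray(areal_kg_per_ha, dtype=float)
    if np.any(areal < 0):
        raise ValueError("areal amount must be >= 0")
    return areal / ctx.factor


def olsen_colwell_convert(olsen_value, soil_class="non_calcareous"):
    """Olsen-P to Colwell-P using the class-specific linear form."""
    try:
        slope, intercept = OLSEN_TO_COLWELL[soil_class]
    except KeyError:
        raise ValueError(f"unknown soil class {soil_class!r}") from None
    return slope * np.asarray(olsen_value, dtype=float) + intercept


def decile_rank_compare(map_a, map_b, mask=None):
    """Decile maps and the Spearman rank correlation of two fields.

    Decile labels 1-10 are assigned by empirical quantiles over the
    unmasked cells (ties resolved by average ranks, so detection-limit
    plateaus share a label); the correlation is computed on the raw values.
    Returns ``(decile_a, decile_b, rho)`` with masked cells set to 0 in the
    decile maps.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    valid = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    n = int(valid.sum())
    if n < 10:
        raise ValueError(f"need at least 10 unmasked cells, got {n}")

    def deciles(values):
        ranks = stats.rankdata(values, method="average")
        return np.ceil(ranks / len(values) * 10).astype(int)

    dec_a = np.zeros(a.shape, dtype=int)
    dec_b = np.zeros(b.shape, dtype=int)
    dec_a[valid] = deciles(a[valid])
    dec_b[valid] = deciles(b[valid])
    rho = float(stats.spearmanr(a[valid], b[valid]).statistic)
    return dec_a, dec_b, rho


def grid_average_sites(
    sites: pd.DataFrame,
    lon_edges,
    lat_edges,
    value_col: str = "value",
    landcover_col: str = "landcover",
):
    """Average point measurements onto a regular grid, per land cover.

    ``sites`` needs columns (lon, lat, landcover, value).  Returns a dict
    ``landcover -> 2-D array (lat, lon)`` with NaN where a cell holds no
    site; sites outside the grid are dropped.
    """
    lon_edges = np.asarray(lon_edges, dtype=float)
    lat_edges = np.asarray(lat_edges, dtype=float)
    out = {}
    for lc, group in sites.groupby(landcover_col):
        sums = np.zeros((len(lat_edges) - 1, len(lon_edges) - 1))
        counts = np.zeros_like(sums)
        ix = np.searchsorted(lon_edges, group["lon"].to_numpy(), side="right") - 1
        iy = np.searchsorted(lat_edges, group["lat"].to_numpy(), side="right") - 1
        ok = (ix >= 0) & (ix < sums.shape[1]) & (iy >= 0) & (iy < sums.shape[0])
        np.add.at(sums, (iy[ok], ix[ok]), group[value_col].to_numpy()[ok])
        np.add.at(counts, (iy[ok], ix[ok]), 1.0)
        with np.errstate(invalid="ignore"):
            out[lc] = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    return out
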