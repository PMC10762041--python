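"""Land-cover bookkeeping and pool mixing under land-use transitions.

Four covers are tracked per cell: cropland, grassland, non-agricultural
vegetation and urban land.  Only cropland and grassland pools are simulated;
non-agricultural land always carries the natural-soil pools and urban land
carries none.  When area converts between covers during a year, the
receiving cover's pools become the area-weighted mix of the retained and
incoming soil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import POOLS, PoolState
from .parameterization import NaturalPools

__all__ = [
    "LANDUSE_CATEGORIES",
    "RAW_CATEGORY_MAP",
    "LandUseState",
    "aggregate_landuse",
    "apply_lucc",
    "initialize_pools",
    "natural_pool_state",
]

LANDUSE_CATEGORIES = ("crop", "grass", "nonagri", "urban")

#: Aggregation from the harmonised raw land-use classes.
RAW_CATEGORY_MAP = {
    "c3ann": "crop",
    "c3nfx": "crop",
    "c3per": "crop",
    "c4ann": "crop",
    "c4per": "crop",
    "pastr": "grass",
    "range": "grass",
    "primf": "nonagri",
    "primn": "nonagri",
    "secdf": "nonagri",
    "secdn": "nonagri",
    "urban": "urban",
}


@dataclass
class LandUseState:
    """Cover fractions and transitions for a run.

    fractions : array (n_years, 4, n_cells) ordered as LANDUSE_CATEGORIES.
    transitions : array (n_years - 1, 4, 4, n_cells);
        ``transitions[y, i, j]`` is the cell fraction converted from cover
        ``j`` to cover ``i`` during year ``y`` (between fraction snapshots
        y and y+1).
    """

    fractions: np.ndarray
    transitions: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        f, d = self.fractions, self.transitions
        if f.ndim != 3 or f.shape[1] != 4:
            raise ValueError("fractions must have shape (years, 4, cells)")
        if d.ndim != 4 or d.shape[1:3] != (4, 4) or d.shape[0] != f.shape[0] - 1:
            raise ValueError("transitions must have shape (years-1, 4, 4, cells)")
        if np.any((f < -atol) | (f > 1 + atol)):
            raise ValueError("cover fractions outside [0, 1]")
        if np.any(f.sum(axis=1) > 1 + atol):
            raise ValueError("cover fractions sum above 1")
        if np.any(d < -atol):
            raise ValueError("negative transition")
        outgoing = d.sum(axis=1) - np.einsum("yiic->yic", d)  # off-diagonal out of j
        if np.any(outgoing > f[:-1] + atol):
            raise ValueError("transitions exceed the source cover fraction")
        # fraction-consistency identity between successive snapshots
        incoming = d.sum(axis=2) - np.einsum("yiic->yic", d)
        expected = f[:-1] - outgoing + incoming
        if np.any(np.abs(expected - f[1:]) > atol):
            raise ValueError("fractions inconsistent with transitions")


def aggregate_landuse(raw_fractions: dict, raw_transitions: dict) -> LandUseState:
    """Aggregate raw 12-class fractions/transitions to the four covers.

    ``raw_fractions`` maps raw class -> array (years, cells);
    ``raw_transitions`` maps (to_class, from_class) -> array (years-1, cells).
    """
    for k in raw_fractions:
        if k not in RAW_CATEGORY_MAP:
            raise ValueError(f"unknown land-use category {k!r}")
    for to_k, from_k in raw_transitions:
        if to_k not in RAW_CATEGORY_MAP or from_k not in RAW_CATEGORY_MAP:
            raise ValueError(f"unknown land-use category in transition {(to_k, from_k)!r}")

    some = next(iter(raw_fractions.values()))
    n_years, n_cells = np.asarray(some).shape
    fractions = np.zeros((n_years, 4, n_cells))
    for k, v in raw_fractions.items():
        fractions[:, LANDUSE_CATEGORIES.index(RAW_CATEGORY_MAP[k])] += np.asarray(v, dtype=float)

    transitions = np.zeros((n_years - 1, 4, 4, n_cells))
    for (to_k, from_k), v in raw_transitions.items():
        i = LANDUSE_CATEGORIES.index(RAW_CATEGORY_MAP[to_k])
        j = LANDUSE_CATEGORIES.index(RAW_CATEGORY_MAP[from_k])
        if i != j:  # intra-cover conversions do not move soil between covers
            transitions[:, i, j] += np.asarray(v, dtype=float)
    return LandUseState(fractions=fractions, transitions=transitions)


def natural_pool_state(natural: NaturalPools, p_c_inf, w_abs_mean) -> PoolState:
    """Pools of unmanaged soil with the solution pool at its steady value."""
    p_c_inf = np.asarray(p_c_inf, dtype=float)
    w_abs_mean = np.asarray(w_abs_mean, dtype=float)
    shape = np.broadcast_shapes(
        np.shape(natural.i_lab), np.shape(p_c_inf), np.shape(w_abs_mean)
    )
    return PoolState(
        i_sol=np.broadcast_to(p_c_inf * w_abs_mean, shape).copy(),
        i_lab=np.broadcast_to(natural.i_lab, shape).copy(),
        i_sec=np.broadcast_to(natural.i_sec, shape).copy(),
        i_prim=np.broadcast_to(natural.i_prim, shape).copy(),
        o_lab=np.broadcast_to(natural.o_lab, shape).copy(),
        o_sta=np.broadcast_to(natural.o_sta, shape).copy(),
        x_occ=np.broadcast_to(natural.x_occ, shape).copy(),
    )


def initialize_pools(natural: NaturalPools, p_c_inf, w_abs_mean):
    """Initial cropland and grassland pools: both inherit the natural soil."""
    return (
        natural_pool_state(natural, p_c_inf, w_abs_mean),
        natural_pool_state(natural, p_c_inf, w_abs_mean),
    )


def apply_lucc(
    pools_by_lu: dict,
    frac_prev: np.ndarray,
    frac_new: np.ndarray,
    transitions: np.ndarray,
    natural_state: PoolState,
    atol: float = 1e-9,
) -> dict:
    """Mix cropland/grassland pools across one year of transitions.

    ``pools_by_lu`` maps "crop"/"grass" to PoolState (leading batch axes
    allowed, trailing axis = cells); ``frac_prev``/``frac_new`` are the
    cover fractions (4, cells) before/after, ``transitions`` the (4, 4,
    cells) matrix of that year.  Non-agricultural source area injects the
    natural-soil pools; urban source area injects zero.  Covers whose new
    fraction is zero store zero pools by convention.
    """
    transitions = np.asarray(transitions, dtype=float)
    if np.any(transitions < -atol):
        raise ValueError("negative transition")
    outgoing = transitions.sum(axis=0) - np.diagonal(transitions, axis1=0, axis2=1).T
    if np.any(outgoing > np.asarray(frac_prev) + atol):
        raise ValueError("transitions exceed the source cover fraction")

    zero = PoolState.zeros(natural_state.i_sol.shape)
    source_pools = {
        "crop": pools_by_lu["crop"],
        "grass": pools_by_lu["grass"],
        "nonagri": natural_state,
        "urban": zero,
    }
    out = {}
    for lu in ("crop", "grass"):
        i = LANDUSE_CATEGORIES.index(lu)
        retained = frac_prev[i] - outgoing[i]
        new_frac = frac_new[i]
        mixed = PoolState.zeros(np.broadcast_shapes(
            getattr(pools_by_lu[lu], "i_lab").shape, np.shape(new_frac)
        ))
        for p in POOLS:
            amount = retained * getattr(pools_by_lu[lu], p)
            for j, src in enumerate(LANDUSE_CATEGORIES):
                if j == i:
                    continue
                delta = transitions[i, j]
                amount = amount + delta * getattr(source_pools[src], p)
            with np.errstate(divide="ignore", invalid="ignore"):
                value = np.where(new_frac > 0, amount / np.where(new_frac > 0, new_frac, 1.0), 0.0)
            setattr(mixed, p, np.maximum(value, 0.0))
        out[lu] = mixed
    return out
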