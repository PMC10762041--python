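"""Cell-level flux parameters for the soil phosphorus dynamics model.

The exchange rates between the inorganic pools (solution, labile, secondary,
occluded) are pedotransfer functions of soil properties, the mean annual
near-surface air temperature and the steady-state partitioning of the
natural-soil P pools.  Rates are built once per cell and kept constant in
time; the steady-state partitioning is taken from the natural (unmanaged)
soil pools, with the solution pool pinned to a prescribed steady-state
solution concentration ``p_c_inf`` times the long-term mean soil water
content.

Units: pools in mgP (kg soil)^-1, water in L (kg soil)^-1, rates in day^-1
except the two Freundlich sorption coefficients ``k_sol_to_lab`` and
``k_sol_to_sec`` which carry mgP kg^-1 day^-1 (mgP/L)^-b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "SoilProperties",
    "NaturalPools",
    "SteadyStateFractions",
    "FluxParameters",
    "ParamConfig",
    "MINERALIZATION_PRESETS",
    "steady_state_fractions",
    "build_flux_parameters",
    "check_parameter_consistency",
]

logger = logging.getLogger(__name__)

#: (k_min_stable, k_min_labile) in day^-1.  "v1.0" keeps the historical
#: residence times (100 yr, 10 yr); "v1.1" shortens them (15 yr, 2 yr) so
#: that grassland pools stabilise early in the simulated century.
MINERALIZATION_PRESETS = {
    "v1.0": (2.7e-5, 2.7e-4),
    "v1.1": (1.8e-4, 1.4e-3),
}

#: Apatite weathering rate (day^-1).
DEFAULT_K_WEATHERING = 2.7e-7

#: Steady-state solution P concentration (mgP L^-1).
DEFAULT_P_C_INF = 0.1

#: Floor for the desorption rate when the linear pedotransfer regression
#: goes non-positive (day^-1); a non-positive rate makes the
#: solution-labile equilibrium ill-posed.
K_LAB_TO_SOL_FLOOR = 1e-6

POOL_NAMES = ("i_sol", "i_lab", "i_sec", "i_prim", "o_lab", "o_sta", "x_occ")


def _asarray(x):
    return np.asarray(x, dtype=float)


@dataclass
class SoilProperties:
    """Static soil properties of one or many cells (arrays broadcast)."""

    sand_pct: np.ndarray
    clay_pct: np.ndarray
    silt_pct: np.ndarray
    ph_water: np.ndarray
    soil_carbon: np.ndarray  # gC (kg soil)^-1
    bulk_density: np.ndarray  # kg fine earth m^-3
    coarse_frag_frac: np.ndarray  # volumetric, 0-1
    depth: float = 0.3  # m, plough-layer thickness

    def __post_init__(self):
        for f in fields(self):
            if f.name == "depth":
                continue
            setattr(self, f.name, _asarray(getattr(self, f.name)))
        self.validate()

    def validate(self) -> None:
        tex = self.sand_pct + self.clay_pct + self.silt_pct
        if not np.all(np.isfinite(tex)):
            raise ValueError("non-finite soil texture")
        if np.any(np.abs(tex - 100.0) > 0.5):
            raise ValueError("sand+clay+silt must be within 100 +/- 0.5")
        for f in fields(self):
            v = getattr(self, f.name)
            if np.any(~np.isfinite(np.asarray(v, dtype=float))) or np.any(
                np.asarray(v, dtype=float) < 0
            ):
                raise ValueError(f"soil property {f.name} must be finite and non-negative")
        if np.any(self.ph_water < 2) or np.any(self.ph_water > 12):
            raise ValueError("pH outside [2, 12]")
        if np.any(self.coarse_frag_frac >= 1):
            raise ValueError("coarse fragment fraction must be < 1")

    @property
    def soil_mass_per_ha(self) -> np.ndarray:
        """Fine-earth mass of the 0-depth layer, kg (ha)^-1."""
        return self.bulk_density * (1.0 - self.coarse_frag_frac) * self.depth * 1e4

    @property
    def conc_to_areal(self) -> np.ndarray:
        """Multiplier from mgP (kg soil)^-1 to kgP ha^-1."""
        return self.soil_mass_per_ha * 1e-6


@dataclass
class NaturalPools:
    """Unmanaged-soil P pools (mgP per kg soil); the solution pool is
    derived from ``p_c_inf`` and the mean water content, never read."""

    i_lab: np.ndarray
    i_sec: np.ndarray
    i_prim: np.ndarray
    o_lab: np.ndarray
    o_sta: np.ndarray
    x_occ: np.ndarray

    def __post_init__(self):
        for f in fields(self):
            v = _asarray(getattr(self, f.name))
            if np.any(v < 0) or np.any(~np.isfinite(v)):
                raise ValueError(f"natural pool {f.name} must be finite and >= 0")
            setattr(self, f.name, v)


@dataclass
class SteadyStateFractions:
    """Steady-state partitioning of the inorganic non-primary pools."""

    f_i_sol: np.ndarray
    f_i_lab: np.ndarray
    f_i_sec: np.ndarray
    f_x_occ: np.ndarray
    p_itot_noprim_inf: np.ndarray  # mgP/kg, the normalising denominator
    p_otot_inf: np.ndarray  # mgP/kg, o_lab + o_sta at steady state

    def __post_init__(self):
        s = self.f_i_sol + self.f_i_lab + self.f_i_sec + self.f_x_occ
        if np.any(np.abs(s - 1.0) > 1e-12):
            raise ValueError("steady-state fractions must sum to 1")


@dataclass
class FluxParameters:
    """All rate constants plus the Freundlich exponent for one or many cells."""

    b: np.ndarray
    k_lab_to_sol: np.ndarray
    k_sol_to_lab: np.ndarray
    k_sol_to_sec: np.ndarray
    k_sec_to_sol: np.ndarray
    k_sec_to_occ: np.ndarray
    k_occ_to_sec: np.ndarray
    k_weathering: np.ndarray
    k_min_stable: np.ndarray
    k_min_labile: np.ndarray
    p_c_inf: np.ndarray
    w_abs_mean: np.ndarray

    def validate(self) -> None:
        for f in fields(self):
            v = np.asarray(getattr(self, f.name), dtype=float)
            if np.any(~np.isfinite(v)):
                raise ValueError(f"non-finite flux parameter {f.name}")
            if f.name != "p_c_inf" and np.any(v <= 0):
                raise ValueError(f"flux parameter {f.name} must be > 0")

    _RATE_FIELDS = (
        "k_lab_to_sol", "k_sol_to_lab", "k_sol_to_sec", "k_sec_to_sol",
        "k_sec_to_occ", "k_occ_to_sec", "k_weathering", "k_min_stable",
        "k_min_labile",
    )

    def scaled(self, step_ratio: float) -> "FluxParameters":
        """Parameters for a refined sub-daily step: every rate constant is
        multiplied by ``step_ratio`` (e.g. 0.5 for half-day steps) while
        the exponent, steady concentration and water content are unchanged.
        The solution-labile equilibrium is rate-ratio-invariant, so the
        redistribution is unaffected."""
        kwargs = {}
        for f in fields(self):
            v = np.asarray(getattr(self, f.name), dtype=float)
            kwargs[f.name] = v * step_ratio if f.name in self._RATE_FIELDS else v
        return FluxParameters(**kwargs)


@dataclass
class ParamConfig:
    """Knobs of the parameter construction."""

    p_c_inf: float = DEFAULT_P_C_INF
    mineralization_preset: str = "v1.1"
    k_weathering: float = DEFAULT_K_WEATHERING

    def mineralization_rates(self) -> tuple[float, float]:
        try:
            return MINERALIZATION_PRESETS[self.mineralization_preset]
        except KeyError:
            raise ValueError(
                f"unknown mineralization preset {self.mineralization_preset!r}"
            ) from None


def steady_state_fractions(
    natural: NaturalPools, w_abs_mean, p_c_inf=DEFAULT_P_C_INF
) -> SteadyStateFractions:
    """Steady-state pool fractions over {i_sol, i_lab, i_sec, x_occ}.

    The steady solution pool is ``p_c_inf * w_abs_mean`` (concentration times
    water content); the denominator excludes primary and organic pools.
    """
    w_abs_mean = _asarray(w_abs_mean)
    p_c_inf = _asarray(p_c_inf)
    if np.any(w_abs_mean <= 0):
        raise ValueError("w_abs_mean must be > 0")
    if np.any(p_c_inf < 0):
        raise ValueError("p_c_inf must be >= 0")
    i_sol_inf = p_c_inf * w_abs_mean
    denom = i_sol_inf + natural.i_lab + natural.i_sec + natural.x_occ
    if np.any(denom <= 0):
        raise ValueError("degenerate steady state: all four inorganic pools are zero")
    out = SteadyStateFractions(
        f_i_sol=i_sol_inf / denom,
        f_i_lab=natural.i_lab / denom,
        f_i_sec=natural.i_sec / denom,
        f_x_occ=natural.x_occ / denom,
        p_itot_noprim_inf=denom,
        p_otot_inf=natural.o_lab + natural.o_sta,
    )
    return out


def build_flux_parameters(
    soil: SoilProperties,
    frac: SteadyStateFractions,
    t_air_mean,
    w_abs_mean,
    config: ParamConfig | None = None,
) -> FluxParameters:
    """Evaluate the pedotransfer regressions and ratio identities.

    ``b``, ``k_lab_to_sol``, ``k_sol_to_sec`` and ``k_sec_to_occ`` come from
    the oxalate-free regressions; ``k_sol_to_lab``, ``k_sec_to_sol`` and
    ``k_occ_to_sec`` follow from the steady-state ratio identities so that
    the constructed parameter set is exactly consistent with the prescribed
    steady state.  Weathering and mineralization rates come from config.
    """
    if config is None:
        config = ParamConfig()
    t_air_mean = _asarray(t_air_mean)
    w_abs_mean = _asarray(w_abs_mean)
    p_c_inf = _asarray(config.p_c_inf)

    f_sol, f_lab = frac.f_i_sol, frac.f_i_lab
    f_sec, f_occ = frac.f_i_sec, frac.f_x_occ

    b = np.exp(-0.628 - 36.702 * f_sol + 1.102 * f_lab + 0.0024 * soil.sand_pct)

    k_lab_to_sol = (
        -4.82
        + 209.0 * f_sol
        + 14.64 * f_occ
        + 9.26 * f_sec
        - 0.008 * soil.soil_carbon
        - 0.0003 * frac.p_itot_noprim_inf
        - 0.018 * soil.silt_pct
    )
    n_floored = int(np.sum(k_lab_to_sol < K_LAB_TO_SOL_FLOOR))
    if n_floored:
        cells = np.flatnonzero(np.atleast_1d(k_lab_to_sol) < K_LAB_TO_SOL_FLOOR)
        logger.warning(
            "k_lab_to_sol regression non-positive for %d cell(s) %s; floored at %.0e day^-1",
            n_floored,
            cells[:20].tolist(),
            K_LAB_TO_SOL_FLOOR,
        )
        k_lab_to_sol = np.maximum(k_lab_to_sol, K_LAB_TO_SOL_FLOOR)

    k_sol_to_sec = np.exp(
        0.002
        + 4.0 * f_sec
        + 0.0008 * frac.p_otot_inf
        + 0.012 * soil.soil_carbon
        + 0.108 * t_air_mean
        - 0.0002 * frac.p_itot_noprim_inf
    )

    k_sec_to_occ = (
        3.68e-5
        + 9.60e-5 * f_occ
        - 1.47e-4 * f_sec
        + 1.22e-5 * soil.ph_water
        - 4.07e-7 * soil.clay_pct
        + 5.16e-8 * soil.soil_carbon
    )

    # Steady-state ratio identities (exact by construction).
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_core = w_abs_mean / (b * np.power(p_c_inf, b - 1.0) * f_sol)
    k_sol_to_lab = k_lab_to_sol * f_lab * ratio_core
    k_sec_to_sol = k_sol_to_sec / (f_sec * ratio_core)
    k_occ_to_sec = k_sec_to_occ * f_sec / f_occ

    k_min_stable, k_min_labile = config.mineralization_rates()
    shape = np.broadcast_shapes(
        np.shape(b), np.shape(k_lab_to_sol), np.shape(w_abs_mean), np.shape(k_sec_to_occ)
    )
    params = FluxParameters(
        b=b,
        k_lab_to_sol=k_lab_to_sol,
        k_sol_to_lab=k_sol_to_lab,
        k_sol_to_sec=k_sol_to_sec,
        k_sec_to_sol=k_sec_to_sol,
        k_sec_to_occ=k_sec_to_occ,
        k_occ_to_sec=k_occ_to_sec,
        k_weathering=np.broadcast_to(_asarray(config.k_weathering), shape).copy(),
        k_min_stable=np.broadcast_to(_asarray(k_min_stable), shape).copy(),
        k_min_labile=np.broadcast_to(_asarray(k_min_labile), shape).copy(),
        p_c_inf=np.broadcast_to(_asarray(config.p_c_inf), shape).copy(),
        w_abs_mean=np.broadcast_to(w_abs_mean, shape).copy(),
    )
    for f in fields(params):
        v = np.asarray(getattr(params, f.name), dtype=float)
        if np.any(~np.isfinite(v)):
            bad = np.flatnonzero(~np.isfinite(np.atleast_1d(v)))
            raise ValueError(
                f"non-finite regression result for {f.name} at cell(s) {bad[:20].tolist()}"
            )
    return params


@dataclass
class ConsistencyReport:
    """Flags for rate constants incompatible with a daily step.

    A gross outflow computed with a flagged rate can exceed the pool it
    leaves within one day, so the run relies on the net-flux clamp.
    """

    flag_k_sec_to_sol: np.ndarray
    flag_k_sol_to_sec: np.ndarray
    bound_k_sol_to_sec: np.ndarray
    n_flag_k_sec_to_sol: int = field(init=False)
    n_flag_k_sol_to_sec: int = field(init=False)

    def __post_init__(self):
        self.n_flag_k_sec_to_sol = int(np.sum(self.flag_k_sec_to_sol))
        self.n_flag_k_sol_to_sec = int(np.sum(self.flag_k_sol_to_sec))


def check_parameter_consistency(params: FluxParameters) -> ConsistencyReport:
    """Compare rates with the bounds that keep a pool's daily outflow below
    the pool size: 1 day^-1 for desorption from the secondary pool and
    ``w_abs_mean * p_c_inf**(1-b)`` for sorption out of the solution pool.
    Never mutates the parameters."""
    bound = params.w_abs_mean * np.power(params.p_c_inf, 1.0 - params.b)
    return ConsistencyReport(
        flag_k_sec_to_sol=np.asarray(params.k_sec_to_sol >= 1.0),
        flag_k_sol_to_sec=np.asarray(params.k_sol_to_sec >= bound),
        bound_k_sol_to_sec=np.asarray(bound),
    )
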