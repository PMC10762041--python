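import numpy as np
import pytest

from soilphos.core import UnitContext
from soilphos.parameterization import FluxParameters
from soilphos.synthetic import WorldConfig, make_world


@pytest.fixture(scope="session")
def tiny_world():
    """3x3 grid, 2 countries, 5 years: fast enough for pipeline tests."""
    return make_world(
        WorldConfig(nx=3, ny=3, n_countries=2, year_start=2000, year_end=2004),
        seed=11,
    )


@pytest.fixture
def unit_identity_ctx():
    """Unit context whose kgP/ha <-> mgP/kg factor is exactly 1
    (1600 kg/m3 * (1 - 0.75) * 0.25 m * 1e4 m2/ha * 1e-6 kg/mg)."""
    ctx = UnitContext(bulk_density=1600.0, coarse_frag_frac=0.75, depth=0.25)
    assert float(ctx.conc_to_areal) == 1.0
    return ctx


def make_params(**overrides) -> FluxParameters:
    """Hand-assembled flux parameters for unit tests (no regressions)."""
    values = dict(
        b=0.8,
        k_lab_to_sol=0.5,
        k_sol_to_lab=5.0,
        k_sol_to_sec=0.02,
        k_sec_to_sol=1e-3,
        k_sec_to_occ=1.6e-5,
        k_occ_to_sec=1.2e-5,
        k_weathering=2.7e-7,
        k_min_stable=1.8e-4,
        k_min_labile=1.4e-3,
        p_c_inf=0.1,
        w_abs_mean=3.0,
    )
    values.update(overrides)
    return FluxParameters(**{k: np.asarray(v, dtype=float) for k, v in values.items()})
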