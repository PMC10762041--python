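import numpy as np
import pytest
from scipy.optimize import brentq

from soilphos.core import (
    POOLS,
    AnnualForcing,
    ClimateRecord,
    PoolState,
    apply_annual_io,
    daily_pool_update,
    integrate_year,
    response_scalars,
    solve_sol_lab_equilibrium,
)
from tests.conftest import make_params


def state(**kw):
    base = {p: 0.0 for p in POOLS}
    base.update(kw)
    return PoolState(**{k: np.asarray(v, dtype=float) for k, v in base.items()})


def climate(t_soil=12.0, w_rel=0.6, w_abs=3.0, t_air=12.0):
    return ClimateRecord(t_soil=np.asarray(t_soil), w_rel=np.asarray(w_rel),
                         w_abs=np.asarray(w_abs), t_air=np.asarray(t_air))


class TestResponseScalars:
    @pytest.mark.parametrize("t,expected", [(15.0, 1.0), (25.0, 2.4), (5.0, 1 / 2.4)])
    def test_weathering_q10(self, t, expected):
        assert float(response_scalars(t, 0.5)["g1"]) == pytest.approx(expected)

    def test_moisture_scalar_is_relative_water(self):
        assert float(response_scalars(10.0, 0.37)["g2"]) == 0.37

    def test_mineralization_q10_reference(self):
        s = response_scalars(30.0, 0.5)
        assert float(s["h1"]) == pytest.approx(1.0)
        assert float(response_scalars(20.0, 0.5)["h1"]) == pytest.approx(0.5)

    def test_moisture_quadratic_and_dry_clamp(self):
        # printed polynomial at saturation: -1.1 + 2.4 - 0.29 = 1.01
        assert float(response_scalars(10.0, 1.0)["h2"]) == pytest.approx(1.01)
        # below ~0.13 the quadratic is negative and must clamp to zero
        assert float(response_scalars(10.0, 0.05)["h2"]) == 0.0


class TestEquilibriumSolver:
    def test_empty_system(self):
        s, l = solve_sol_lab_equilibrium(0.0, make_params(), 3.0)
        assert float(s) == 0.0 and float(l) == 0.0

    def test_symmetric_linear_closed_form(self):
        # b=1, equal rates, unit water: P_sol = k_ls*W*T/(k_sl + k_ls*W) = 1
        p = make_params(b=1.0, k_sol_to_lab=2.0, k_lab_to_sol=2.0)
        s, l = solve_sol_lab_equilibrium(2.0, p, 1.0)
        assert float(s) == pytest.approx(1.0, abs=1e-12)
        assert float(l) == pytest.approx(1.0, abs=1e-12)

    def test_matches_scalar_bisection_oracle(self):
        p = make_params(b=0.5, k_sol_to_lab=2.0, k_lab_to_sol=1.0)
        s, _ = solve_sol_lab_equilibrium(10.0, p, 4.0)
        f = lambda x: 2.0 * x**0.5 + 1.0 * 4.0**0.5 * x - 1.0 * 4.0**0.5 * 10.0
        ref = brentq(f, 0.0, 10.0, xtol=1e-14)
        assert float(s) == pytest.approx(ref, abs=1e-8)

    def test_sum_preserved_and_residual_small(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            b = rng.uniform(0.2, 1.5)
            ksl = rng.uniform(1e-3, 20.0)
            kls = rng.uniform(1e-3, 5.0)
            w = rng.uniform(0.1, 5.0)
            total = rng.uniform(0.0, 200.0)
            p = make_params(b=b, k_sol_to_lab=ksl, k_lab_to_sol=kls)
            s, l = solve_sol_lab_equilibrium(total, p, w)
            assert float(s + l) == total
            assert 0.0 <= float(s) <= total
            resid = ksl * float(s) ** b + kls * w**b * float(s) - kls * w**b * total
            assert abs(resid) < 1e-10 * max(1.0, total)

    def test_rejects_negative_total(self):
        with pytest.raises(ValueError):
            solve_sol_lab_equilibrium(-1.0, make_params(), 3.0)


class TestDailyPoolUpdate:
    def test_frozen_dynamics(self):
        p = make_params(**{k: 0.0 for k in (
            "k_lab_to_sol", "k_sol_to_lab", "k_sol_to_sec", "k_sec_to_sol",
            "k_sec_to_occ", "k_occ_to_sec", "k_weathering", "k_min_stable",
            "k_min_labile")})
        st0 = state(i_sol=1.0, i_lab=50.0, i_sec=30.0, i_prim=200.0,
                    o_lab=60.0, o_sta=150.0, x_occ=20.0)
        st1, fluxes = daily_pool_update(st0, p, climate())
        for pool in POOLS:
            assert float(getattr(st1, pool)) == float(getattr(st0, pool))
        assert all(float(v) == 0.0 for v in fluxes.values())

    def test_occlusion_deocclusion_balance_at_steady_pools(self):
        # rates tied by the steady-state ratio: fluxes cancel at those pools
        p = make_params(k_sec_to_occ=1.6e-5, k_occ_to_sec=1.6e-5 * 100.0 / 250.0)
        st0 = state(i_sec=100.0, x_occ=250.0, i_sol=0.3, i_lab=50.0)
        _, fluxes = daily_pool_update(st0, p, climate())
        assert float(fluxes["occlusion"]) == pytest.approx(
            float(fluxes["deocclusion"]), rel=1e-12)

    def test_weathering_flux_arithmetic(self):
        p = make_params()
        st0 = state(i_prim=500.0, i_lab=10.0)
        clim = climate(t_soil=15.0, w_rel=1.0)  # g1 = g2 = 1
        _, fluxes = daily_pool_update(st0, p, clim)
        assert float(fluxes["weathering"]) == pytest.approx(2.7e-7 * 500.0, rel=1e-12)
        assert float(fluxes["weathering"]) == pytest.approx(1.35e-4, rel=1e-12)

    def test_total_p_conserved(self):
        p = make_params(k_sol_to_sec=12.6)  # deliberately clamp-triggering
        st0 = state(i_sol=0.5, i_lab=80.0, i_sec=40.0, i_prim=300.0,
                    o_lab=50.0, o_sta=120.0, x_occ=60.0)
        st = st0
        for _ in range(200):
            st, _ = daily_pool_update(st, p, climate())
            st.check_nonnegative()
        assert float(st.total) == pytest.approx(float(st0.total), rel=1e-12)

    def test_negative_pool_rejected(self):
        with pytest.raises(ValueError, match="negative pool"):
            daily_pool_update(state(i_lab=-1.0), make_params(), climate())


class TestApplyAnnualIO:
    def test_zero_forcing_is_identity(self, unit_identity_ctx):
        st0 = state(i_sol=0.3, i_lab=50.0, i_sec=30.0, o_lab=20.0)
        st1, upns, losses = apply_annual_io(st0, AnnualForcing(), unit_identity_ctx)
        for pool in POOLS:
            assert float(getattr(st1, pool)) == float(getattr(st0, pool))
        assert float(upns) == 0.0
        assert all(float(v) == 0.0 for v in losses.values())

    def test_shortfall_bookkeeping(self, unit_identity_ctx):
        st0 = state(i_sol=0.5, i_lab=4.5)
        forcing = AnnualForcing(uptake_from_ilab=8.0)
        st1, upns, _ = apply_annual_io(st0, forcing, unit_identity_ctx)
        assert float(st1.i_sol) == 0.0 and float(st1.i_lab) == 0.0
        assert float(upns) == pytest.approx(3.0, abs=1e-12)

    def test_manure_composition_split(self, unit_identity_ctx):
        from soilphos.drivers import CompositionFractions, split_composition

        ilab, olab, osta = split_composition(10.0, CompositionFractions().manure)
        forcing = AnnualForcing(manure_to_ilab=ilab, manure_to_olab=olab,
                                manure_to_osta=osta)
        st1, _, _ = apply_annual_io(state(), forcing, unit_identity_ctx)
        assert (float(st1.i_lab), float(st1.o_lab), float(st1.o_sta)) == (8.0, 1.0, 1.0)

    def test_erosion_spares_solution_pool(self, unit_identity_ctx):
        st0 = state(i_sol=2.0, i_lab=100.0, i_sec=50.0)
        forcing = AnnualForcing(erosion_frac_loss=0.01)
        st1, _, losses = apply_annual_io(st0, forcing, unit_identity_ctx)
        assert float(st1.i_sol) == 2.0
        assert float(st1.i_lab) == pytest.approx(99.0)
        assert float(losses["i_lab"]) == pytest.approx(1.0)
        assert float(losses["i_sol"]) == 0.0


class TestIntegrateYear:
    def test_zero_forcing_zero_rates_identity(self, unit_identity_ctx):
        p = make_params(**{k: 0.0 for k in (
            "k_lab_to_sol", "k_sol_to_lab", "k_sol_to_sec", "k_sec_to_sol",
            "k_sec_to_occ", "k_occ_to_sec", "k_weathering", "k_min_stable",
            "k_min_labile")})
        st0 = state(i_lab=50.0, o_sta=100.0)
        st1, diag = integrate_year(st0, p, climate(), AnnualForcing(),
                                   unit_identity_ctx, n_days=30)
        assert float(st1.i_lab) == 50.0 and float(st1.o_sta) == 100.0
        assert float(np.max(np.abs(diag.mass_balance_residual()))) < 1e-12

    def test_organic_pools_decay_exponentially(self, unit_identity_ctx):
        p = make_params()
        st0 = state(o_lab=100.0, o_sta=200.0)
        clim = climate(t_soil=20.0, w_rel=0.6)
        s = response_scalars(clim.t_soil, clim.w_rel)
        st1, _ = integrate_year(st0, p, clim, AnnualForcing(), unit_identity_ctx)
        # discrete daily decay: (1 - k h1 h2)^365 ~ exp(-k h1 h2 * 365)
        rate = float(p.k_min_labile * s["h1"] * s["h2"])
        assert float(st1.o_lab) / 100.0 == pytest.approx(
            np.exp(-rate * 365.0), rel=2e-2)
        assert float(st1.o_lab) / 100.0 == pytest.approx((1 - rate) ** 365, rel=1e-10)

    def test_mass_balance_closes_on_random_forcing(self, unit_identity_ctx):
        rng = np.random.default_rng(5)
        p = make_params()
        st0 = state(i_sol=0.3, i_lab=60.0, i_sec=40.0, i_prim=250.0,
                    o_lab=40.0, o_sta=90.0, x_occ=70.0)
        forcing = AnnualForcing(
            chem_to_ilab=rng.uniform(0, 30), manure_to_ilab=rng.uniform(0, 10),
            manure_to_olab=rng.uniform(0, 2), manure_to_osta=rng.uniform(0, 2),
            residues_to_ilab=rng.uniform(0, 5), residues_to_olab=rng.uniform(0, 5),
            residues_to_osta=rng.uniform(0, 3), depo_to_ilab=rng.uniform(0, 0.5),
            depo_to_iprim=rng.uniform(0, 0.5), uptake_from_ilab=rng.uniform(0, 25),
            erosion_frac_loss=rng.uniform(0, 1e-3),
        )
        _, diag = integrate_year(st0, p, climate(), forcing, unit_identity_ctx)
        scale = max(1.0, float(st0.total))
        assert float(np.max(np.abs(diag.mass_balance_residual()))) < 1e-9 * scale
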