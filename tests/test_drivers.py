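import numpy as np
import pandas as pd
import pytest

from soilphos.drivers import (
    CompositionFractions,
    CountryTable,
    CropParameters,
    GrassParameters,
    cropland_plant_forcing,
    crop_yield_area_series,
    deposition_forcing,
    erosion_fraction,
    fertilizer_forcing,
    grassland_plant_forcing,
    manure_forcing,
    sludge_forcing,
    split_composition,
)
from soilphos.parameterization import SoilProperties


class TestManure:
    def test_fixed_p_to_n_ratio(self):
        n = np.full((1, 2, 3), 10.0)
        out = manure_forcing(n, country_id=np.zeros(3, dtype=int))
        np.testing.assert_allclose(out, 2.0)

    def test_zero_nitrogen_gives_zero_everywhere(self):
        n = np.zeros((2, 2, 4))
        out = manure_forcing(n, country_id=np.zeros(4, dtype=int))
        assert not out.any()

    def test_estimate2_rescales_to_country_table(self):
        years = np.array([1990, 1991])
        n = np.full((2, 2, 4), 10.0)  # estimate1 = 2 kgP/ha everywhere
        frac = np.full((2, 2, 4), 0.25)
        area = np.full(4, 100.0)
        cid = np.zeros(4, dtype=int)
        # estimate1 country total per year: 2 * 0.25 * 100 * 4 cells * 2 lus = 400
        table = CountryTable(pd.DataFrame({
            "country": 0, "year": years, "variable": "manure_p", "value": 800.0,
        }))
        out = manure_forcing(n, cid, mode="estimate2", country_table=table,
                             landuse_frac=frac, land_area=area, years=years,
                             window=(1950, 2017))
        np.testing.assert_allclose(out, 4.0)  # doubled everywhere

    def test_estimate2_country_mean_matches_table_by_construction(self):
        rng = np.random.default_rng(2)
        years = np.arange(1995, 2005)
        n = rng.uniform(0, 30, (10, 2, 6))
        frac = rng.uniform(0.1, 0.4, (10, 2, 6))
        area = np.full(6, 50.0)
        cid = np.array([0, 0, 0, 1, 1, 1])
        rows = []
        for c in (0, 1):
            for y in years:
                rows.append((c, y, "manure_p", rng.uniform(100, 1000)))
        table = CountryTable(pd.DataFrame(rows, columns=["country", "year",
                                                         "variable", "value"]))
        out = manure_forcing(n, cid, mode="estimate2", country_table=table,
                             landuse_frac=frac, land_area=area, years=years)
        for c in (0, 1):
            cells = cid == c
            total = (out[:, :, cells] * frac[:, :, cells] * area[cells]).sum(axis=(1, 2))
            assert total.mean() == pytest.approx(
                table.series(c, "manure_p").mean(), rel=1e-12)

    def test_unassigned_cell_raises(self):
        with pytest.raises(ValueError, match="country"):
            manure_forcing(np.zeros((1, 2, 2)), country_id=np.array([0, -1]))


class TestFertilizer:
    def test_grass_p_to_n_ratio(self):
        crop, grass = fertilizer_forcing(10.0, 0.0, 0.5, 0.25)
        assert np.asarray(grass).item() == pytest.approx(2.2)

    def test_cropland_correction_arithmetic(self):
        crop, grass = fertilizer_forcing(1.0 / 0.22, 5.0, 0.5, 0.25)
        assert np.asarray(grass).item() == pytest.approx(1.0)
        assert np.asarray(crop).item() == pytest.approx((2.5 - 0.25) / 0.5)

    def test_no_grassland_means_total_goes_to_cropland(self):
        crop, _ = fertilizer_forcing(0.0, 7.0, 0.4, 0.0)
        assert np.asarray(crop).item() == pytest.approx(7.0)

    def test_zero_cropland_fraction(self):
        crop, _ = fertilizer_forcing(0.0, 7.0, 0.0, 0.3)
        assert np.asarray(crop).item() == 0.0


class TestGrasslandPlants:
    def test_npp_split_below_share(self):
        p = GrassParameters()
        assert p.npp_below_share == 0.54

    def test_uptake_arithmetic(self):
        # npp chosen so npp_above = 2000, npp_below = 2348 (share 0.54)
        p = GrassParameters(p_pct_above=8.8e-2, npp_below_share=2348 / 4348)
        uptake, _ = grassland_plant_forcing(4348.0, 0.0, p)
        expected = (1 / 0.45) * (1 / 0.20) * (
            8.8e-4 * 0.8 * 2000 + 4.4e-4 * 0.7 * 2348
        )
        assert np.asarray(uptake).item() == pytest.approx(expected, rel=1e-12)
        assert np.asarray(uptake).item() == pytest.approx(23.68, rel=1e-2)

    def test_full_appropriation_leaves_no_residues(self):
        _, residues = grassland_plant_forcing(3000.0, 1.0)
        assert np.asarray(residues).item() == 0.0

    def test_field_scaled_npp_mode(self):
        u1, _ = grassland_plant_forcing(1000.0, 0.0, npp_mode="kastner")
        u2, _ = grassland_plant_forcing(1000.0, 0.0, npp_mode="sun_scaled")
        assert np.asarray(u2 / u1).item() == pytest.approx(979.0 / 460.0)

    def test_below_concentration_is_half_above(self):
        assert GrassParameters(p_pct_above=0.1).p_pct_below == pytest.approx(0.05)


def _country_series(values_by_year):
    return pd.Series(values_by_year).sort_index()


class TestCropSeries:
    def setup_method(self):
        self.years = np.array([1950, 1961, 1980, 2000])
        self.map_yield = np.array([4000.0, 6000.0])
        self.map_area = np.array([100.0, 200.0])
        self.cy = {0: _country_series({1961: 2.0, 1980: 3.0, 2000: 4.0})}
        self.ca = {0: _country_series({1961: 50.0, 1980: 60.0, 2000: 80.0})}
        self.pop = {0: _country_series({1950: 0.8e6, 1961: 1e6, 1980: 2e6, 2000: 3e6})}
        self.cid = np.zeros(2, dtype=int)

    def run(self):
        return crop_yield_area_series(self.map_yield, self.map_area, self.cy,
                                      self.ca, self.pop, self.cid, self.years)

    def test_reference_year_reproduces_map(self):
        y, a = self.run()
        np.testing.assert_allclose(y[-1], self.map_yield)
        np.testing.assert_allclose(a[-1], self.map_area)

    def test_pre_anchor_yield_scales_with_population(self):
        y, _ = self.run()
        # 1950 yield = 1961 yield * pop(1950)/pop(1961)
        np.testing.assert_allclose(y[0], y[1] * 0.8, rtol=1e-12)

    def test_pre_anchor_area_held_constant(self):
        _, a = self.run()
        np.testing.assert_allclose(a[0], a[1])

    def test_missing_reference_year_raises(self):
        self.cy = {0: _country_series({1961: 2.0, 1980: 3.0})}
        with pytest.raises(KeyError, match="reference year"):
            self.run()


class TestCroplandPlants:
    def test_root_shoot_ratio_from_aboveground_fraction(self):
        crop = CropParameters("c", 0.3, 0.1, harvest_index=0.5, frac_above=0.8)
        assert crop.root_shoot_ratio == pytest.approx(0.25)

    def test_uptake_arithmetic(self):
        crop = CropParameters("c", p_pct_harvest=0.3, p_pct_abov_ex_harvest=0.1,
                              harvest_index=0.5, frac_above=1 / 1.2)
        assert crop.root_shoot_ratio == pytest.approx(0.2)
        assert crop.p_pct_root == pytest.approx(0.075)
        uptake, _ = cropland_plant_forcing(
            {"c": np.array([5000.0])}, {"c": np.array([10.0])}, [crop])
        expected = 50 * (0.075 * 0.2 / 0.5 + 0.1 * (1 / 0.5 - 1) + 0.3)
        assert np.asarray(uptake).item() == pytest.approx(expected, rel=1e-12)
        assert np.asarray(uptake).item() == pytest.approx(21.5, rel=1e-12)

    def test_forage_keeps_no_aboveground_residue(self):
        forage = CropParameters("f", 0.15, 0.15, 0.8, 0.8, is_forage=True)
        other = CropParameters("o", 0.15, 0.15, 0.8, 0.8)
        assert forage.frac_resid == 0.0
        assert other.frac_resid == 0.5

    def test_single_crop_reduces_to_per_crop_values(self):
        crop = CropParameters("c", 0.3, 0.1, 0.5, 0.8)
        y = {"c": np.array([3000.0, 6000.0])}
        a = {"c": np.array([10.0, 0.0])}
        uptake, residues = cropland_plant_forcing(y, a, [crop])
        # zero-area cell gets zero forcing; the other matches the crop alone
        assert np.asarray(uptake[1]).item() == 0.0 and np.asarray(residues[1]).item() == 0.0
        a2 = {"c": np.array([10.0, 5.0])}
        u2, _ = cropland_plant_forcing(y, a2, [crop])
        assert np.asarray(u2[0]).item() == pytest.approx(np.asarray(uptake[0]).item())

    def test_area_weighted_aggregation(self):
        c1 = CropParameters("c1", 0.3, 0.1, 0.5, 0.8)
        c2 = CropParameters("c2", 0.1, 0.05, 0.4, 0.9)
        y = {"c1": np.array([4000.0]), "c2": np.array([8000.0])}
        a = {"c1": np.array([30.0]), "c2": np.array([10.0])}
        u_both, _ = cropland_plant_forcing(y, a, [c1, c2])
        u1, _ = cropland_plant_forcing(y, {"c1": a["c1"], "c2": np.array([0.0])}, [c1, c2])
        u2, _ = cropland_plant_forcing(y, {"c1": np.array([0.0]), "c2": a["c2"]}, [c1, c2])
        assert np.asarray(u_both).item() == pytest.approx(0.75 * np.asarray(u1).item() + 0.25 * np.asarray(u2).item())

    def test_root_crop_residues_keep_unharvested_root(self):
        root = CropParameters("r", 0.06, 0.25, harvest_index=0.85, frac_above=0.6,
                              is_root_crop=True)
        y = {"r": np.array([20000.0])}
        a = {"r": np.array([5.0])}
        uptake, residues = cropland_plant_forcing(y, a, [root])
        hi, rsr = 0.85, 1 / 0.6 - 1
        exp_up = 200 * (0.25 / (hi * rsr) + 0.75 * 0.25 * (1 / hi - 1) + 0.06)
        exp_re = 200 * (0.75 * 0.25 * (1 / hi - 1) + 0.5 * 0.25 / (hi * rsr))
        assert np.asarray(uptake).item() == pytest.approx(exp_up, rel=1e-12)
        assert np.asarray(residues).item() == pytest.approx(exp_re, rel=1e-12)

    def test_zero_harvest_index_rejected(self):
        with pytest.raises(ValueError, match="harvest index"):
            CropParameters("bad", 0.3, 0.1, harvest_index=0.0, frac_above=0.8)


class TestComposition:
    @pytest.mark.parametrize("total,fracs,expected", [
        (10.0, "manure", (8.0, 1.0, 1.0)),
        (10.0, "residues", (4.0, 4.0, 2.0)),
        (0.0, "manure", (0.0, 0.0, 0.0)),
    ])
    def test_splits(self, total, fracs, expected):
        parts = split_composition(total, getattr(CompositionFractions(), fracs))
        assert tuple(np.asarray(v).item() for v in parts) == pytest.approx(expected)
        assert np.asarray(sum(parts)).item() == total

    def test_sludge_uses_manure_fractions(self):
        c = CompositionFractions()
        assert c.sludge == c.manure

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            CompositionFractions(manure_i_lab=0.9, manure_o_lab=0.3)


class TestDeposition:
    def test_dust_split(self):
        ilab, iprim = deposition_forcing({"dust": np.array([1.0])}, years=[2000])
        assert np.asarray(ilab).item() == pytest.approx(0.1)
        assert np.asarray(iprim).item() == pytest.approx(0.9)

    def test_dust_plus_seasalt(self):
        ilab, iprim = deposition_forcing(
            {"dust": np.array([1.0]), "seasalt": np.array([1.0])}, years=[2000])
        assert np.asarray(ilab).item() == pytest.approx(0.6)
        assert np.asarray(iprim).item() == pytest.approx(1.4)

    def test_all_zero(self):
        ilab, iprim = deposition_forcing(
            {k: np.array([0.0]) for k in ("dust", "seasalt", "pbap", "natcomb",
                                          "anthcomb")}, years=[1990, 2000])
        assert not ilab.any() and not iprim.any()

    def test_emission_splice_agrees_on_overlap_mean(self):
        a = pd.Series({1990: 1.0, 1995: 2.0, 2000: 3.0})
        b = pd.Series({1995: 4.0, 2000: 6.0, 2005: 8.0})
        comp = {"anthcomb": np.array([1.0])}
        ilab, _ = deposition_forcing(comp, years=[1995, 2000, 2005],
                                     anth_emissions_a=a, anth_emissions_b=b)
        # overlap years use series A directly; 2005 uses B scaled so that the
        # overlap means agree: factor = mean(2,3)/mean(4,6) = 0.5
        assert np.asarray(ilab[0]).item() == pytest.approx(0.5 * 2.0 / 2.0)
        assert np.asarray(ilab[2]).item() == pytest.approx(0.5 * (8.0 * 0.5) / 2.0)


class TestSludge:
    def test_removal_efficiencies_and_arithmetic(self):
        years = np.array([2000])
        pop = {0: pd.Series({2000: 1e6})}
        exc = {0: ((1970, 2010), (0.5, 0.5))}
        treat = {0: ((1970, 2010), np.array([[0.2, 0.3, 0.5], [0.2, 0.3, 0.5]]))}
        area = {0: pd.Series({2000: 1e5})}
        out = sludge_forcing(pop, exc, treat, area, years)
        expected = (0.2 * 0.10 + 0.3 * 0.45 + 0.5 * 0.90) * 0.5 * 1e6 / 1e5
        assert np.asarray(out[0][0]).item() == pytest.approx(expected, rel=1e-12)
        assert np.asarray(out[0][0]).item() == pytest.approx(3.025, rel=1e-12)

    def test_untreated_population_contributes_nothing(self):
        years = np.array([2000])
        pop = {0: pd.Series({2000: 1e6})}
        exc = {0: ((1970, 2010), (0.5, 0.5))}
        treat = {0: ((1970, 2010), np.zeros((2, 3)))}
        area = {0: pd.Series({2000: 1e5})}
        assert np.asarray(sludge_forcing(pop, exc, treat, area, years)[0][0]).item() == 0.0

    def test_interpolation_held_outside_anchors(self):
        years = np.array([1960, 1990, 2020])
        pop = {0: pd.Series({1960: 1e6, 1990: 1e6, 2020: 1e6})}
        exc = {0: ((1970, 2010), (0.4, 0.6))}
        treat = {0: ((1970, 2010), np.array([[0.0, 0.0, 0.2], [0.0, 0.0, 0.4]]))}
        area = {0: pd.Series({1960: 1e5, 1990: 1e5, 2020: 1e5})}
        out = sludge_forcing(pop, exc, treat, area, years)[0]
        # 1960 uses the 1970 anchors, 2020 the 2010 anchors; 1990 interpolates
        assert np.asarray(out[0]).item() == pytest.approx(0.2 * 0.9 * 0.4 * 10.0)
        assert np.asarray(out[2]).item() == pytest.approx(0.4 * 0.9 * 0.6 * 10.0)
        assert np.asarray(out[1]).item() == pytest.approx(0.3 * 0.9 * 0.5 * 10.0)


class TestErosion:
    def soil(self):
        return SoilProperties(sand_pct=40.0, clay_pct=30.0, silt_pct=30.0,
                              ph_water=6.5, soil_carbon=15.0, bulk_density=1300.0,
                              coarse_frag_frac=0.1)

    def test_mass_fraction_arithmetic(self):
        frac = erosion_fraction(2000.0, self.soil())
        assert np.asarray(frac).item() == pytest.approx(2000.0 / 3.51e6, rel=1e-12)

    def test_zero_loss(self):
        assert float(erosion_fraction(0.0, self.soil())) == 0.0

    def test_capped_at_total_soil_mass(self):
        assert float(erosion_fraction(1e12, self.soil())) == 1.0
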