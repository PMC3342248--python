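"""Biomass estimators: allometry, snags, shrubs, debris, fuels, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

import standforge as sf
from standforge.allometry import (
    AllometricEquation,
    DecayDensityTable,
    DiameterRangeError,
    EquationRegistry,
    FuelClassCoefficients,
    FuelCoefficients,
    K_INTERCEPT,
    PoolEstimate,
    SubstitutionRule,
    UnresolvedSpeciesError,
    aggregate_report,
    coarse_debris_biomass,
    fine_fuel_biomass,
    frustum_volume_m3,
    litter_duff_biomass,
    rmse_to_sd,
    shrub_extrapolate,
    snag_biomass,
    tree_biomass,
)
from standforge.stand_model import (
    CoarseIntercept,
    FuelTransect,
    PlotGeometry,
    ShrubDemographyPlot,
    SnagRecord,
    StemRecord,
)


def flat_density(rho: float) -> DecayDensityTable:
    return DecayDensityTable({"default": {c: rho for c in range(1, 6)}})


class TestTreeBiomass:
    def test_log10_linear_evaluation_matches_hand_formula(self):
        reg = EquationRegistry([AllometricEquation(
            "X", "whole", "log10_linear", (-2.0, 2.4), 1.0, 300.0)])
        tb = tree_biomass(StemRecord("t", "X", 50.0, 0, 0), reg)
        # independent evaluation: 10^(−2) · 50^2.4
        assert tb.total_kg == pytest.approx(10.0 ** -2 * 50.0 ** 2.4, rel=1e-12)
        assert tb.total_kg == pytest.approx(119.5364, rel=1e-4)

    def test_branch_and_foliage_capped_at_110cm(self, registry):
        def comps(dbh):
            return tree_biomass(StemRecord("t", "ABCO", dbh, 0, 0), registry)
        at_110, at_120 = comps(110.0), comps(120.0)
        for comp in ("branch", "foliage"):
            assert at_120.components_kg[comp] == at_110.components_kg[comp]
        assert at_120.components_kg["bole"] > at_110.components_kg["bole"]

    def test_bole_proxy_species_kicks_in_above_threshold(self, registry):
        # the largest white fir borrow a noble-fir bole equation
        below = tree_biomass(StemRecord("t", "ABCO", 149.0, 0, 0), registry)
        above = tree_biomass(StemRecord("t", "ABCO", 151.0, 0, 0), registry)
        assert above.components_kg["bole"] > below.components_kg["bole"]

    def test_dbh_below_all_ranges_is_a_range_error(self, registry):
        with pytest.raises(DiameterRangeError):
            tree_biomass(StemRecord("t", "ABCO", 0.5, 0, 0), registry)

    def test_unknown_species_without_rule_is_unresolved(self, registry):
        with pytest.raises(UnresolvedSpeciesError):
            tree_biomass(StemRecord("t", "ZZZZ", 20.0, 0, 0), registry)

    def test_total_is_sum_of_components(self, registry):
        tb = tree_biomass(StemRecord("t", "PILA", 80.0, 0, 0), registry)
        assert tb.total_kg == pytest.approx(sum(tb.components_kg.values()))
        assert set(tb.components_kg) == {"bole", "branch", "foliage"}

    @pytest.mark.parametrize("species", ["ABCO", "PILA", "CADE", "QUKE"])
    def test_monotone_in_dbh_within_range(self, registry, species):
        dbhs = np.linspace(1.5, 99.0, 40)
        totals = [tree_biomass(StemRecord("t", species, d, 0, 0), registry).total_kg
                  for d in dbhs]
        assert all(b >= a for a, b in zip(totals, totals[1:]))


class TestRmseToSd:
    def test_zero_rmse_gives_zero_sd(self):
        assert rmse_to_sd(1000.0, 0.0, 10.0) == 0.0

    def test_known_value_base10(self):
        # s=0.1 in log10: SD = 1000·sqrt(exp((0.1·ln10)²) − 1) ≈ 233.3 kg
        assert rmse_to_sd(1000.0, 0.1, 10.0) == pytest.approx(233.34, abs=0.5)

    def test_matches_lognormal_moment_simulation(self, rng):
        # draw a lognormal with arithmetic mean m̂ and log10-scale sd 0.1;
        # the sample SD must approach the closed-form value
        m_hat, s = 1000.0, 0.1
        sigma = s * math.log(10.0)
        draws = rng.lognormal(math.log(m_hat) - sigma**2 / 2, sigma, size=400_000)
        assert rmse_to_sd(m_hat, s, 10.0) == pytest.approx(draws.std(), rel=0.02)

    def test_strictly_increasing_in_rmse(self):
        sds = [rmse_to_sd(500.0, s, math.e) for s in (0.05, 0.1, 0.2, 0.4)]
        assert all(b > a for a, b in zip(sds, sds[1:]))


class TestSnagBiomass:
    def test_cylinder_and_cone_limits(self):
        assert frustum_volume_m3(100.0, 100.0, 10.0) == pytest.approx(
            math.pi * 0.5**2 * 10.0, rel=1e-12)
        assert frustum_volume_m3(100.0, 0.0, 10.0) == pytest.approx(
            math.pi * 0.5**2 * 10.0 / 3.0, rel=1e-12)

    def test_hand_calculated_frustum_mass(self):
        # dbh 100, top 50, h 20, ρ 360: V = π·20/3·0.4375 = 9.163 m³ → 3.299 Mg
        snag = SnagRecord("s", "UNKN", 100.0, 20.0, 50.0, 2, 0, 0)
        mass = snag_biomass(snag, flat_density(360.0))
        assert mass == pytest.approx(3.2987, abs=5e-4)

    def test_density_table_rejects_increasing_decay_density(self):
        with pytest.raises(ValueError):
            DecayDensityTable({"default": {1: 300, 2: 350, 3: 300, 4: 250, 5: 200}})


class TestShrubExtrapolate:
    GEOM = PlotGeometry(800.0, 320.0)
    DEM = [ShrubDemographyPlot("ARPA", 4.0, 5.333, 14.747),
           ShrubDemographyPlot("VAUL", 4.0, 0.083, 1.069)]

    def test_cover_times_density_over_area(self):
        table = shrub_extrapolate({"ARPA": 2524.0}, self.DEM, None, self.GEOM)
        assert table.loc["ARPA", "biomass_mg_per_ha"] == pytest.approx(
            2524.0 * 14.747 / 25.6 / 1000.0)
        assert round(table.loc["ARPA", "stems_per_ha"]) == 526

    def test_zero_cover_gives_zero(self):
        table = shrub_extrapolate({}, self.DEM, None, self.GEOM)
        assert table.loc["TOTAL", "biomass_mg_per_ha"] == 0.0

    def test_half_scale_proxy(self):
        proxies = {"RIRO": ("VAUL", 0.5)}
        table = shrub_extrapolate({"RIRO": 100.0, "VAUL": 100.0},
                                  self.DEM, proxies, self.GEOM)
        assert table.loc["RIRO", "biomass_mg_per_ha"] == pytest.approx(
            table.loc["VAUL", "biomass_mg_per_ha"] / 2.0)

    def test_unresolvable_species_is_reported(self):
        with pytest.raises(UnresolvedSpeciesError, match="CECO"):
            shrub_extrapolate({"CECO": 10.0}, self.DEM, None, self.GEOM)


def _transect(intercepts=(), **kw) -> FuelTransect:
    defaults = dict(transect_id="t", x_m=0.0, y_m=0.0, azimuth_deg=0.0,
                    length_m=20.0)
    defaults.update(kw)
    return FuelTransect(coarse_intercepts=tuple(intercepts), **defaults)


class TestCoarseDebris:
    def test_no_intercepts_gives_zero(self):
        total, large = coarse_debris_biomass([_transect()], flat_density(400.0))
        assert total.mean_mg_per_ha == 0.0 and large.mean_mg_per_ha == 0.0

    def test_single_intercept_hand_calculation(self):
        # d = 0.2 m on L = 20 m at 400 kg/m³: π²·0.04/160·400·10 = 9.8696 Mg/ha
        tr = _transect([CoarseIntercept(20.0, 1)])
        total, large = coarse_debris_biomass([tr], flat_density(400.0))
        assert total.mean_mg_per_ha == pytest.approx(9.8696, abs=1e-4)
        assert large.mean_mg_per_ha == 0.0

    def test_large_subset_splits_at_threshold(self):
        tr = _transect([CoarseIntercept(20.0, 1), CoarseIntercept(120.0, 1)])
        total, large = coarse_debris_biomass([tr], flat_density(400.0))
        assert 0.0 < large.mean_mg_per_ha < total.mean_mg_per_ha


class TestFineFuels:
    COEFFS = FuelCoefficients(
        class_1h=FuelClassCoefficients(0.31, 0.48),
        class_10h=FuelClassCoefficients(1.37, 0.48),
        class_100h=FuelClassCoefficients(4.22, 0.40),
    )

    def test_zero_counts_give_zero_everywhere(self):
        out = fine_fuel_biomass([_transect()], self.COEFFS)
        assert all(p.mean_mg_per_ha == 0.0 for p in out.values())

    def test_linearity_in_counts(self):
        one = fine_fuel_biomass([_transect(count_1h=5, count_10h=3,
                                           count_100h=2)], self.COEFFS)
        two = fine_fuel_biomass([_transect(count_1h=10, count_10h=6,
                                           count_100h=4)], self.COEFFS)
        for cls in one:
            assert two[cls].mean_mg_per_ha == pytest.approx(
                2.0 * one[cls].mean_mg_per_ha, rel=1e-12)

    def test_missing_coefficients_rejected(self):
        with pytest.raises(ValueError):
            fine_fuel_biomass([_transect()], None)


class TestLitterDuff:
    def test_zero_depth(self):
        assert litter_duff_biomass([0.0, 0.0], 125.2).mean_mg_per_ha == 0.0

    def test_calibrated_bulk_density_reproduces_expected_load(self):
        # 1.05 cm of litter at 125.2 kg/m³ → 13.15 Mg/ha
        est = litter_duff_biomass([1.05], 125.2)
        assert est.mean_mg_per_ha == pytest.approx(13.15, abs=5e-3)

    def test_linear_in_depth(self):
        a = litter_duff_biomass([1.0], 200.1).mean_mg_per_ha
        b = litter_duff_biomass([3.0], 200.1).mean_mg_per_ha
        assert b == pytest.approx(3.0 * a, rel=1e-12)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            litter_duff_biomass([-0.1], 125.2)


class TestAggregation:
    def test_empty_stand_gives_all_zero_report(self):
        zero = PoolEstimate(0.0, 0.0, 0)
        shrubs = shrub_extrapolate({}, [], None, PlotGeometry(100, 100))
        rep = aggregate_report([], [], zero, zero, shrubs,
                               {"1h": zero, "10h": zero, "100h": zero},
                               zero, zero, area_ha=1.0)
        assert rep.grand_total_mg_ha() == 0.0

    def test_pool_additivity_on_synthetic_stand(self, small_stand, registry,
                                                densities, fuel_coefficients):
        area = small_stand.geometry.area_ha
        live = [tree_biomass(s, registry) for s in small_stand.live_stems]
        snags = [(s, snag_biomass(s, densities)) for s in small_stand.snags]
        debris = coarse_debris_biomass(small_stand.transects, densities)
        shrubs = shrub_extrapolate(small_stand.shrub_patches,
                                   small_stand.demography,
                                   sf.allometry.DEFAULT_SHRUB_PROXIES,
                                   small_stand.geometry)
        fuels = fine_fuel_biomass(small_stand.transects, fuel_coefficients)
        litter = litter_duff_biomass(
            [t.litter_cm for t in small_stand.transects], 125.2)
        duff = litter_duff_biomass(
            [t.duff_cm for t in small_stand.transects], 200.1)
        rep = aggregate_report(live, snags, debris[0], debris[1], shrubs,
                               fuels, litter, duff, area)
        tot = rep.live_total
        # nested diameter classes and exact per-species additivity
        assert tot["bio_ge100"] <= tot["bio_ge10"] <= tot["bio_ge1"]
        assert tot["bio_ge1"] == pytest.approx(
            sum(tb.total_kg for tb in live) / 1000.0 / area, rel=1e-9)
        assert tot["sd_ge1"] == pytest.approx(
            sum(tb.sd_kg for tb in live) / 1000.0 / area, rel=1e-9)
        assert rep.grand_total_mg_ha() == pytest.approx(
            tot["bio_ge1"] + rep.snag_total["bio_ge10"]
            + rep.debris_total.mean_mg_per_ha + rep.shrub_total_mg_ha
            + rep.fine_fuel_total_mg_ha, rel=1e-12)
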