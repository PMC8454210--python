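"""Bioclimate derivations: pressure, daytime temperature, growing-season
aggregation, canopy light and Rubisco kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafopt import (SiteEnvironment, air_pressure, ambient_co2, canopy_light,
                     daytime_temperature, growing_season_stats,
                     rubisco_kinetics, viscosity_ratio)
from leafopt.bioclim import par_to_daily_mol
from leafopt.exceptions import DegenerateSiteError, PolarDayError


class TestAirPressure:
    def test_sea_level_reference(self):
        assert air_pressure(0.0) == pytest.approx(101.325, abs=1e-12)

    def test_high_elevation_fixture(self):
        # frozen from an independent hand evaluation of the barometric formula
        assert air_pressure(4361.0) == pytest.approx(58.7955941699108, rel=1e-10)

    def test_monotone_decreasing(self):
        z = np.linspace(-400, 6000, 100)
        assert np.all(np.diff(air_pressure(z)) < 0)

    def test_domain_floor(self):
        with pytest.raises(ValueError):
            air_pressure(-600.0)

    def test_ca_tracks_pressure(self):
        p = air_pressure(np.array([0.0, 2000.0, 4000.0]))
        ca = ambient_co2(p)
        assert np.all(np.diff(ca) < 0)
        assert ca[0] == pytest.approx(101.325e3 * 410e-6, rel=1e-12)


class TestDaytimeTemperature:
    def test_degenerate_cycle_returns_the_constant(self):
        assert daytime_temperature(12.0, 12.0, 45.0, 10.0) == pytest.approx(12.0)

    def test_equator_weights(self):
        # x = 0 forces weights 1/2 +- 1/pi
        expected = 20.0 * (0.5 + 1 / np.pi) + 10.0 * (0.5 - 1 / np.pi)
        assert daytime_temperature(20.0, 10.0, 0.0, 10.0) == pytest.approx(
            expected, rel=1e-12)

    def test_july_montane_fixture(self):
        # frozen from an independent one-line evaluation of the sine model
        assert daytime_temperature(18.0, 8.0, 29.6, 21.2) == pytest.approx(
            15.72014116585449, rel=1e-10)

    def test_polar_night_raises(self):
        with pytest.raises(PolarDayError):
            daytime_temperature(5.0, -5.0, 80.0, 23.4)

    def test_tmax_lt_tmin_rejected(self):
        with pytest.raises(ValueError):
            daytime_temperature(5.0, 6.0, 30.0, 10.0)

    @given(st.floats(-20, 40), st.floats(0, 15), st.floats(-5, 5))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_shift_invariance(self, tmin, spread, shift):
        """Adding c to both extremes adds c to the daytime mean."""
        base = daytime_temperature(tmin + spread, tmin, 29.6, 21.2)
        shifted = daytime_temperature(tmin + spread + shift, tmin + shift,
                                      29.6, 21.2)
        assert shifted == pytest.approx(base + shift, abs=1e-9)

    def test_bounded_by_extremes(self):
        t = daytime_temperature(18.0, 8.0, 29.6, 21.2)
        assert 8.0 <= t <= 18.0


class TestGrowingSeason:
    def test_all_days_warm(self):
        gs = growing_season_stats(np.full(365, 10.0))
        assert gs.tg == 10.0 and gs.f == 1.0

    def test_half_year_season(self):
        temps = np.concatenate([np.full(182, -5.0), np.full(182, 5.0)])
        gs = growing_season_stats(temps)
        assert gs.tg == pytest.approx(5.0) and gs.f == pytest.approx(0.5)

    def test_sinusoid_fixture(self):
        # frozen from an explicit day-by-day loop oracle
        days = 5.0 + 12.0 * np.sin(2 * np.pi * np.arange(365) / 365.0)
        gs = growing_season_stats(days)
        assert gs.tg == pytest.approx(10.472269124308488, rel=1e-12)
        assert gs.f == pytest.approx(0.6356164383561644, rel=1e-12)

    def test_empty_season_raises(self):
        with pytest.raises(DegenerateSiteError):
            growing_season_stats(np.full(365, -3.0))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_matches_day_loop_oracle(self, seed):
        """Vectorised means agree exactly with an explicit loop."""
        rng = np.random.default_rng(seed)
        temps = rng.normal(3.0, 8.0, 365)
        vpd = rng.uniform(0.1, 2.0, 365)
        if not np.any(temps > 0):
            temps[rng.integers(365)] = 1.0
        # brute-force oracle
        t_sum = d_sum = n = 0
        for t, d in zip(temps, vpd):
            if t > 0.0:
                t_sum, d_sum, n = t_sum + t, d_sum + d, n + 1
        gs = growing_season_stats(temps, vpd=vpd)
        assert gs.tg == pytest.approx(t_sum / n, rel=1e-12)
        assert gs.d0 == pytest.approx(d_sum / n, rel=1e-12)
        assert gs.f == pytest.approx(n / 365.0, rel=1e-12)


class TestCanopyLight:
    def test_zero_lai_limit(self):
        r_daily = par_to_daily_mol(400.0)
        assert canopy_light(400.0, 0.0) == pytest.approx(r_daily, rel=1e-12)

    def test_closed_form_attenuation(self):
        # LAI=2, k=0.5 -> (1 - e^-1) / 1
        expected = par_to_daily_mol(400.0) * (1.0 - np.exp(-1.0))
        assert canopy_light(400.0, 2.0, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_attenuation_decreasing_in_lai(self):
        lai = np.linspace(0.0, 8.0, 50)
        out = canopy_light(400.0, lai)
        assert np.all(np.diff(out) < 0)

    def test_cannot_create_light(self, sites):
        for s in sites:
            assert s.r_lai <= par_to_daily_mol(s.r0) + 1e-12

    def test_daily_conversion_round_trip(self):
        daily = par_to_daily_mol(400.0, daylight_hours=12.0)
        assert daily / (12.0 * 3600.0 * 1e-6) == pytest.approx(400.0, rel=1e-12)


class TestRubiscoKinetics:
    def test_reference_values_at_25C(self, constants):
        kin = rubisco_kinetics(25.0, 101.325, constants)
        assert kin.kc == pytest.approx(39.97, rel=1e-12)
        assert kin.ko == pytest.approx(27.48e3, rel=1e-12)
        assert kin.eta_rel == pytest.approx(1.0, rel=1e-12)
        assert kin.gammastar == pytest.approx(4.332, rel=1e-12)

    def test_effective_k_fixture(self, constants):
        # K = Kc (1 + Po/Ko) with Po = 0.2095 * 101325 Pa, frozen by hand
        kin = rubisco_kinetics(25.0, 101.325, constants)
        assert kin.k == pytest.approx(70.8457886599345, rel=1e-10)

    def test_cold_fixtures(self, constants):
        kin = rubisco_kinetics(10.0, 101.325, constants)
        assert kin.kc == pytest.approx(7.320005219993901, rel=1e-8)
        assert kin.gammastar == pytest.approx(1.9300676681089672, rel=1e-8)
        assert kin.k == pytest.approx(19.6241990301284, rel=1e-8)

    def test_viscosity_ratio_fixture(self):
        assert viscosity_ratio(10.0) == pytest.approx(1.4594339548530029,
                                                      rel=1e-10)

    def test_pressure_scaling(self, constants):
        full = rubisco_kinetics(18.0, 101.325, constants)
        half = rubisco_kinetics(18.0, 101.325 / 2, constants)
        assert half.po == pytest.approx(full.po / 2, rel=1e-12)
        assert half.gammastar == pytest.approx(full.gammastar / 2, rel=1e-12)
        assert half.k < full.k
        # substituting Po/2 into the full-pressure K reproduces half-pressure K
        assert half.k == pytest.approx(
            full.kc * (1 + full.po / 2 / full.ko), rel=1e-12)

    def test_extrapolation_warns(self, constants):
        with pytest.warns(UserWarning):
            rubisco_kinetics(50.0, 101.325, constants)


class TestSiteEnvironment:
    def test_derived_pressure_and_ca(self):
        site = SiteEnvironment("x", 2000.0, 29.6, 10.0, 14.0, 0.8, 400.0,
                               3.0, 10.0, 0.8, 0.7)
        assert site.patm == pytest.approx(float(air_pressure(2000.0)))
        assert site.ca == pytest.approx(float(ambient_co2(site.patm)))

    def test_invalid_f_rejected(self):
        with pytest.raises(ValueError):
            SiteEnvironment("x", 2000.0, 29.6, 10.0, 14.0, 0.8, 400.0,
                            3.0, 10.0, 1.4, 0.7)

    def test_with_elevation_recomputes(self):
        site = SiteEnvironment("x", 1000.0, 29.6, 10.0, 14.0, 0.8, 400.0,
                               3.0, 10.0, 0.8, 0.7)
        high = site.with_elevation(4000.0)
        assert high.patm < site.patm and high.ca < site.ca
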