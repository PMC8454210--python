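"""Optimality trait models: limits, frozen arithmetic fixtures, invariants."""

import numpy as np
import pytest

from leafopt import (PhysioConstants, SiteEnvironment, chi_from_isotope,
                     chi_optimal, delta13c_leaf, fv_instantaneous,
                     lma_deciduous, lma_theoretical, narea_simple,
                     narea_two_step, predict_site, rubisco_kinetics,
                     vcmax25_predicted, vcmax_coordination)
from leafopt.exceptions import PhysicalDomainError

SEA = 101.325


def _site(**kw):
    defaults = dict(site_id="ref", elevation=1500.0, latitude=29.6, tg=12.0,
                    tdj=16.0, d0=0.8, r0=420.0, lai=3.0, r_lai=9.0, f=0.85,
                    alpha_p=0.75)
    defaults.update(kw)
    return SiteEnvironment(**defaults)


class TestChiOptimal:
    def test_humid_limit(self):
        assert chi_optimal(25.0, 1e-10, SEA, 40.0) == pytest.approx(1.0, abs=1e-4)

    def test_arid_limit(self, constants):
        gamma = rubisco_kinetics(25.0, SEA, constants).gammastar
        assert chi_optimal(25.0, 1e9, SEA, 40.0) == pytest.approx(
            gamma / 40.0, abs=1e-3)

    def test_reference_fixture(self):
        # frozen from a line-by-line evaluation of the least-cost solution
        assert chi_optimal(25.0, 1.0, SEA, 40.0) == pytest.approx(
            0.7536165248978381, rel=1e-10)

    def test_decreasing_in_vpd(self):
        d0 = np.linspace(0.2, 4.0, 30)
        chi = chi_optimal(18.0, d0, SEA, 40.0)
        assert np.all(np.diff(chi) < 0)

    def test_bounds_on_grid(self, constants):
        for t in (2.0, 12.0, 25.0, 35.0):
            for d0 in (0.1, 0.7, 2.5):
                for patm in (60.0, 80.0, SEA):
                    ca = patm * 1000 * 410e-6
                    gamma = rubisco_kinetics(t, patm, constants).gammastar
                    chi = chi_optimal(t, d0, patm, ca)
                    assert gamma / ca < chi < 1.0

    def test_nonpositive_vpd_rejected(self):
        with pytest.raises(ValueError):
            chi_optimal(25.0, 0.0, SEA, 40.0)

    def test_inconsistent_site_rejected(self):
        with pytest.raises(PhysicalDomainError):
            chi_optimal(25.0, 1.0, SEA, 4.0)

    def test_pressure_only_perturbation_lowers_chi(self):
        """The direct elevation effect: lower pressure at fixed climate and
        CO2 mole fraction raises transpiration costs and lowers chi."""
        lo = chi_optimal(16.0, 0.8, 60.0, 60.0 * 1000 * 410e-6)
        hi = chi_optimal(16.0, 0.8, SEA, SEA * 1000 * 410e-6)
        assert lo < hi


class TestChiFromIsotope:
    def test_full_discrimination_endpoint(self, constants):
        # Delta = b' and a negligible photorespiration term give chi = 1
        d_leaf = (constants.d13c_air - 30.0) / (1 + 30.0 / 1000.0)
        res = chi_from_isotope(d_leaf, ca=1e12)
        assert res.chi == pytest.approx(1.0, abs=1e-9)

    def test_zero_discrimination_endpoint(self, constants):
        d_leaf = (constants.d13c_air - 4.4) / (1 + 4.4 / 1000.0)
        res = chi_from_isotope(d_leaf, ca=1e12)
        assert res.chi == pytest.approx(0.0, abs=1e-9)

    def test_reference_fixture(self):
        # Delta = 20 permil at 25 C, sea level, ca = 40 Pa; hand evaluated
        d_leaf = -27.45098039215686
        res = chi_from_isotope(d_leaf, d13c_air=-8.0, temperature=25.0,
                               patm=SEA, ca=40.0)
        assert res.chi == pytest.approx(0.6770624999999999, rel=1e-10)
        assert not res.flagged

    def test_out_of_range_flagged_not_clipped(self):
        d_leaf = (-8.0 - 35.0) / (1 + 35.0 / 1000.0)  # Delta = 35 permil
        res = chi_from_isotope(d_leaf, temperature=25.0, patm=SEA, ca=40.0)
        assert res.chi > 1.2 and res.flagged

    def test_round_trip_identity(self):
        rng = np.random.default_rng(11)
        chi = rng.uniform(0.2, 1.1, 200)
        d13c = delta13c_leaf(chi, 18.0, 80.0, 33.0)
        back = chi_from_isotope(d13c, temperature=18.0, patm=80.0, ca=33.0)
        np.testing.assert_allclose(back.chi, chi, rtol=1e-12)


class TestVcmaxCoordination:
    def test_dark_limit(self):
        assert vcmax_coordination(25.0, 0.0, 0.8, 40.0, SEA) == 0.0

    def test_linear_in_light(self):
        v1 = vcmax_coordination(25.0, 400.0, 0.8, 40.0, SEA)
        v2 = vcmax_coordination(25.0, 800.0, 0.8, 40.0, SEA)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_reference_fixture(self):
        # frozen from an independent evaluation of the coordination solution
        assert vcmax_coordination(25.0, 800.0, 0.8, 40.0, SEA) == pytest.approx(
            92.06821151968573, rel=1e-10)

    def test_low_ci_error_names_inequality(self):
        with pytest.raises(PhysicalDomainError, match="m ="):
            vcmax_coordination(25.0, 800.0, 0.15, 40.0, SEA)


class TestFvInstantaneous:
    def test_unity_at_reference(self):
        assert fv_instantaneous(25.0) == pytest.approx(1.0, abs=1e-15)

    def test_cold_fixture(self):
        assert fv_instantaneous(10.0) == pytest.approx(0.26094767475242675,
                                                       rel=1e-10)

    def test_monotone_through_reference(self):
        assert fv_instantaneous(15.0) < 1.0 < fv_instantaneous(30.0)


class TestVcmax25:
    def test_identity_at_25C(self):
        site = _site(tdj=25.0)
        chi = chi_optimal(25.0, site.d0, site.patm, site.ca)
        v = vcmax_coordination(25.0, site.r0, chi, site.ca, site.patm)
        assert vcmax25_predicted(site, chi) == pytest.approx(v, rel=1e-12)

    def test_positive_and_basis_switch(self):
        site = _site()
        v_tdj = vcmax25_predicted(site, temperature_basis="tdj")
        v_tg = vcmax25_predicted(site, temperature_basis="tg")
        assert v_tdj > 0 and v_tg > 0 and v_tdj != v_tg

    def test_pressure_only_perturbation_raises_vcmax25(self):
        site = _site()
        high = site.with_elevation(4000.0).replace(
            tg=site.tg, tdj=site.tdj, d0=site.d0, r0=site.r0)
        assert vcmax25_predicted(high) > vcmax25_predicted(site)


class TestLmaTheoretical:
    CHI = 0.7536165248978381  # least-cost chi at the standard conditions

    def test_proportional_to_longevity(self):
        m1 = lma_theoretical(20.0, 90.0, 25.0, 40.0, self.CHI, SEA)
        m2 = lma_theoretical(20.0, 180.0, 25.0, 40.0, self.CHI, SEA)
        assert m2 == pytest.approx(2 * m1, rel=1e-12)

    def test_reference_fixture(self):
        assert lma_theoretical(20.0, 180.0, 25.0, 40.0, self.CHI, SEA) == \
            pytest.approx(73.95771485968682, rel=1e-10)

    def test_light_elasticity_is_unity(self):
        """d ln Ma / d ln I_abs = 1 for the theoretical model (vs 1.22 for
        the fitted deciduous model — a documented difference)."""
        h = 1e-6
        lo = np.log(lma_theoretical(20.0 * (1 - h), 180.0, 25.0, 40.0,
                                    self.CHI, SEA))
        hi = np.log(lma_theoretical(20.0 * (1 + h), 180.0, 25.0, 40.0,
                                    self.CHI, SEA))
        elasticity = (hi - lo) / (2 * np.log1p(h))
        assert elasticity == pytest.approx(1.0, abs=1e-6)

    def test_temperature_decline_three_percent(self):
        """ln(Ma) declines ~3% per degree at standard conditions."""
        def ln_ma(t):
            chi = chi_optimal(t, 1.0, SEA, 40.0)
            return np.log(lma_theoretical(20.0, 180.0, t, 40.0, chi, SEA))
        d = (ln_ma(25.01) - ln_ma(24.99)) / 0.02
        assert -d == pytest.approx(0.03, abs=0.01)


class TestLmaDeciduous:
    def test_light_scaling_forced_by_coefficient(self):
        assert lma_deciduous(40.0, 0.6, 12.0, 0.8) / lma_deciduous(
            20.0, 0.6, 12.0, 0.8) == pytest.approx(2 ** 1.22, rel=1e-12)

    def test_moisture_scaling_forced_by_coefficient(self):
        assert lma_deciduous(20.0, 0.6, 12.0, 0.4) / lma_deciduous(
            20.0, 0.6, 12.0, 0.8) == pytest.approx(2 ** 0.60, rel=1e-12)

    def test_reference_fixture(self):
        assert lma_deciduous(20.0, 0.6, 12.0, 0.8) == pytest.approx(
            79.06225008897799, rel=1e-10)

    def test_log_domain_errors(self):
        with pytest.raises(PhysicalDomainError, match="alpha_p"):
            lma_deciduous(20.0, 0.6, 12.0, 0.0)

    def test_fitted_light_elasticity(self):
        h = 1e-6
        lo, hi = (np.log(lma_deciduous(20.0 * (1 + s * h), 0.6, 12.0, 0.8))
                  for s in (-1, 1))
        assert (hi - lo) / (2 * np.log1p(h)) == pytest.approx(1.22, abs=1e-6)


class TestNarea:
    def test_no_intercept(self):
        assert narea_simple(0.0, 0.0) == 0.0
        assert narea_two_step(0.0, 0.0) == 0.0

    def test_printed_coefficients(self):
        assert narea_simple(100.0, 50.0) == pytest.approx(2.15, rel=1e-12)

    def test_additivity(self):
        a = narea_simple(60.0, 30.0)
        b = narea_simple(40.0, 20.0)
        assert narea_simple(100.0, 50.0) == pytest.approx(a + b, rel=1e-12)

    def test_n_fixer_offset(self):
        assert narea_simple(100.0, 50.0, n_fixer=True, n_fixer_offset=0.3) \
            == pytest.approx(2.45, rel=1e-12)

    def test_two_step_metabolic_term(self):
        assert narea_two_step(0.0, 100.0, alloc=9.5) == pytest.approx(
            9.5 * 0.3135, rel=1e-12)

    def test_two_step_fixture(self):
        assert narea_two_step(80.0, 60.0, alloc=7.2) == pytest.approx(
            1.5180239230582624, rel=1e-10)

    def test_models_agree_under_coefficient_identification(self, constants):
        """With the structural term linearised to the simple model's slope
        and alloc chosen so alloc * 0.003135 = 0.003, the two routes
        coincide on a grid."""
        consts = constants.replace(nstruct_coeffs=(0.02, 1.0))
        alloc = 0.003 / constants.nrub_slope
        ma, v = np.meshgrid(np.linspace(10, 200, 7), np.linspace(5, 120, 7))
        np.testing.assert_allclose(
            narea_two_step(ma, v, alloc=alloc, constants=consts),
            narea_simple(ma, v), rtol=1e-12)


class TestPredictSite:
    def test_deterministic(self):
        site = _site()
        assert predict_site(site) == predict_site(site)

    def test_all_positive_and_chi_bounded(self, sites, constants):
        for s in sites:
            p = predict_site(s, constants)
            gamma = rubisco_kinetics(s.tdj, s.patm, constants).gammastar
            assert gamma / s.ca < p.chi < 1.0
            assert p.vcmax25 > 0 and p.ma > 0 and p.narea > 0
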