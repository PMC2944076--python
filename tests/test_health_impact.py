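import math

import numpy as np
import pytest

from airburden.exposure import DeltaExposure, PM_METRIC, O3_METRIC, ThresholdPolicy
from airburden.grid import GriddedField, make_grid
from airburden.health_impact import (
    CRF_REGISTRY,
    HealthImpactError,
    attributable_fraction,
    crf_direct,
    crf_from_rr,
    excess_mortality,
    run_scenario,
    years_of_life_lost,
)


class TestCRFConstruction:
    def test_o3_respiratory_two_pollutant(self):
        crf = crf_from_rr(1.04, 1.013, 1.067, 10.0, "o3", "respiratory")
        assert crf.beta == pytest.approx(math.log(1.04) / 10, rel=1e-12)
        assert crf.beta == pytest.approx(3.922e-3, rel=1e-3)
        assert crf.beta_se == pytest.approx(math.log(1.067 / 1.013) / 39.2, rel=1e-12)
        assert crf.beta_se == pytest.approx(1.325e-3, rel=1e-3)

    def test_pm_cardiopulmonary(self):
        crf = crf_from_rr(1.13, 1.10, 1.16, 10.0, "pm25", "cardiopulmonary")
        assert crf.beta == pytest.approx(1.222e-2, rel=1e-3)

    def test_null_risk(self):
        crf = crf_from_rr(1.0, 1.0, 1.0, 10.0, "o3", "respiratory")
        assert crf.beta == 0.0
        assert crf.beta_se == 0.0

    def test_unordered_ci_rejected(self):
        with pytest.raises(HealthImpactError, match="ordered"):
            crf_from_rr(1.04, 1.05, 1.067, 10.0, "o3", "respiratory")

    def test_direct_slope_stored_verbatim(self):
        crf = crf_direct(0.00432, 0.00121, "o3", "respiratory", model="threshold-56ppb")
        assert (crf.beta, crf.beta_se) == (0.00432, 0.00121)

    def test_direct_negative_se_rejected(self):
        with pytest.raises(HealthImpactError):
            crf_direct(0.004, -0.001, "o3", "respiratory")

    def test_direct_and_rr_routes_agree(self):
        a = crf_direct(math.log(1.04) / 10, 0.0, "o3", "respiratory")
        b = crf_from_rr(1.04, 1.04, 1.04, 10.0, "o3", "respiratory")
        assert a.beta == pytest.approx(b.beta, rel=1e-15)

    def test_registry_ships_both_pollutants(self):
        pollutants = {c.pollutant for s in CRF_REGISTRY.values() for c in s}
        assert pollutants == {"o3", "pm25"}
        causes = {c.cause for c in CRF_REGISTRY["krewski2009"]}
        assert causes == {"all_cause", "cardiopulmonary", "lung_cancer"}


def _dx(grid, value, metric=O3_METRIC):
    units = "ppb" if metric == O3_METRIC else "ug/m3"
    return DeltaExposure(metric, GriddedField(grid, np.full(grid.shape, float(value)),
                                              units=units))


class TestAttributableFraction:
    grid = make_grid(2, 4)

    def test_zero_beta_gives_zero_af(self):
        crf = crf_direct(0.0, 0.0, "o3", "respiratory")
        af = attributable_fraction(crf, _dx(self.grid, 25.0))
        assert af.values == pytest.approx(0.0)

    def test_af_at_increment_recovers_rr(self):
        # AF at dX = increment must equal (rr-1)/rr to machine precision
        for rr in (1.04, 1.13, 1.5):
            crf = crf_from_rr(rr, rr, rr, 10.0, "pm25", "cardiopulmonary")
            af = attributable_fraction(crf, _dx(self.grid, 10.0, PM_METRIC))
            assert af.values.flat[0] == pytest.approx((rr - 1) / rr, rel=1e-14)

    def test_af_value_for_four_percent_rr(self):
        crf = crf_from_rr(1.04, 1.013, 1.067, 10.0, "o3", "respiratory")
        af = attributable_fraction(crf, _dx(self.grid, 10.0))
        assert af.values.flat[0] == pytest.approx(0.03846, abs=5e-5)

    def test_af_bounded_and_monotone(self):
        crf = crf_from_rr(1.1, 1.1, 1.1, 10.0, "o3", "respiratory")
        values = [
            attributable_fraction(crf, _dx(self.grid, dx)).values.flat[0]
            for dx in (0.0, 1.0, 10.0, 100.0, 1000.0)
        ]
        assert values[0] == 0.0
        assert all(0 <= v < 1 for v in values)
        assert all(a < b for a, b in zip(values, values[1:]))
        assert values[-1] > 0.999  # AF -> 1 in the large-exposure limit

    def test_metric_mismatch_rejected(self):
        crf = crf_from_rr(1.04, 1.04, 1.04, 10.0, "o3", "respiratory")
        with pytest.raises(HealthImpactError, match="metric"):
            attributable_fraction(crf, _dx(self.grid, 10.0, PM_METRIC))


class TestBurdenArithmetic:
    grid = make_grid(2, 4)

    def _f(self, value):
        return GriddedField(self.grid, np.full(self.grid.shape, float(value)))

    def test_excess_mortality_example(self):
        mort = excess_mortality(self._f(0.1), self._f(0.01), self._f(1e6))
        assert mort.values == pytest.approx(1000.0)

    def test_zero_af_gives_zero_mortality(self):
        mort = excess_mortality(self._f(0.0), self._f(0.01), self._f(1e6))
        assert mort.values == pytest.approx(0.0)

    def test_matches_cellwise_product_oracle(self, rng):
        af = rng.uniform(0, 0.5, self.grid.shape)
        y0 = rng.uniform(0, 0.02, self.grid.shape)
        pop = rng.uniform(0, 1e6, self.grid.shape)
        mort = excess_mortality(
            GriddedField(self.grid, af), GriddedField(self.grid, y0),
            GriddedField(self.grid, pop),
        )
        np.testing.assert_array_equal(mort.values, y0 * af * pop)

    def test_negative_inputs_rejected(self):
        with pytest.raises(HealthImpactError, match="negative"):
            excess_mortality(self._f(-0.1), self._f(0.01), self._f(1e6))

    def test_yll_identity_and_zero(self):
        mort = self._f(123.0)
        assert years_of_life_lost(mort, self._f(1.0)).values == pytest.approx(123.0)
        assert years_of_life_lost(self._f(0.0), self._f(9.77)).values == pytest.approx(0.0)

    def test_scale_equivariance_in_y0(self, rng):
        af = GriddedField(self.grid, rng.uniform(0, 0.5, self.grid.shape))
        y0 = GriddedField(self.grid, rng.uniform(0, 0.02, self.grid.shape))
        pop = GriddedField(self.grid, rng.uniform(0, 1e6, self.grid.shape))
        base = excess_mortality(af, y0, pop).values
        scaled = excess_mortality(af, GriddedField(self.grid, 3.0 * y0.values), pop).values
        np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-14)


CRFS = CRF_REGISTRY["jerrett2009"] + CRF_REGISTRY["krewski2009"]


class TestRunScenario:
    def test_inactive_threshold_changes_nothing(self, small_world):
        base = run_scenario(small_world, CRFS)
        # LCT below every present concentration and below preindustrial
        pols = {"o3": ThresholdPolicy(lct=1e-9), "pm25": ThresholdPolicy(lct=1e-9)}
        with_lct = run_scenario(small_world, CRFS, pols)
        for key in base:
            np.testing.assert_allclose(with_lct[key].mort.values, base[key].mort.values,
                                       rtol=1e-12)

    def test_doubling_population_doubles_burden(self, small_world):
        import copy

        base = run_scenario(small_world, CRFS)
        w2 = copy.copy(small_world)
        w2.population = GriddedField(small_world.grid,
                                     2.0 * small_world.population.values,
                                     units="persons")
        doubled = run_scenario(w2, CRFS)
        for key in base:
            np.testing.assert_allclose(doubled[key].mort.values,
                                       2.0 * base[key].mort.values, rtol=1e-12)

    def test_threshold_dominance(self, small_world):
        """Any LCT reduces burden cell-wise; any HCT reduces it too."""
        base = run_scenario(small_world, CRFS)
        lct = run_scenario(small_world, CRFS, {
            "o3": ThresholdPolicy(lct=33.3), "pm25": ThresholdPolicy(lct=5.8)})
        hct = run_scenario(small_world, CRFS, {"pm25": ThresholdPolicy(hct=30.0)})
        for key in base:
            assert np.all(lct[key].mort.values <= base[key].mort.values + 1e-9)
            assert np.all(hct[key].mort.values <= base[key].mort.values + 1e-9)
            assert lct[key].total_mort < base[key].total_mort

    def test_small_beta_first_order_expansion(self, small_world):
        """Total burden ~ sum pop*y0*beta*dX when beta*dX << 1."""
        from airburden.exposure import delta_exposure
        from airburden.health_impact import (
            _present_exposures,
            _preindustrial_exposures,
        )
        from airburden import demography as dmg

        beta = 1e-5
        crf = crf_direct(beta, 0.0, "o3", "respiratory")
        burden = run_scenario(small_world, (crf,))[("o3", "respiratory")]
        dx = delta_exposure(_present_exposures(small_world)["o3"],
                            _preindustrial_exposures(small_world)["o3"])
        y0 = dmg.rate_surface(small_world.demography, small_world.weights, "respiratory")
        pop = dmg.adult_population(small_world.population, small_world.demography,
                                   small_world.regions)
        linear = (pop.values * y0.values * beta * dx.values.values).sum()
        assert burden.total_mort == pytest.approx(linear, rel=0.01)

    def test_yll_is_mortality_times_yll0_cellwise(self, small_world):
        burdens = run_scenario(small_world, CRFS)
        from airburden.demography import yll0_surface

        for (pol, cause), b in burdens.items():
            yll0 = yll0_surface(small_world.demography, small_world.weights, cause)
            np.testing.assert_allclose(b.yll.values, b.mort.values * yll0.values,
                                       rtol=1e-12)

    def test_missing_crf_rejected(self, small_world):
        with pytest.raises(HealthImpactError):
            run_scenario(small_world, ())
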