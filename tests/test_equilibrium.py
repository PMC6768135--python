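"""Speciation solver and design simulators."""

import numpy as np
import pytest

from ligex import (
    ComplexSystem,
    MixtureTotals,
    absorbance,
    solve_speciation,
    speciation_oracle,
)
from ligex import equilibrium as eq
from ligex.exceptions import SpeciationError  # noqa: F401  (public contract)

from conftest import strong_classical_system, strong_system


def relerr(a, b):
    return abs(a - b) / max(abs(b), 1e-300)


class TestSolveSpeciation:
    def test_no_binding_frees_everything(self):
        s = ComplexSystem(n=1, log_beta_MX=-30.0, log_beta_MLn=-30.0)
        t = MixtureTotals(1e-3, 5e-4, 2e-4)
        st = solve_speciation(s, t)
        assert st.free_M == pytest.approx(1e-3, rel=1e-9)
        assert st.free_X == pytest.approx(5e-4, rel=1e-9)
        assert st.free_L == pytest.approx(2e-4, rel=1e-9)
        assert st.conc_MX < 1e-12 and st.conc_MLn < 1e-12

    def test_strong_1to1_binding_matches_quadratic_root(self):
        # M + X <=> MX with equal totals C has the closed form
        # [M] = [X] = (-1 + sqrt(1 + 4*beta*C)) / (2*beta)
        s = ComplexSystem(n=1, log_beta_MX=8.0, log_beta_MLn=-30.0)
        C = 3e-4
        st = solve_speciation(s, MixtureTotals(C, C, 0.0))
        beta = 10.0 ** 8
        free = (-1.0 + np.sqrt(1.0 + 4.0 * beta * C)) / (2.0 * beta)
        assert st.free_M == pytest.approx(free, rel=1e-9)
        assert st.conc_MX == pytest.approx(C - free, rel=1e-9)
        assert st.conc_MX == pytest.approx(C, rel=0.01)  # strong-binding limit

    def test_competitive_n2_matches_oracle_to_6sf(self):
        s = ComplexSystem(n=2, log_beta_MX=6.0, log_beta_MLn=14.0)
        t = MixtureTotals(3e-4, 3e-4, 2e-4)
        a = solve_speciation(s, t)
        b = speciation_oracle(s, t)
        for f in ("free_M", "free_X", "free_L", "conc_MX", "conc_MLn"):
            assert relerr(getattr(a, f), getattr(b, f)) < 1e-6, f

    def test_mass_balances_hold(self):
        s = ComplexSystem(n=3, log_beta_MX=10.0, log_beta_MLn=30.0)
        t = MixtureTotals(1e-3, 4e-4, 9e-4)
        st = solve_speciation(s, t)
        assert max(st.residuals) <= 1e-9
        assert st.free_M + st.conc_MX + st.conc_MLn == pytest.approx(1e-3, rel=1e-9)
        assert st.free_X + st.conc_MX == pytest.approx(4e-4, rel=1e-9)
        assert st.free_L + 3 * st.conc_MLn == pytest.approx(9e-4, rel=1e-9)

    @pytest.mark.parametrize("totals", [
        MixtureTotals(0.0, 0.0, 0.0),
        MixtureTotals(0.0, 1e-4, 2e-4),
        MixtureTotals(1e-4, 0.0, 2e-4),
        MixtureTotals(1e-4, 2e-4, 0.0),
    ])
    def test_zero_component_edge_cases(self, totals):
        s = ComplexSystem(n=2, log_beta_MX=8.0, log_beta_MLn=16.0)
        st = solve_speciation(s, totals)
        assert max(st.residuals) <= 1e-9
        if totals.C_M_total == 0:
            assert st.conc_MX == 0 and st.conc_MLn == 0

    def test_oracle_equivalence_on_random_grid(self, rng):
        # quick randomized cross-check; the full >=200-system sweep runs in
        # the acceptance suite
        for _ in range(40):
            n = int(rng.integers(1, 4))
            s = ComplexSystem(n=n,
                              log_beta_MX=float(rng.uniform(2, 16)),
                              log_beta_MLn=float(rng.uniform(2, 16)))
            t = MixtureTotals(*(10.0 ** rng.uniform(-6, -2) for _ in range(3)))
            a, b = solve_speciation(s, t), speciation_oracle(s, t)
            for f in ("free_M", "free_X", "free_L"):
                assert relerr(getattr(a, f), getattr(b, f)) < 1e-6


class TestAbsorbance:
    def test_empty_state_is_dark(self):
        s = ComplexSystem()
        st = solve_speciation(s, MixtureTotals(0, 0, 0))
        assert absorbance(s, st) == 0.0

    def test_beer_lambert_direct_product(self):
        s = ComplexSystem(n=1, log_beta_MX=16.0, eps_MX=1600.0)
        st = solve_speciation(s, MixtureTotals(3e-4, 3e-4, 0.0))
        assert st.conc_MX == pytest.approx(3e-4, rel=1e-6)
        assert absorbance(s, st) == pytest.approx(0.48, rel=1e-5)

    def test_all_species_contribute(self):
        s = ComplexSystem(n=2, log_beta_MX=6.0, log_beta_MLn=14.0,
                          eps_MX=1600.0, eps_MLn=50.0, eps_M=10.0, eps_L=5.0,
                          path_length=2.0)
        st = solve_speciation(s, MixtureTotals(3e-4, 3e-4, 2e-4))
        expected = 2.0 * (1600 * st.conc_MX + 50 * st.conc_MLn
                          + 10 * st.free_M + 5 * st.free_L)
        assert absorbance(s, st) == pytest.approx(expected, rel=1e-12)


class TestExchangeDesign:
    def test_zero_noise_strong_limit_is_linear_with_slope_eps_over_n(self):
        # pre-equivalence attenuation: A = eps*(C_MX - C_L/n); in the deep
        # strong limit (indicator fully formed, displacement quantitative)
        # the simulated points sit on that line to < 1e-6 AU
        for n in (1, 2):
            s = strong_system(n, log_beta_MX=16.0, log_beta_MLn=20.0 * n + 4.0)
            ser = eq.simulate_exchange_design(s, 3e-4, eq.STANDARD_EXCHANGE_LIGAND)
            pred = 1600.0 * (3e-4 - ser.x_values / n)
            assert np.max(np.abs(ser.absorbances - pred)) < 1e-6

    def test_absorbance_monotone_nonincreasing_in_ligand(self):
        s = ComplexSystem(n=1, log_beta_MX=6.0, log_beta_MLn=9.0)
        ser = eq.simulate_exchange_design(s, 3e-4, np.linspace(1e-5, 1e-3, 15))
        assert np.all(np.diff(ser.absorbances) <= 1e-15)

    def test_seed_determinism(self):
        s = strong_system(1)
        a = eq.simulate_exchange_design(s, 3e-4, eq.STANDARD_EXCHANGE_LIGAND,
                                        noise_sd=0.002, seed=7)
        b = eq.simulate_exchange_design(s, 3e-4, eq.STANDARD_EXCHANGE_LIGAND,
                                        noise_sd=0.002, seed=7)
        np.testing.assert_array_equal(a.absorbances, b.absorbances)
        assert a.seed == 7 and a.noise_sd == 0.002

    def test_rejects_nonpositive_indicator(self):
        with pytest.raises(ValueError):
            eq.simulate_exchange_design(strong_system(1), 0.0, [1e-5])


class TestCalibrationDesign:
    def test_strong_limit_linear_through_origin(self):
        s = strong_system(1, log_beta_MX=16.0)
        ser = eq.simulate_calibration_design(s, eq.STANDARD_CALIBRATION_LEVELS)
        np.testing.assert_allclose(ser.absorbances, 1600.0 * ser.x_values,
                                   rtol=1e-5)

    def test_seed_determinism(self):
        s = strong_system(1)
        a = eq.simulate_calibration_design(s, eq.STANDARD_CALIBRATION_LEVELS,
                                           0.002, seed=3)
        b = eq.simulate_calibration_design(s, eq.STANDARD_CALIBRATION_LEVELS,
                                           0.002, seed=3)
        np.testing.assert_array_equal(a.absorbances, b.absorbances)


class TestJobDesign:
    def test_default_grid_is_nine_interior_fractions(self):
        s = strong_classical_system(1)
        ser = eq.simulate_job_design(s, 1e-3)
        np.testing.assert_allclose(ser.x_values, np.arange(1, 10) / 10.0)
        assert ser.method_kind == "job"

    def test_symmetric_1to1_curve(self):
        ser = eq.simulate_job_design(strong_classical_system(1), 1e-3, 9)
        np.testing.assert_allclose(ser.absorbances, ser.absorbances[::-1],
                                   rtol=1e-9)

    def test_apex_near_one_over_n_plus_one(self):
        for n in (1, 2, 3):
            ser = eq.simulate_job_design(strong_classical_system(n), 1e-3, 19)
            apex = ser.x_values[np.argmax(ser.absorbances)]
            grid = ser.x_values
            ideal = 1.0 / (1.0 + n)
            assert abs(apex - grid[np.argmin(np.abs(grid - ideal))]) < 1e-12

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            eq.simulate_job_design(strong_classical_system(1), 1e-3, 2)


class TestMoleRatioDesign:
    def test_strong_limit_breaks_at_one_over_n_on_metal_axis(self):
        # plateau for C_M >= C_L/n, i.e. metal:ligand ratio >= 1/n
        for n in (1, 2):
            s = strong_classical_system(n)
            ratios = np.linspace(0.05, 3.0, 30)
            ser = eq.simulate_moleratio_design(s, 5e-4, ratios * 5e-4)
            plateau = ser.absorbances[ser.x_values > 1.0 / n + 0.05]
            rising = ser.absorbances[ser.x_values < 1.0 / n - 0.05]
            assert np.ptp(plateau) < 1e-6
            slope = np.diff(rising) / np.diff(ser.x_values[: len(rising)])
            assert np.all(slope > 0)

    def test_seed_determinism(self):
        s = strong_classical_system(1)
        a = eq.simulate_moleratio_design(s, 5e-4, eq.STANDARD_MOLERATIO_METAL,
                                         0.002, seed=5)
        b = eq.simulate_moleratio_design(s, 5e-4, eq.STANDARD_MOLERATIO_METAL,
                                         0.002, seed=5)
        np.testing.assert_array_equal(a.absorbances, b.absorbances)


class TestTypes:
    def test_invalid_system_rejected(self):
        with pytest.raises(ValueError):
            ComplexSystem(n=0)
        with pytest.raises(ValueError):
            ComplexSystem(eps_MX=-1.0)
        with pytest.raises(ValueError):
            ComplexSystem(log_beta_MX=np.inf)

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            MixtureTotals(-1e-4, 0.0, 0.0)

    def test_series_requires_sorted_x(self):
        with pytest.raises(ValueError):
            eq.TitrationSeries("calibration", [2.0, 1.0], [0.1, 0.2])

    def test_job_series_requires_mole_fractions(self):
        with pytest.raises(ValueError):
            eq.TitrationSeries("job", [0.2, 1.4], [0.1, 0.2])
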