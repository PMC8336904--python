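"""The extended input-output core: coefficients, inverses, equilibrium, shocks."""

import numpy as np
import pytest

from depio import synthetic_data as sd
from depio.demo_model import (
    coefficients,
    extended_system,
    hawkins_simon,
    leontief_inverse,
    shock_impact,
    solve_equilibrium,
    spectral_radius,
)
from depio.economy_io import Economy
from depio.exceptions import BasisError, NonProductiveError, SingularSystemError


def tiny_economy():
    """Hand-checkable 2-sector economy: A = [[0.2, 0.15], [0.1, 0.2]]."""
    Z = np.array([[20.0, 30.0], [10.0, 40.0]])
    x = np.array([100.0, 200.0])
    va = x - Z.sum(axis=0)  # (70, 130)
    return Economy(
        sectors=["S1", "S2"],
        Z=Z, x=x,
        wages=0.5 * va,
        social_contributions=0.12 * va,
        gos=0.36 * va,
        net_taxes_production=0.02 * va,
        jobs=np.array([10.0, 16.0]),
        f_other=x - Z.sum(axis=1),
        labour_force=40.0,
        w_U=0.9,
        y_S=11.0,
    ).validate()


class TestCoefficients:
    def test_direct_division(self):
        c = coefficients(tiny_economy())
        np.testing.assert_allclose(c.A, [[0.2, 0.15], [0.1, 0.2]])
        np.testing.assert_allclose(c.l_d, [0.1, 0.08])
        np.testing.assert_allclose(c.w_x, 0.5 * np.array([70, 130]) / [100, 200])

    def test_component_rows_sum_to_value_added_coefficients(self, economy):
        c = coefficients(economy)
        np.testing.assert_allclose(
            c.wages_d + c.social_contributions_d + c.gos_d
            + c.net_taxes_production_d,
            c.v_d, rtol=1e-9)

    def test_zero_output_sector_yields_zero_column_not_nan(self):
        economy = tiny_economy()
        economy.Z[:, 1] = 0.0
        economy.Z[1, :] = 0.0
        economy.x[1] = 0.0
        economy.jobs[1] = 0.0
        for name in ("wages", "social_contributions", "gos",
                     "net_taxes_production"):
            getattr(economy, name)[1] = 0.0
        economy.f_other[1] = 0.0
        c = coefficients(economy)
        assert np.all(np.isfinite(c.A))
        assert np.all(c.A[:, 1] == 0.0)
        assert c.l_d[1] == 0.0


class TestLeontiefInverse:
    def test_zero_matrix_gives_identity(self):
        np.testing.assert_array_equal(leontief_inverse(np.zeros((3, 3))),
                                      np.eye(3))

    def test_one_sector_geometric_series(self):
        np.testing.assert_allclose(leontief_inverse(np.array([[0.5]])),
                                   [[2.0]])

    def test_matches_neumann_series_oracle(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0, 1, (5, 5))
        A *= 0.7 / spectral_radius(A)
        series = np.eye(5)
        term = np.eye(5)
        for _ in range(200):
            term = term @ A
            series += term
        np.testing.assert_allclose(leontief_inverse(A), series, atol=1e-8)

    def test_result_dominates_identity(self, economy):
        L = leontief_inverse(coefficients(economy).A)
        assert np.all(L >= np.eye(economy.n) - 1e-12)

    def test_nonproductive_matrix_raises_with_radius(self):
        with pytest.raises(NonProductiveError, match="1.2"):
            leontief_inverse(np.array([[1.2]]))

    def test_hawkins_simon_detects_nonproductive(self):
        assert hawkins_simon(np.array([[0.3, 0.2], [0.4, 0.1]]))
        assert not hawkins_simon(np.array([[0.9, 0.9], [0.9, 0.9]]))


class TestExtendedSystem:
    def test_reduces_to_open_model_without_households(self):
        c = coefficients(tiny_economy())
        system = extended_system(c, np.zeros(2), np.zeros(2), 0.5)
        np.testing.assert_allclose(system.M, np.eye(2) - c.A)

    def test_reduces_to_type_two_without_benefit(self):
        c = coefficients(tiny_economy())
        c_E = np.array([0.6, 0.4])
        system = extended_system(c, c_E, np.array([0.5, 0.5]), 0.0)
        np.testing.assert_allclose(
            system.M, np.eye(2) - c.A - np.outer(c_E, c.w_x))

    def test_two_sector_hand_assembly(self):
        c = coefficients(tiny_economy())
        c_E = np.array([0.6, 0.4])
        c_U = np.array([0.5, 0.5])
        w_U = 0.9
        system = extended_system(c, c_E, c_U, w_U)
        expected = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                expected[i, j] = ((1.0 if i == j else 0.0) - c.A[i, j]
                                  - c_E[i] * c.w_x[j]
                                  + c_U[i] * w_U * c.l_d[j])
        np.testing.assert_allclose(system.M, expected)

    def test_singular_system_raises(self):
        c = coefficients(tiny_economy())
        # c_E w_x engineered so the first row of M vanishes
        w = c.w_x
        c_E = np.array([(1.0 - c.A[0, 0]) / w[0], 0.0])
        A0 = c.A.copy()
        A0[0, 1] = -c_E[0] * w[1]  # zero out remaining entry
        from depio.demo_model import CoefficientSet
        c0 = CoefficientSet(A=A0, w_x=c.w_x, l_d=np.zeros(2), v_d=c.v_d,
                            wages_d=c.wages_d,
                            social_contributions_d=c.social_contributions_d,
                            gos_d=c.gos_d,
                            net_taxes_production_d=c.net_taxes_production_d)
        with pytest.raises(SingularSystemError):
            extended_system(c0, c_E, np.zeros(2), 1.0)


class TestEquilibrium:
    def test_open_model_reduction(self):
        economy = tiny_economy()
        economy.y_S = 0.0
        c = coefficients(economy)
        system = extended_system(c, np.zeros(2), np.zeros(2), economy.w_U)
        c_D = np.array([5.0, 7.0])
        sol = solve_equilibrium(economy, system, c_D)
        expected = leontief_inverse(c.A) @ (c_D + economy.f_other)
        np.testing.assert_allclose(sol.x, expected, rtol=1e-12)

    def test_balances_hold(self):
        economy = tiny_economy()
        c = coefficients(economy)
        system = extended_system(c, np.array([0.6, 0.4]),
                                 np.array([0.5, 0.5]), economy.w_U)
        sol = solve_equilibrium(economy, system, np.array([3.0, 4.0]))
        assert max(sol.residuals.values()) < 1e-8

    def test_matches_dense_block_system_oracle(self):
        economy = tiny_economy()
        c = coefficients(economy)
        c_E = np.array([0.6, 0.4])
        c_U = np.array([0.5, 0.5])
        system = extended_system(c, c_E, c_U, economy.w_U)
        c_D = np.array([3.0, 4.0])
        # full (n+2) x (n+2) block system solved densely
        n = 2
        block = np.zeros((n + 2, n + 2))
        block[:n, :n] = np.eye(n) - c.A
        block[:n, n] = -c_E
        block[:n, n + 1] = -c_U * economy.w_U
        block[n, :n] = -c.w_x
        block[n, n] = 1.0
        block[n + 1, :n] = c.l_d
        block[n + 1, n + 1] = 1.0
        rhs = np.concatenate([c_D + economy.f_other,
                              [economy.y_S, economy.labour_force]])
        dense = np.linalg.solve(block, rhs)
        sol = solve_equilibrium(economy, system, c_D)
        np.testing.assert_allclose(sol.x, dense[:n], rtol=1e-10)
        assert sol.y_E == pytest.approx(dense[n], rel=1e-10)
        assert sol.u == pytest.approx(dense[n + 1], rel=1e-10)

    def test_exhausted_labour_force_is_flagged_not_clipped(self):
        economy = tiny_economy()
        economy.labour_force = 1.0
        c = coefficients(economy)
        system = extended_system(c, np.zeros(2), np.zeros(2), economy.w_U)
        sol = solve_equilibrium(economy, system, np.array([10.0, 10.0]))
        assert not sol.feasible
        assert sol.u < 0


class TestShockImpact:
    def _system(self, economy, profiles):
        c = coefficients(economy)
        _, emp, unemp = profiles
        return c, extended_system(c, 0.65 * emp.shares, 0.65 * unemp.shares,
                                  economy.w_U)

    def test_zero_shock_zero_impact(self, economy, profiles):
        _, system = self._system(economy, profiles)
        np.testing.assert_array_equal(
            shock_impact(system, np.zeros(economy.n)), np.zeros(economy.n))

    def test_linearity(self, economy, profiles):
        _, system = self._system(economy, profiles)
        rng = np.random.default_rng(1)
        a = rng.uniform(-5, 20, economy.n)
        b = rng.uniform(-5, 20, economy.n)
        np.testing.assert_allclose(
            shock_impact(system, 2 * a + b),
            2 * shock_impact(system, a) + shock_impact(system, b),
            rtol=1e-9, atol=1e-9)

    def test_basis_mismatch_rejected(self, economy, profiles):
        _, system = self._system(economy, profiles)
        purchaser = type("V", (), {"values": np.zeros(economy.n),
                                   "basis": "purchaser"})()
        with pytest.raises(BasisError):
            shock_impact(system, purchaser)

    def test_direct_formula_equals_two_equilibrium_subtraction(
            self, economy, profiles):
        _, system = self._system(economy, profiles)
        rng = np.random.default_rng(2)
        c_D = rng.uniform(0, 100, economy.n)
        with_shock = solve_equilibrium(economy, system, c_D)
        without = solve_equilibrium(economy, system, np.zeros(economy.n))
        direct = shock_impact(system, c_D)
        np.testing.assert_allclose(with_shock.x - without.x, direct,
                                   rtol=1e-9)

    def test_demographic_balance_after_shock(self, economy, profiles):
        c, system = self._system(economy, profiles)
        rng = np.random.default_rng(3)
        c_D = rng.uniform(0, 100, economy.n)
        with_shock = solve_equilibrium(economy, system, c_D)
        without = solve_equilibrium(economy, system, np.zeros(economy.n))
        x_D = shock_impact(system, c_D)
        delta_u = with_shock.u - without.u
        assert delta_u == pytest.approx(-float(c.l_d @ x_D), rel=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_multiplier_ordering_open_type4_type2(self, seed):
        config = sd.SyntheticConfig(seed=seed)
        economy = sd.generate_economy(config)
        _, emp, unemp = sd.generate_profiles(config)
        c = coefficients(economy)
        c_E, c_U = 0.65 * emp.shares, 0.65 * unemp.shares
        system = extended_system(c, c_E, c_U, economy.w_U)
        rng = np.random.default_rng(seed)
        shock = rng.uniform(0, 50, economy.n)
        open_x = leontief_inverse(c.A) @ shock
        type4 = shock_impact(system, shock)
        type2 = np.linalg.solve(
            np.eye(economy.n) - c.A - np.outer(c_E, c.w_x), shock)
        assert np.all(open_x <= type4 + 1e-8)
        assert np.all(type4 <= type2 + 1e-8)
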