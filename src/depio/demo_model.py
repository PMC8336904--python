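"""Demo-economic extended input-output core.

An open Leontief economy ``(I - A) x = f`` is closed twice over: first with
respect to employed-household consumption (income generated by production is
re-spent through the employed profile, the classic type-II closure), and then
with respect to the employed/unemployed substitution (with a fixed labour
force, extra labour demand moves people off unemployment benefit, removing
their benefit-financed consumption — the demo-economic, type-IV closure).

The closed system is

    M = I - A - c_E w_x + c_U w_U l_d

where ``c_E`` and ``c_U`` are column vectors of consumption coefficients for
employed and unemployed households, ``w_x`` is the row vector of wages per
unit of sectoral output, ``l_d`` the row vector of labour coefficients
(jobs per million euros) and ``w_U`` the benefit per unemployed person.  The
sign on the unemployment term is positive: an output increase *reduces*
benefit-financed consumption.

The equilibrium of the full block system

    [[I - A, -c_E, -c_U w_U], [-w_x, 1, 0], [l_d, 0, 1]] (x, y_E, u)
        = (c^D + f^O, y_S, p)

is ``x = M^{-1} (c^D + f^O + c_E y_S + c_U w_U p)`` with ``y_E = w_x x + y_S``
and ``u = p - l_d x``.  A demand shock ``c^D`` therefore propagates as
``x^D = M^{-1} c^D``, identical to the difference between the equilibria with
and without the shock (the exogenous-income and benefit terms cancel).

Linear systems are solved by LU factorisation; the extended inverse itself is
exposed only as a diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .economy_io import PRODUCER_DOMESTIC, Economy
from .exceptions import (
    BasisError,
    DimensionError,
    NonProductiveError,
    SingularSystemError,
)

logger = logging.getLogger(__name__)

_COND_LIMIT = 1e12


def spectral_radius(A: np.ndarray) -> float:
    """Largest eigenvalue modulus of a square matrix."""
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def hawkins_simon(A: np.ndarray) -> bool:
    """True when all leading principal minors of ``I - A`` are positive.

    For a nonnegative coefficient matrix this is equivalent to the economy
    being productive (every nonnegative final demand is attainable with
    nonnegative gross outputs).
    """
    B = np.eye(len(A)) - np.asarray(A, dtype=float)
    return all(np.linalg.det(B[: k, : k]) > 0 for k in range(1, len(B) + 1))


@dataclass(frozen=True)
class CoefficientSet:
    """Direct coefficients per unit of gross output.

    ``A[i, j]`` is the input of sector ``i`` per unit of output of ``j``;
    ``w_x``, ``l_d`` and ``v_d`` are wages, jobs and value added per unit of
    output, with ``v_d`` split into its four components.
    """

    A: np.ndarray
    w_x: np.ndarray
    l_d: np.ndarray
    v_d: np.ndarray
    wages_d: np.ndarray
    social_contributions_d: np.ndarray
    gos_d: np.ndarray
    net_taxes_production_d: np.ndarray


def coefficients(economy: Economy) -> CoefficientSet:
    """Derive the direct coefficient set; zero-output sectors get zeros."""
    x = economy.x
    safe = np.where(x > 0, x, 1.0)
    inv_x = np.where(x > 0, 1.0 / safe, 0.0)
    A = economy.Z * inv_x[np.newaxis, :]
    comp = {name: getattr(economy, name) * inv_x for name in (
        "wages", "social_contributions", "gos", "net_taxes_production")}
    return CoefficientSet(
        A=A,
        w_x=comp["wages"],
        l_d=economy.jobs * inv_x,
        v_d=economy.value_added * inv_x,
        wages_d=comp["wages"],
        social_contributions_d=comp["social_contributions"],
        gos_d=comp["gos"],
        net_taxes_production_d=comp["net_taxes_production"],
    )


def leontief_inverse(A: np.ndarray) -> np.ndarray:
    """(I - A)^{-1}: total output requirements per unit of final demand."""
    A = np.asarray(A, dtype=float)
    rho = spectral_radius(A)
    if rho >= 1.0:
        raise NonProductiveError(
            f"coefficient matrix is not productive (spectral radius {rho:.4f})"
        )
    n = A.shape[0]
    return np.linalg.solve(np.eye(n) - A, np.eye(n))


@dataclass(frozen=True)
class ExtendedSystem:
    """The closed (type-IV) system matrix with its closure ingredients."""

    M: np.ndarray
    c_E: np.ndarray
    c_U: np.ndarray
    w_U: float
    coeffs: CoefficientSet
    condition: float
    spectral_radius_check: float

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return np.linalg.solve(self.M, np.asarray(rhs, dtype=float))

    def extended_inverse(self) -> np.ndarray:
        """M^{-1}; diagnostic only — solves go through factorisation."""
        return np.linalg.solve(self.M, np.eye(self.M.shape[0]))


def extended_system(coeffs: CoefficientSet, c_E, c_U, w_U: float) -> ExtendedSystem:
    """Assemble M = I - A - c_E w_x + c_U w_U l_d and verify invertibility."""
    A = coeffs.A
    n = A.shape[0]
    c_E = np.asarray(c_E, dtype=float).reshape(-1)
    c_U = np.asarray(c_U, dtype=float).reshape(-1)
    if c_E.shape != (n,) or c_U.shape != (n,):
        raise DimensionError("consumption coefficient vectors must have length n")
    if w_U < 0:
        raise ValueError("unemployment benefit w_U must be nonnegative")
    M = (np.eye(n) - A - np.outer(c_E, coeffs.w_x)
         + w_U * np.outer(c_U, coeffs.l_d))
    cond = float(np.linalg.cond(M))
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise SingularSystemError(
            f"extended system matrix is singular or ill-conditioned "
            f"(condition number {cond:.3g})"
        )
    rho = spectral_radius(np.eye(n) - M)
    logger.debug("extended system: cond=%.3g, rho(I-M)=%.4f", cond, rho)
    return ExtendedSystem(M=M, c_E=c_E, c_U=c_U, w_U=float(w_U), coeffs=coeffs,
                          condition=cond, spectral_radius_check=rho)


@dataclass(frozen=True)
class EquilibriumSolution:
    """Equilibrium output, employed income and unemployment, with residuals."""

    x: np.ndarray
    y_E: float
    u: float
    feasible: bool
    residuals: dict


def solve_equilibrium(economy: Economy, system: ExtendedSystem,
                      c_D_total) -> EquilibriumSolution:
    """Solve the closed system for a given exogenous dependency demand.

    The constant term is the algebraically complete
    ``c^D + f^O + c_E y_S + c_U w_U p``.  Unemployment outside ``[0, p]`` is
    flagged infeasible (labour force exhausted), never clipped.
    """
    c_D_total = np.asarray(c_D_total, dtype=float).reshape(-1)
    if c_D_total.shape != (economy.n,):
        raise DimensionError("c_D_total length does not match economy")
    p = economy.labour_force
    rhs = (c_D_total + economy.f_other + system.c_E * economy.y_S
           + system.c_U * system.w_U * p)
    x = system.solve(rhs)
    coeffs = system.coeffs
    y_E = float(coeffs.w_x @ x + economy.y_S)
    u = float(p - coeffs.l_d @ x)
    scale = max(float(np.max(np.abs(x))), 1.0)
    residuals = {
        "supply_demand": float(np.max(np.abs(
            (np.eye(economy.n) - coeffs.A) @ x - system.c_E * y_E
            - system.c_U * system.w_U * u - c_D_total - economy.f_other
        ))) / scale,
        "income": abs(-coeffs.w_x @ x + y_E - economy.y_S) / max(abs(y_E), 1.0),
        "demographic": abs(coeffs.l_d @ x + u - p) / max(abs(p), 1.0),
    }
    feasible = 0.0 <= u <= p
    if not feasible:
        logger.warning("equilibrium infeasible: u=%.2f outside [0, %.2f]", u, p)
    return EquilibriumSolution(x=x, y_E=y_E, u=u, feasible=feasible,
                               residuals=residuals)


def shock_impact(system: ExtendedSystem, c_D) -> np.ndarray:
    """Output impact ``x^D = M^{-1} c^D`` of an exogenous demand shock.

    ``c_D`` may be a plain vector or any object with ``values``/``basis``
    attributes, in which case the basis must be producer-domestic.
    """
    basis = getattr(c_D, "basis", None)
    values = getattr(c_D, "values", c_D)
    if basis is not None and basis != PRODUCER_DOMESTIC:
        raise BasisError(
            f"shock must be in producer_domestic basis, got {basis!r}"
        )
    values = np.asarray(values, dtype=float).reshape(-1)
    if values.shape[0] != system.M.shape[0]:
        raise DimensionError("shock vector length does not match system")
    return system.solve(values)
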