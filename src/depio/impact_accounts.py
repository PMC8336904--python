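"""Employment and income accounts derived from an output impact.

Given the sectoral output response ``x^D`` to a demand shock, employment and
value added sustained by that demand are ``l^D = diag(l_d) x^D`` and
``v^D = diag(v_d) x^D``, with value added split into wages, social
contributions, gross operating surplus (GOS) and net taxes on production.

Employment is further decomposed with the standard telescoping convention:

* direct   — first-round jobs on the shock itself, ``diag(l_d) c^D``;
* indirect — the open-model supply-chain remainder,
  ``diag(l_d) ((I - A)^{-1} - I) c^D``;
* induced  — the income-consumption closure remainder,
  ``diag(l_d) (M^{-1} - (I - A)^{-1}) c^D``.

The three components sum exactly to the total by construction.  With a fixed
labour force, the change in unemployment is minus total employment created.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .demo_model import (
    CoefficientSet,
    ExtendedSystem,
    leontief_inverse,
    shock_impact,
)
from .exceptions import DimensionError, ValidationError

VA_KEYS = ("wages", "social_contributions", "gos", "net_taxes_production")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed report precision."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def employment_impact(x_D, coeffs: CoefficientSet) -> np.ndarray:
    """Jobs sustained per sector: elementwise ``l_d[j] * x_D[j]``."""
    x_D = np.asarray(x_D, dtype=float)
    if x_D.shape != coeffs.l_d.shape:
        raise DimensionError("x_D length does not match coefficients")
    return coeffs.l_d * x_D


def value_added_impact(x_D, coeffs: CoefficientSet) -> pd.DataFrame:
    """Value added per sector with its four components and total."""
    x_D = np.asarray(x_D, dtype=float)
    if x_D.shape != coeffs.v_d.shape:
        raise DimensionError("x_D length does not match coefficients")
    out = pd.DataFrame({
        "wages": coeffs.wages_d * x_D,
        "social_contributions": coeffs.social_contributions_d * x_D,
        "gos": coeffs.gos_d * x_D,
        "net_taxes_production": coeffs.net_taxes_production_d * x_D,
    })
    out["total"] = out[list(VA_KEYS)].sum(axis=1)
    return out


def decompose(c_D, A, system: ExtendedSystem):
    """Split employment into (direct, indirect, induced) sectoral vectors."""
    values = np.asarray(getattr(c_D, "values", c_D), dtype=float).reshape(-1)
    L = leontief_inverse(A)
    x_open = L @ values
    x_total = system.solve(values)
    l_d = system.coeffs.l_d
    direct = l_d * values
    indirect = l_d * (x_open - values)
    induced = l_d * (x_total - x_open)
    return direct, indirect, induced


@dataclass(frozen=True)
class ImpactResult:
    """Full sectoral account of one demand shock (million euros, jobs)."""

    sectors: tuple
    x_D: np.ndarray
    jobs_direct: np.ndarray
    jobs_indirect: np.ndarray
    jobs_induced: np.ndarray
    va: pd.DataFrame
    delta_u: float
    base_spend: float

    @property
    def jobs_total(self) -> np.ndarray:
        return self.jobs_direct + self.jobs_indirect + self.jobs_induced

    @property
    def va_total(self) -> np.ndarray:
        return self.va["total"].to_numpy()

    def totals(self) -> dict:
        """Economy-wide totals keyed as in the comparison reports."""
        out = {
            "output": float(self.x_D.sum()),
            "value_added": float(self.va["total"].sum()),
            "jobs_total": float(self.jobs_total.sum()),
            "jobs_direct": float(self.jobs_direct.sum()),
            "jobs_indirect": float(self.jobs_indirect.sum()),
            "jobs_induced": float(self.jobs_induced.sum()),
        }
        for key in VA_KEYS:
            out[key] = float(self.va[key].sum())
        return out

    def to_frame(self) -> pd.DataFrame:
        """Sector-level table mirroring the published layouts."""
        df = pd.DataFrame({
            "sector": list(self.sectors),
            "output": self.x_D,
            "jobs_direct": self.jobs_direct,
            "jobs_indirect": self.jobs_indirect,
            "jobs_induced": self.jobs_induced,
            "jobs_total": self.jobs_total,
        })
        for key in (*VA_KEYS, "total"):
            df[f"va_{key}"] = self.va[key].to_numpy()
        return df


def compute_impact(system: ExtendedSystem, shock, base_spend: float,
                   sectors=None) -> ImpactResult:
    """Run a shock through the closed model and assemble all accounts."""
    x_D = shock_impact(system, shock)
    direct, indirect, induced = decompose(shock, system.coeffs.A, system)
    va = value_added_impact(x_D, system.coeffs)
    total_jobs = float((direct + indirect + induced).sum())
    if sectors is None:
        sectors = tuple(f"S{i + 1}" for i in range(len(x_D)))
    return ImpactResult(
        sectors=tuple(sectors),
        x_D=x_D,
        jobs_direct=direct,
        jobs_indirect=indirect,
        jobs_induced=induced,
        va=va,
        delta_u=-total_jobs,
        base_spend=float(base_spend),
    )


def per_million(total: float, base_spend: float) -> float:
    """Return generated per million euros of expenditure."""
    if base_spend <= 0:
        raise ValidationError("multiplier base must be positive")
    return total / base_spend


def multipliers_per_million(result: ImpactResult) -> dict:
    """Output, jobs and value-added return per million euros of spending."""
    if result.base_spend <= 0:
        raise ValidationError("multiplier base must be positive")
    totals = result.totals()
    keys = ("output", "jobs_total", "value_added", *VA_KEYS)
    return {key: totals[key] / result.base_spend for key in keys}
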