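"""End-to-end benefit-mix scenarios, the all-in-kind counterfactual, reports.

A :class:`Scenario` runs the full chain — shock construction per benefit,
purchaser-to-producer conversion, closed-model impact, employment and income
accounts — for a list of benefit specs against one economy and one set of
household profiles.  The counterfactual rebuilds the entire budget (public
spend and co-payments preserved) as a single in-kind benefit, which is the
policy question of interest: what would the economy-wide return have been had
the system granted formal care only, instead of the actual mix of in-kind
services and cash benefits?

Report helpers compute percentage shares and baseline/counterfactual deltas
at the printed precision, and the fixture summary reproduces the published
headline statistics from the packaged tables by report arithmetic (the
published magnitudes themselves stem from national data the package does not
ship).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import benefit_shocks as bs
from .benefit_shocks import BenefitSpec, ShockVector
from .demo_model import ExtendedSystem, coefficients, extended_system
from .economy_io import Economy, PriceBridge
from .exceptions import DimensionError, ValidationError
from .impact_accounts import (
    ImpactResult,
    compute_impact,
    per_million,
    round_half_up,
)
from .synthetic_data import DEFAULT_CONSUMPTION_PROPENSITY, PublishedTables

logger = logging.getLogger(__name__)

_TOTAL_KEYS = ("output", "value_added", "wages", "social_contributions",
               "gos", "net_taxes_production", "jobs_total", "jobs_direct",
               "jobs_indirect", "jobs_induced")


@dataclass(frozen=True)
class Scenario:
    """One full model run: specs, producer-basis shocks and impact accounts."""

    name: str
    economy: Economy
    profiles: tuple
    bridge: PriceBridge
    specs: tuple
    shocks: dict
    impacts: dict
    combined: ImpactResult
    system: ExtendedSystem

    def totals(self) -> dict:
        return self.combined.totals()

    @property
    def total_spend(self) -> float:
        return sum(s.total_cost for s in self.specs)


@dataclass(frozen=True)
class Comparison:
    """Baseline vs counterfactual totals with deltas and percent changes."""

    frame: pd.DataFrame

    def delta(self, key: str) -> float:
        return float(self.frame.loc[key, "delta"])

    def pct_change(self, key: str) -> float:
        return float(self.frame.loc[key, "pct_change"])


def run_scenario(economy: Economy, profiles, specs,
                 bridge: PriceBridge | None = None,
                 name: str = "benefit_mix",
                 multiplier_base: str = "total",
                 consumption_propensity: float = DEFAULT_CONSUMPTION_PROPENSITY,
                 ) -> Scenario:
    """Run the full pipeline for a list of benefit specs.

    ``profiles`` is the (dependent, employed, unemployed) triple in purchaser
    basis.  The employed/unemployed closure coefficients are the profile
    shares scaled by ``consumption_propensity`` (the fraction of gross income
    re-spent on consumption, the rest leaking to savings and direct taxes)
    and passed through the price bridge, so only the domestic producer-price
    content of induced consumption re-enters demand.  ``multiplier_base``
    selects the per-million normalisation base: the benefit's total cost
    (``"total"``) or its public spend only (``"public"``).
    """
    dep, emp, unemp = profiles
    for profile in (dep, emp, unemp):
        if len(profile.shares) != economy.n:
            raise DimensionError("profile sector scheme does not match economy")
    if multiplier_base not in ("total", "public"):
        raise ValidationError("multiplier_base must be 'total' or 'public'")
    if not 0.0 < consumption_propensity <= 1.0:
        raise ValidationError("consumption_propensity must lie in (0, 1]")
    if bridge is None:
        bridge = PriceBridge.identity(economy.n)

    from .economy_io import to_producer_domestic

    coeffs = coefficients(economy)
    c_E = consumption_propensity * to_producer_domestic(emp.shares, bridge).values
    c_U = consumption_propensity * to_producer_domestic(unemp.shares, bridge).values
    system = extended_system(coeffs, c_E, c_U, economy.w_U)

    shocks: dict[str, ShockVector] = {}
    impacts: dict[str, ImpactResult] = {}
    for spec in specs:
        purchaser = bs.build_shock(spec, dep)
        producer = bs.convert_shock(purchaser, bridge)
        base = spec.total_cost if multiplier_base == "total" else spec.public_spend
        impact = compute_impact(system, producer, base or 1.0,
                                sectors=economy.sectors)
        key = spec.benefit_type
        shocks[key] = bs.combine([shocks[key], producer]) if key in shocks else producer
        impacts[key] = impact if key not in impacts else _add_impacts(
            impacts[key], impact)
        logger.info(
            "scenario %s / %s: shock %.2f -> output %.2f, jobs %.0f",
            name, key, producer.total, impact.x_D.sum(), impact.jobs_total.sum(),
        )

    if shocks:
        combined_shock = bs.combine(list(shocks.values()))
        total_base = sum(s.total_cost for s in specs) or 1.0
        combined = compute_impact(system, combined_shock, total_base,
                                  sectors=economy.sectors)
    else:
        zero = np.zeros(economy.n)
        combined = compute_impact(
            system, ShockVector(zero, basis="producer_domestic"), 1.0,
            sectors=economy.sectors)

    return Scenario(
        name=name, economy=economy, profiles=tuple(profiles), bridge=bridge,
        specs=tuple(specs), shocks=shocks, impacts=impacts, combined=combined,
        system=system,
    )


def _add_impacts(a: ImpactResult, b: ImpactResult) -> ImpactResult:
    return ImpactResult(
        sectors=a.sectors,
        x_D=a.x_D + b.x_D,
        jobs_direct=a.jobs_direct + b.jobs_direct,
        jobs_indirect=a.jobs_indirect + b.jobs_indirect,
        jobs_induced=a.jobs_induced + b.jobs_induced,
        va=a.va + b.va,
        delta_u=a.delta_u + b.delta_u,
        base_spend=a.base_spend + b.base_spend,
    )


def exclusive_in_kind(baseline: Scenario,
                      copay_policy: str = "keep_ratio") -> Scenario:
    """Re-run the baseline with the whole budget granted as in-kind services.

    ``copay_policy="keep_ratio"`` preserves the baseline's aggregate
    public/co-payment split; ``"all_public"`` treats the entire budget as
    public spending (no consumption offset).
    """
    if baseline.total_spend <= 0:
        raise ValidationError("baseline scenario has no spending to reallocate")
    public = sum(s.public_spend for s in baseline.specs)
    copay = sum(s.copayment for s in baseline.specs)
    if copay_policy == "all_public":
        public, copay = public + copay, 0.0
    elif copay_policy != "keep_ratio":
        raise ValidationError("copay_policy must be 'keep_ratio' or 'all_public'")
    targets = [s.target_sector for s in baseline.specs]
    spec = BenefitSpec(benefit_type="in_kind", public_spend=public,
                       copayment=copay, target_sector=targets[0])
    return run_scenario(
        baseline.economy, baseline.profiles, [spec], bridge=baseline.bridge,
        name="exclusive_in_kind",
    )


def compare(baseline, counterfactual) -> Comparison:
    """Absolute deltas and percent changes of the scenario totals.

    Accepts scenarios, :class:`ImpactResult` objects or plain total mappings.
    Deltas are counterfactual minus baseline; percent change is relative to
    the baseline.
    """
    base = baseline.totals() if hasattr(baseline, "totals") else dict(baseline)
    cf = (counterfactual.totals() if hasattr(counterfactual, "totals")
          else dict(counterfactual))
    keys = [k for k in _TOTAL_KEYS if k in base and k in cf]
    rows = []
    for key in keys:
        b, c = float(base[key]), float(cf[key])
        rows.append({
            "quantity": key,
            "baseline": b,
            "counterfactual": c,
            "delta": c - b,
            "pct_change": (c - b) / b * 100.0 if b != 0 else np.nan,
        })
    return Comparison(pd.DataFrame(rows).set_index("quantity"))


def shares_report(table, round_to: int | None = None):
    """Percentage shares of a results table or vector (columns sum to 100).

    A Series (or 1-D array) is normalised by its own total; a DataFrame is
    normalised column by column.
    """
    if isinstance(table, pd.DataFrame):
        totals = table.sum(axis=0)
        shares = table.divide(totals, axis=1) * 100.0
    else:
        series = pd.Series(table, dtype=float)
        shares = series / series.sum() * 100.0
    if round_to is not None:
        shares = shares.map(lambda v: round_half_up(v, round_to)) \
            if isinstance(shares, pd.Series) \
            else shares.apply(lambda col: col.map(lambda v: round_half_up(v, round_to)))
    return shares


def fixture_summary(fixture: PublishedTables) -> dict:
    """Recompute the published headline statistics from the packaged tables.

    Pure report arithmetic on the fixture: totals, shares, per-million
    multipliers, producer-price retention and counterfactual deltas.
    """
    sector_rows = fixture.output_value_added.drop(index="Total")
    benefit_jobs = fixture.employment["total"]
    benefit_output = pd.Series({
        "cbpa": fixture.output_value_added.loc["Total", "cbpa_output"],
        "cbic": fixture.output_value_added.loc["Total", "cbic_output"],
        "in_kind": fixture.output_value_added.loc["Total", "in_kind_output"],
    })
    benefit_va = pd.Series({
        "cbpa": fixture.output_value_added.loc["Total", "cbpa_value_added"],
        "cbic": fixture.output_value_added.loc["Total", "cbic_value_added"],
        "in_kind": fixture.output_value_added.loc["Total", "in_kind_value_added"],
    })
    cbic_va_components = fixture.value_added_components.loc["cbic"]
    comparison = compare(fixture.simulation["benefit_mix"].to_dict(),
                         fixture.simulation["exclusive_in_kind"].to_dict())
    cbic_cost = fixture.spend.loc["cbic", "initial_cost"]
    return {
        "total_jobs": float(benefit_jobs.sum()),
        "global_output": float(sector_rows["global_output"].sum()),
        "in_kind_employment_share_pct": float(shares_report(benefit_jobs)["in_kind"]),
        "in_kind_output_share_pct": float(shares_report(benefit_output)["in_kind"]),
        "cbic_value_added_share_pct": float(shares_report(benefit_va)["cbic"]),
        "cbic_gos_share_pct": float(shares_report(cbic_va_components)["gos"]),
        "cbic_retention_pct": float(
            fixture.spend.loc["cbic", "producer_domestic_consumption"]
            / cbic_cost * 100.0),
        "cbic_output_multiplier": per_million(
            float(fixture.output_value_added.loc["Total", "cbic_output"]), cbic_cost),
        "cbic_jobs_per_million": per_million(
            float(fixture.employment.loc["cbic", "total"]), cbic_cost),
        "jobs_delta": comparison.delta("jobs_total"),
        "jobs_delta_pct": comparison.pct_change("jobs_total"),
        "output_delta": comparison.delta("output"),
    }
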