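"""Synthetic economies, household profiles and benefit specs.

The generator emulates the structural features the analysis relies on, for a
16-sector open economy: a productive coefficient matrix (spectral radius well
below one, Hawkins-Simon satisfied by construction), strictly positive value
added in every sector split into wages, social contributions, gross operating
surplus and net taxes on production, positive sectoral employment, a labour
force exceeding baseline employment, a dependent-household consumption
profile skewed toward necessity sectors (trade, accommodation/food and real
estate analogues), and employed/unemployed profiles that are similar but not
identical.  Public/co-payment splits of the benefit costs fall in the
50.9-54.8% public range observed in the Spanish long-term-care system.

Construction guarantees rather than samples the key properties:

* the coefficient matrix is a random positive matrix rescaled to the target
  spectral radius, so productivity holds by construction;
* gross output is derived as ``x = (I - A)^{-1} f`` from a strictly positive
  final-demand draw, so flows, outputs and final demand are mutually
  consistent with positive value added;
* the unemployment benefit is a 0.4-0.6 fraction of the economy-wide mean
  wage, capped below the cheapest sector's wage per job so that benefit-financed
  consumption per head stays below employed consumption in every sector (the
  monotonicity condition that orders the open, demo-economic and type-II
  multipliers).

The module also packages the published aggregate tables as CSV fixtures,
exactly as printed (including a 0.03 rounding inconsistency in the global
value-added column), so report arithmetic can be checked against them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .benefit_shocks import BenefitSpec
from .economy_io import PURCHASER, ConsumptionProfile, Economy
from .exceptions import InfeasibleConfigError, ValidationError

# ratio of employer social contributions to wages, and net production taxes
# as a share of value added; loosely Spanish national-accounts proportions
_SC_TO_WAGES = 0.24
_NTP_SHARE = 0.02


def _check_fraction_range(name: str, rng_pair) -> tuple[float, float]:
    lo, hi = float(rng_pair[0]), float(rng_pair[1])
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValidationError(f"{name} must be an ordered sub-interval of [0, 1]")
    return lo, hi


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic economy generator."""

    n_sectors: int = 16
    seed: int = 0
    target_spectral_radius: float = 0.6
    wage_share_range: tuple = (0.45, 0.60)
    labour_intensity_range: tuple = (2.0, 20.0)
    necessity_skew: float = 0.5
    copay_share_range: tuple = (0.452, 0.491)
    import_share_range: tuple = (0.05, 0.30)
    margin_rate_range: tuple = (0.0, 0.15)
    benefit_wage_fraction_range: tuple = (0.4, 0.6)

    def __post_init__(self) -> None:
        if self.n_sectors < 1:
            raise ValidationError("n_sectors must be >= 1")
        if not (0.0 <= self.target_spectral_radius < 1.0):
            raise ValidationError("target_spectral_radius must lie in [0, 1)")
        for name in ("wage_share_range", "copay_share_range",
                     "import_share_range", "margin_rate_range",
                     "benefit_wage_fraction_range"):
            _check_fraction_range(name, getattr(self, name))
        if not (0.0 <= self.necessity_skew <= 1.0):
            raise ValidationError("necessity_skew must lie in [0, 1]")
        lo, hi = self.labour_intensity_range
        if not (0.0 < lo <= hi):
            raise ValidationError("labour_intensity_range must be positive")
        # wages + proportional social contributions + net production taxes
        # must leave room for a positive gross operating surplus
        if self.wage_share_range[1] * (1.0 + _SC_TO_WAGES) + _NTP_SHARE >= 1.0:
            raise InfeasibleConfigError(
                "wage share range forces negative gross operating surplus: "
                f"max wage share {self.wage_share_range[1]:.3f} with "
                f"contributions ratio {_SC_TO_WAGES} and production-tax share "
                f"{_NTP_SHARE} exceeds value added"
            )


#: fraction of gross income re-spent on consumption in the default closure
DEFAULT_CONSUMPTION_PROPENSITY = 0.65


def _consistent_labour_force(config, A, f_other, w_x, l_d, w_U, y_S,
                             slack: float) -> float:
    """Labour force leaving positive unemployment in the closed baseline.

    Solves the fixed point ``p = slack * l_d x(p)`` of the closed model with
    the generator's companion profiles and price bridge, so the baseline
    equilibrium has an unemployment rate of roughly ``1 - 1/slack``.  Small
    economies without profiles fall back to a fixed margin over direct jobs.
    """
    n = config.n_sectors
    if n < 3:
        x = np.linalg.solve(np.eye(n) - A, f_other)
        return float(slack * l_d @ x)
    from .economy_io import to_producer_domestic

    _, emp, unemp = generate_profiles(config)
    bridge = generate_price_bridge(config)
    prop = DEFAULT_CONSUMPTION_PROPENSITY
    c_E = prop * to_producer_domestic(emp.shares, bridge).values
    c_U = prop * to_producer_domestic(unemp.shares, bridge).values
    M = np.eye(n) - A - np.outer(c_E, w_x) + w_U * np.outer(c_U, l_d)
    base = np.linalg.solve(M, f_other + c_E * y_S)
    per_p = np.linalg.solve(M, c_U * w_U)
    a = float(l_d @ base)
    b = float(l_d @ per_p)
    if slack * b >= 1.0:  # pragma: no cover - benefit term never this large
        raise InfeasibleConfigError("benefit feedback exceeds labour demand")
    return slack * a / (1.0 - slack * b)


def necessity_sectors(n_sectors: int) -> list[int]:
    """Indices of the necessity-good sectors (trade, accommodation, real estate).

    For the canonical 16-sector scheme these are the S6, S8 and S11 analogues;
    smaller economies (>= 3 sectors) use their first three sectors.
    """
    if n_sectors < 3:
        raise ValidationError(
            "necessity sectors are undefined for economies with < 3 sectors")
    if n_sectors >= 11:
        return [5, 7, 10]
    return [0, 1, 2]


def care_sector_index(n_sectors: int) -> int:
    """Index of the social-work (formal care) sector: S15 when available."""
    return 14 if n_sectors >= 15 else n_sectors - 1


def generate_economy(config: SyntheticConfig) -> Economy:
    """Generate a consistent synthetic economy; deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_sectors
    target = config.target_spectral_radius

    care = care_sector_index(n)
    estate = 10 if n >= 11 else None

    if target == 0.0:
        A = np.zeros((n, n))
    else:
        for _ in range(100):
            B = rng.uniform(0.2, 1.0, size=(n, n))
            # goods sectors (primary/industry analogues, the first third) are
            # intermediate-input heavy; services are input-light; formal care
            # least of all (personal services are delivered by labour, not
            # supply chains)
            goods = max(1, n // 3)
            B[:, :goods] *= rng.uniform(1.15, 1.35, size=goods)
            B[:, goods:] *= rng.uniform(0.60, 0.85, size=n - goods)
            B[:, care] *= 0.5
            # intermediate demand is dominated by materials and energy, and
            # goods production sources mostly from other goods sectors
            # (~70% of industrial inputs), while services split their inputs
            # more evenly (~45% goods)
            B[:goods, :goods] *= 2.2
            B[goods:, :goods] *= 0.45
            B[:goods, goods:] *= 1.3
            B[goods:, goods:] *= 0.75
            rho = float(np.max(np.abs(np.linalg.eigvals(B))))
            A = B * (target / rho)
            if A.sum(axis=0).max() < 0.92:
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise InfeasibleConfigError(
                "could not draw a coefficient matrix with column sums < 0.92")

    f = rng.uniform(5000.0, 20000.0, size=n)
    x = np.linalg.solve(np.eye(n) - A, f)
    Z = A * x[np.newaxis, :]

    va = x - Z.sum(axis=0)
    wage_share = rng.uniform(*config.wage_share_range, size=n)
    # care remunerates labour above all; real-estate value added is almost
    # entirely capital income (gross operating surplus)
    wage_share[care] = config.wage_share_range[1]
    if estate is not None:
        wage_share[estate] = rng.uniform(0.08, 0.15)
    wages = wage_share * va
    social_contributions = _SC_TO_WAGES * wages
    net_taxes = _NTP_SHARE * va
    gos = va - wages - social_contributions - net_taxes
    if np.any(gos <= 0):
        raise InfeasibleConfigError("drawn shares leave non-positive surplus")

    lo, hi = config.labour_intensity_range
    # goods production is capital-intensive (few jobs per million euros),
    # services labour-intensive; formal care sustains roughly twice the jobs
    # of the economy average and real estate almost none
    goods = max(1, n // 3)
    l_d = rng.uniform(lo + 0.45 * (hi - lo), hi, size=n)
    l_d[:goods] = rng.uniform(lo, lo + 0.35 * (hi - lo), size=goods)
    l_d[care] = rng.uniform(2.1, 2.7) * (lo + hi) / 2.0
    if estate is not None:
        l_d[estate] = rng.uniform(0.1, 0.25) * (lo + hi) / 2.0
    jobs = l_d * x

    mean_wage = wages.sum() / jobs.sum()
    min_sector_wage = float(np.min(wages / jobs))
    frac = rng.uniform(*config.benefit_wage_fraction_range)
    w_U = min(frac * mean_wage, 0.7 * min_sector_wage)

    y_S = 0.25 * wages.sum()
    slack = rng.uniform(1.08, 1.18)
    labour_force = _consistent_labour_force(
        config, A, f, wages / np.where(x > 0, x, 1.0), l_d, w_U, y_S, slack)

    economy = Economy(
        sectors=[f"S{i + 1}" for i in range(n)],
        Z=Z,
        x=x,
        wages=wages,
        social_contributions=social_contributions,
        gos=gos,
        net_taxes_production=net_taxes,
        jobs=jobs,
        f_other=f,
        labour_force=float(labour_force),
        w_U=float(w_U),
        y_S=float(y_S),
    )
    return economy.validate()


def generate_profiles(config: SyntheticConfig, necessity: list[int] | None = None):
    """Generate (dependent, employed, unemployed) consumption profiles.

    The dependent profile places at least ``necessity_skew`` of its mass on
    the necessity sectors.  The unemployed profile is a small multiplicative
    tilt of the employed one — lower on accommodation/food, higher on real
    estate — which keeps the two similar (high rank correlation) but distinct.
    """
    n = config.n_sectors
    if necessity is None:
        necessity = necessity_sectors(n)
    if not necessity or any(not 0 <= k < n for k in necessity):
        raise ValidationError("necessity sector indices outside the scheme")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    other = [k for k in range(n) if k not in necessity]
    mass = min(1.0, config.necessity_skew + rng.uniform(0.02, 0.12))
    dep = np.zeros(n)
    dep[necessity] = mass * rng.dirichlet(np.full(len(necessity), 4.0))
    if other:
        dep[other] = (1.0 - mass) * rng.dirichlet(np.full(len(other), 3.0))
    dep /= dep.sum()

    emp = rng.dirichlet(np.full(n, 5.0))
    tilt = rng.uniform(0.9, 1.1, size=n)
    if n >= 11:
        tilt[7] = 0.87    # accommodation & food: unemployed spend less
        tilt[10] = 1.13   # real estate: unemployed spend more
    unemp = emp * tilt
    unemp /= unemp.sum()

    return (
        ConsumptionProfile(dep, basis=PURCHASER, household_class="dependent"),
        ConsumptionProfile(emp, basis=PURCHASER, household_class="employed"),
        ConsumptionProfile(unemp, basis=PURCHASER, household_class="unemployed"),
    )


def generate_price_bridge(config: SyntheticConfig) -> "PriceBridge":
    """Synthetic purchaser-to-producer conversion rates.

    Margins and taxes are drawn from the configured ranges and credited to the
    trade/transport analogues; import shares are drawn per sector, with the
    formal-care sector fully domestic (services carry no margins and are not
    imported) and the real-estate analogue mostly domestic.
    """
    from .economy_io import PriceBridge

    n = config.n_sectors
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    margin = rng.uniform(*config.margin_rate_range, size=n)
    tax = rng.uniform(0.02, 0.10, size=n)
    imports = rng.uniform(*config.import_share_range, size=n)
    care = care_sector_index(n)
    margin[care] = 0.0
    imports[care] = 0.0
    if n >= 11:
        imports[10] *= 0.3  # real estate: overwhelmingly domestic
        recipients = {"trade": (5, 0.7), "transport": (6, 0.3)}
        margin[[5, 6]] = 0.0  # margin sectors do not pay margins on themselves
    else:
        recipients = {"trade": (0, 1.0)}
        margin[0] = 0.0
    return PriceBridge(margin_rate=margin, tax_rate=tax, import_share=imports,
                       margin_recipients=recipients)


# published initial benefit costs, million euros (2012)
BENEFIT_COSTS = {"cbpa": 355.42, "cbic": 2305.12, "in_kind": 4544.85}


def generate_benefit_specs(config: SyntheticConfig,
                           totals: dict | None = None) -> list[BenefitSpec]:
    """Benefit specs with public/co-payment splits drawn from the configured range.

    Totals default to the published 2012 initial costs per benefit type.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    totals = dict(BENEFIT_COSTS if totals is None else totals)
    target = care_sector_index(config.n_sectors)
    specs = []
    for benefit, total in totals.items():
        copay_share = rng.uniform(*config.copay_share_range)
        copay = total * copay_share
        specs.append(BenefitSpec(
            benefit_type=benefit,
            public_spend=total - copay,
            copayment=copay,
            target_sector=target,
        ))
    return specs


# ---------------------------------------------------------------------------
# Published-table fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PublishedTables:
    """The published aggregate tables, verbatim as printed.

    ``output_value_added``: sectoral output and value added by benefit type (M euros,
    with the printed Total row).  ``employment``: per-benefit direct, indirect,
    induced and total jobs.  ``value_added_components``: per-benefit value-added component
    totals.  ``simulation``: benefit-mix vs exclusive-in-kind aggregates with
    deltas.  ``spend``: initial cost and producer-price domestic consumption
    per benefit (the in-kind initial cost is printed in two variants, kept in
    ``initial_cost`` and ``initial_cost_alt``).
    """

    output_value_added: pd.DataFrame
    employment: pd.DataFrame
    value_added_components: pd.DataFrame
    simulation: pd.DataFrame
    spend: pd.DataFrame


def _read_data(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("depio.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, **kwargs)


def published_tables() -> PublishedTables:
    """Load the packaged published tables (no recomputation)."""
    return PublishedTables(
        output_value_added=_read_data("output_value_added.csv", index_col="sector"),
        employment=_read_data("employment_totals.csv", index_col="benefit"),
        value_added_components=_read_data("value_added_components.csv", index_col="benefit"),
        simulation=_read_data("benefit_mix_simulation.csv", index_col="quantity"),
        spend=_read_data("spend.csv", index_col="benefit"),
    )
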