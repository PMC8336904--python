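"""Construction of the exogenous dependency-consumption vector c^D.

Three long-term-care benefit types are modelled:

* **in-kind services** — residential/day/home-help care bought directly from
  the social-work sector.  Public spending plus the household co-payment is
  injected into the care sector; the co-payment is financed by dependent
  households, so the same amount is withdrawn from their consumption basket,
  spread over the dependent profile.  The vector sums to the public spend.
* **CBPA** (cash benefit for personal assistance) — must be spent on formal
  care, so it is structurally identical to in-kind.
* **CBIC** (cash benefit for informal care) — paid to family caregivers and
  effectively household income: the full cost (public + co-payment) is spent
  across all sectors through the dependent profile, with no negative offset.

The care-sector injection is a payment for services, which carry no trade or
transport margins: when a shock is converted to producer prices only the
profile-distributed part passes through the price bridge, the injection is
carried over unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import yaml

from .economy_io import (
    PRODUCER_DOMESTIC,
    PURCHASER,
    ConsumptionProfile,
    PriceBridge,
    to_producer_domestic,
)
from .exceptions import BasisError, DimensionError, ValidationError

logger = logging.getLogger(__name__)

BENEFIT_TYPES = ("in_kind", "cbpa", "cbic")


@dataclass(frozen=True)
class BenefitSpec:
    """One benefit line: type, public spend and co-payment in million euros."""

    benefit_type: str
    public_spend: float
    copayment: float
    target_sector: int

    def __post_init__(self) -> None:
        if self.benefit_type not in BENEFIT_TYPES:
            raise ValidationError(f"unknown benefit type {self.benefit_type!r}")
        if self.public_spend < 0 or self.copayment < 0:
            raise ValidationError("public spend and co-payment must be >= 0")
        if self.target_sector < 0:
            raise ValidationError("target sector index must be >= 0")

    @property
    def total_cost(self) -> float:
        return self.public_spend + self.copayment


@dataclass(frozen=True)
class ShockVector:
    """Per-sector exogenous demand (million euros), possibly negative.

    ``convertible`` is the portion subject to purchaser-to-producer
    conversion; the remainder (the care-sector service injection) is exempt.
    """

    values: np.ndarray
    basis: str = PURCHASER
    provenance: tuple = ()
    convertible: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.convertible is None:
            object.__setattr__(self, "convertible", self.values.copy())
        else:
            object.__setattr__(
                self, "convertible", np.asarray(self.convertible, dtype=float))
        if self.convertible.shape != self.values.shape:
            raise DimensionError("convertible part must match shock dimension")

    @property
    def total(self) -> float:
        return float(self.values.sum())


def _check_profile(c_D: ConsumptionProfile, spec: BenefitSpec) -> None:
    if c_D.basis != PURCHASER:
        raise BasisError("benefit shocks are built from purchaser-basis profiles")
    if spec.target_sector >= len(c_D.shares):
        raise ValidationError(
            f"target sector {spec.target_sector} outside the sector scheme")


def _formal_care_shock(spec: BenefitSpec, c_D: ConsumptionProfile) -> ShockVector:
    _check_profile(c_D, spec)
    n = len(c_D.shares)
    injection = np.zeros(n)
    injection[spec.target_sector] = spec.total_cost
    offset = -spec.copayment * c_D.shares
    if spec.copayment > spec.public_spend:
        # no household budget constraint is enforced on the offset
        logger.warning(
            "%s co-payment (%.2f) exceeds public spend (%.2f); the offset on "
            "dependents' consumption is applied without a budget check",
            spec.benefit_type, spec.copayment, spec.public_spend,
        )
    return ShockVector(
        values=injection + offset,
        basis=PURCHASER,
        provenance=(spec,),
        convertible=offset,
    )


def build_in_kind(spec: BenefitSpec, c_D: ConsumptionProfile) -> ShockVector:
    """In-kind services: care-sector injection net of the co-payment offset."""
    if spec.benefit_type != "in_kind":
        raise ValidationError("spec is not an in_kind benefit")
    return _formal_care_shock(spec, c_D)


def build_cbpa(spec: BenefitSpec, c_D: ConsumptionProfile) -> ShockVector:
    """CBPA: structurally identical to in-kind (benefit tied to formal care)."""
    if spec.benefit_type != "cbpa":
        raise ValidationError("spec is not a cbpa benefit")
    return _formal_care_shock(spec, c_D)


def build_cbic(spec: BenefitSpec, c_D: ConsumptionProfile,
               include_copay_offset: bool = False) -> ShockVector:
    """CBIC: the full cost spent across all sectors through the dependent profile.

    By default the co-payment carries no negative offset (the transfer is
    household income and the co-payment returns to the same household circle);
    ``include_copay_offset=True`` switches to the formal-care treatment of the
    co-payment instead.
    """
    if spec.benefit_type != "cbic":
        raise ValidationError("spec is not a cbic benefit")
    _check_profile(c_D, spec)
    if include_copay_offset:
        values = spec.public_spend * c_D.shares - spec.copayment * c_D.shares
    else:
        values = spec.total_cost * c_D.shares
    return ShockVector(values=values, basis=PURCHASER, provenance=(spec,),
                       convertible=values.copy())


_BUILDERS = {"in_kind": build_in_kind, "cbpa": build_cbpa, "cbic": build_cbic}


def build_shock(spec: BenefitSpec, c_D: ConsumptionProfile) -> ShockVector:
    """Dispatch to the builder for the spec's benefit type."""
    return _BUILDERS[spec.benefit_type](spec, c_D)


def combine(shocks) -> ShockVector:
    """Elementwise sum of shocks sharing a basis; provenance concatenated."""
    shocks = list(shocks)
    if not shocks:
        raise ValidationError("cannot combine an empty list of shocks")
    basis = shocks[0].basis
    n = shocks[0].values.shape[0]
    for s in shocks[1:]:
        if s.basis != basis:
            raise BasisError(
                f"cannot combine shocks with bases {basis!r} and {s.basis!r}")
        if s.values.shape[0] != n:
            raise DimensionError("shock dimensions differ")
    return ShockVector(
        values=sum(s.values for s in shocks),
        basis=basis,
        provenance=tuple(p for s in shocks for p in s.provenance),
        convertible=sum(s.convertible for s in shocks),
    )


def convert_shock(shock: ShockVector, bridge: PriceBridge) -> ShockVector:
    """Convert a purchaser-basis shock to domestic producer prices.

    The convertible part goes through the price bridge; the exempt part (the
    care-sector service injection) is carried over unchanged.
    """
    if shock.basis == PRODUCER_DOMESTIC:
        raise BasisError("shock is already in producer_domestic basis")
    exempt = shock.values - shock.convertible
    converted = to_producer_domestic(shock.convertible, bridge).values
    return ShockVector(
        values=exempt + converted,
        basis=PRODUCER_DOMESTIC,
        provenance=shock.provenance,
        convertible=converted,
    )


def read_benefits(path, sectors=None) -> list[BenefitSpec]:
    """Read a benefits.yaml: list of {type, public_spend, copayment, target_sector}.

    ``target_sector`` may be a sector label (resolved against ``sectors``)
    or an integer index.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    specs = []
    for entry in entries:
        target = entry["target_sector"]
        if isinstance(target, str):
            if sectors is None:
                raise ValidationError(
                    "sector labels in benefits.yaml need a sector list")
            target = sectors.index(target)
        specs.append(BenefitSpec(
            benefit_type=entry["type"],
            public_spend=float(entry["public_spend"]),
            copayment=float(entry["copayment"]),
            target_sector=int(target),
        ))
    return specs
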