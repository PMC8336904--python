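"""Economy data bundle: containers, CSV round-trip, and data-layer transforms.

The central container is :class:`Economy`, a small open economy described by a
symmetric input-output table: a square matrix ``Z`` of domestic inter-industry
flows (million euros, producer prices), gross output ``x``, the four value-added
components (wages, social contributions, gross operating surplus, net taxes on
production), sectoral employment, residual final demand, and the scalars needed
by the demo-economic closure (labour force ``p``, unemployment benefit ``w_U``,
exogenous employed-household income ``y_S``).

The data-layer transforms mirror what national accountants do before an impact
analysis: aggregating a fine sector classification through bridge matrices,
converting purchaser-price expenditure to domestic producer prices (taxes off,
margins reallocated to the trade/transport sectors, imports off), and
normalising household expenditure into unit-sum consumption profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    DimensionError,
    DoubleConversionError,
    ValidationError,
)

logger = logging.getLogger(__name__)

PURCHASER = "purchaser"
PRODUCER_DOMESTIC = "producer_domestic"

HOUSEHOLD_CLASSES = ("dependent", "employed", "unemployed")
VA_COMPONENTS = ("wages", "social_contributions", "gos", "net_taxes_production")

_FLOWS_FILE = "flows.csv"
_VECTORS_FILE = "vectors.csv"
_SCALARS_FILE = "scalars.csv"


def _as_vector(values, n: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).reshape(-1)
    if arr.shape != (n,):
        raise DimensionError(f"{name}: expected length {n}, got {arr.shape}")
    return arr


@dataclass
class Economy:
    """A small open economy in producer prices (million euros).

    ``Z[i, j]`` is sales of sector ``i`` to sector ``j``.  ``f_other`` is final
    demand excluding dependent/employed/unemployed household consumption (the
    exogenous final demand of the model).  ``w_U`` is the average annual welfare
    benefit per unemployed person, stored in million euros per person so that
    ``w_U * u`` is in million euros.
    """

    sectors: list[str]
    Z: np.ndarray
    x: np.ndarray
    wages: np.ndarray
    social_contributions: np.ndarray
    gos: np.ndarray
    net_taxes_production: np.ndarray
    jobs: np.ndarray
    f_other: np.ndarray
    labour_force: float
    w_U: float
    y_S: float

    def __post_init__(self) -> None:
        n = len(self.sectors)
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape != (n, n):
            raise DimensionError(
                f"flow matrix: expected ({n}, {n}), got {self.Z.shape}"
            )
        for name in ("x", "wages", "social_contributions", "gos",
                     "net_taxes_production", "jobs", "f_other"):
            setattr(self, name, _as_vector(getattr(self, name), n, name))

    @property
    def n(self) -> int:
        return len(self.sectors)

    @property
    def value_added(self) -> np.ndarray:
        return (self.wages + self.social_contributions + self.gos
                + self.net_taxes_production)

    def validate(self) -> "Economy":
        """Check the structural invariants; return self if they hold."""
        neg = np.argwhere(self.Z < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative inter-industry flow at ({self.sectors[i]}, "
                f"{self.sectors[j]}): {self.Z[i, j]}"
            )
        active = (self.Z.sum(axis=0) + self.Z.sum(axis=1)) > 0
        if np.any(self.x[active] <= 0):
            raise ValidationError("gross output must be > 0 for sectors with flows")
        intermediate = self.Z.sum(axis=0)
        resid = self.value_added - (self.x - intermediate)
        scale = np.maximum(np.abs(self.x), 1.0)
        if np.any(np.abs(resid) > 1e-6 * scale):
            raise ValidationError(
                "value-added components do not sum to output minus "
                f"intermediate inputs (max residual {np.max(np.abs(resid)):.3g})"
            )
        if np.any(self.jobs < 0):
            raise ValidationError("jobs must be nonnegative")
        if self.labour_force < self.jobs.sum():
            raise ValidationError("labour force below baseline employment")
        return self


@dataclass(frozen=True)
class ConsumptionProfile:
    """Unit-sum per-sector expenditure shares for one household class."""

    shares: np.ndarray
    basis: str = PURCHASER
    household_class: str = "dependent"

    def __post_init__(self) -> None:
        object.__setattr__(self, "shares", np.asarray(self.shares, dtype=float))
        if self.household_class not in HOUSEHOLD_CLASSES:
            raise ValidationError(f"unknown household class {self.household_class!r}")
        if np.any(self.shares < 0):
            raise ValidationError("profile shares must be nonnegative")
        if abs(self.shares.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"profile shares must sum to 1 (got {self.shares.sum():.12f})"
            )


@dataclass(frozen=True)
class SectorSpend:
    """A per-sector expenditure vector carrying its price basis."""

    values: np.ndarray
    basis: str = PURCHASER

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class PriceBridge:
    """Per-sector rates for purchaser-to-domestic-producer conversion.

    ``margin_recipients`` maps a margin type ("trade", "transport", ...) to a
    ``(sector_index, weight)`` pair; the pooled margins are credited to those
    sectors with the given weights (weights sum to 1).
    """

    margin_rate: np.ndarray
    tax_rate: np.ndarray
    import_share: np.ndarray
    margin_recipients: dict = field(
        default_factory=lambda: {"trade": (0, 1.0)}
    )

    def __post_init__(self) -> None:
        for name in ("margin_rate", "tax_rate", "import_share"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        for name in ("margin_rate", "tax_rate", "import_share"):
            rate = getattr(self, name)
            if np.any(rate < 0) or np.any(rate > 1):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if np.any(self.margin_rate + self.tax_rate >= 1):
            raise ValidationError("margin_rate + tax_rate must be < 1 per sector")
        weights = sum(w for _, w in self.margin_recipients.values())
        if abs(weights - 1.0) > 1e-9:
            raise ValidationError("margin recipient weights must sum to 1")

    @classmethod
    def identity(cls, n: int) -> "PriceBridge":
        """A no-op bridge (all rates zero)."""
        z = np.zeros(n)
        return cls(margin_rate=z, tax_rate=z.copy(), import_share=z.copy())


@dataclass(frozen=True)
class BridgeMatrix:
    """Allocation matrix from a fine classification (rows) to coarse sectors."""

    M: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "M", np.asarray(self.M, dtype=float))
        if self.M.ndim != 2:
            raise DimensionError("bridge matrix must be 2-D")
        if np.any(self.M < 0) or np.any(self.M > 1):
            raise ValidationError("bridge entries must lie in [0, 1]")
        rowsums = self.M.sum(axis=1)
        bad = np.flatnonzero(np.abs(rowsums - 1.0) > 1e-9)
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"bridge row {i} sums to {rowsums[i]:.12f}, not 1"
            )

    @classmethod
    def identity(cls, n: int) -> "BridgeMatrix":
        return cls(np.eye(n))


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def write_economy(economy: Economy, path) -> None:
    """Write the CSV bundle (flows.csv, vectors.csv, scalars.csv) to ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    flows = pd.DataFrame(economy.Z, index=economy.sectors, columns=economy.sectors)
    flows.index.name = "sector"
    flows.to_csv(path / _FLOWS_FILE)
    vectors = pd.DataFrame(
        {
            "sector": economy.sectors,
            "output": economy.x,
            "wages": economy.wages,
            "social_contributions": economy.social_contributions,
            "gos": economy.gos,
            "net_taxes_production": economy.net_taxes_production,
            "jobs": economy.jobs,
            "final_demand_other": economy.f_other,
        }
    )
    vectors.to_csv(path / _VECTORS_FILE, index=False)
    scalars = pd.DataFrame(
        {
            "name": ["labour_force", "w_U", "y_S"],
            "value": [economy.labour_force, economy.w_U, economy.y_S],
        }
    )
    scalars.to_csv(path / _SCALARS_FILE, index=False)


def read_economy(path) -> Economy:
    """Read the CSV bundle written by :func:`write_economy` and validate it."""
    path = Path(path)
    for fname in (_FLOWS_FILE, _VECTORS_FILE, _SCALARS_FILE):
        if not (path / fname).exists():
            raise ValidationError(f"missing bundle file: {fname}")
    flows = pd.read_csv(path / _FLOWS_FILE, index_col=0,
                        float_precision="round_trip")
    vectors = pd.read_csv(path / _VECTORS_FILE, float_precision="round_trip")
    scalars = pd.read_csv(path / _SCALARS_FILE,
                          float_precision="round_trip").set_index("name")["value"]
    sectors = [str(s) for s in flows.index]
    if list(flows.columns) != sectors:
        raise DimensionError("flow matrix row and column sector lists differ")
    if list(vectors["sector"].astype(str)) != sectors:
        raise DimensionError(
            f"vectors.csv sector list ({len(vectors)}) does not match "
            f"flows.csv ({len(sectors)})"
        )
    economy = Economy(
        sectors=sectors,
        Z=flows.to_numpy(dtype=float),
        x=vectors["output"],
        wages=vectors["wages"],
        social_contributions=vectors["social_contributions"],
        gos=vectors["gos"],
        net_taxes_production=vectors["net_taxes_production"],
        jobs=vectors["jobs"],
        f_other=vectors["final_demand_other"],
        labour_force=float(scalars["labour_force"]),
        w_U=float(scalars["w_U"]),
        y_S=float(scalars["y_S"]),
    )
    return economy.validate()


def write_profiles(profiles, path) -> None:
    """Write dependent/employed/unemployed profiles to a profiles.csv."""
    dep, emp, unemp = profiles
    n = len(dep.shares)
    df = pd.DataFrame(
        {
            "sector": [f"S{i + 1}" for i in range(n)],
            "c_D": dep.shares,
            "c_E": emp.shares,
            "c_U": unemp.shares,
            "basis": dep.basis,
        }
    )
    df.to_csv(path, index=False)


def read_profiles(path):
    """Read profiles.csv into (dependent, employed, unemployed) profiles."""
    df = pd.read_csv(path, float_precision="round_trip")
    basis = str(df["basis"].iloc[0])
    return tuple(
        ConsumptionProfile(df[col].to_numpy(float), basis=basis, household_class=cls)
        for col, cls in (("c_D", "dependent"), ("c_E", "employed"),
                         ("c_U", "unemployed"))
    )


def read_bridge(path) -> BridgeMatrix:
    """Read a bridge matrix CSV (fine_code, then one column per coarse sector)."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return BridgeMatrix(df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def aggregate(fine, bridge_rows: BridgeMatrix, bridge_cols: BridgeMatrix | None = None):
    """Aggregate a fine-classification matrix or vector to coarse sectors.

    For a matrix, rows are mapped through ``bridge_rows`` and columns through
    ``bridge_cols`` (defaults to ``bridge_rows``); the grand total is conserved
    because every bridge row sums to one.
    """
    fine = np.asarray(fine, dtype=float)
    if fine.ndim == 1:
        if fine.shape[0] != bridge_rows.M.shape[0]:
            raise DimensionError("vector length does not match bridge rows")
        return bridge_rows.M.T @ fine
    if bridge_cols is None:
        bridge_cols = bridge_rows
    if fine.shape != (bridge_rows.M.shape[0], bridge_cols.M.shape[0]):
        raise DimensionError(
            f"matrix shape {fine.shape} does not match bridges "
            f"({bridge_rows.M.shape[0]}, {bridge_cols.M.shape[0]})"
        )
    return bridge_rows.M.T @ fine @ bridge_cols.M


def to_producer_domestic(spend, bridge: PriceBridge) -> SectorSpend:
    """Convert purchaser-price expenditure to domestic producer prices.

    Fixed sequence: (1) remove net taxes on products, (2) strip trade and
    transport margins and credit them to the margin-recipient sectors, and
    (3) remove the imported share.  The map is linear, so it commutes with
    summing shock components.
    """
    if isinstance(spend, SectorSpend):
        if spend.basis == PRODUCER_DOMESTIC:
            raise DoubleConversionError(
                "vector is already in producer_domestic basis"
            )
        values = spend.values
    else:
        values = np.asarray(spend, dtype=float)
    n = values.shape[0]
    if bridge.tax_rate.shape != (n,):
        raise DimensionError("price bridge dimension does not match vector")
    after_tax = values * (1.0 - bridge.tax_rate)
    margins = after_tax * bridge.margin_rate
    kept = after_tax - margins
    pool = margins.sum()
    for recipient, weight in bridge.margin_recipients.values():
        kept[recipient] += pool * weight
    domestic = kept * (1.0 - bridge.import_share)
    logger.info(
        "price conversion (taxes -> margins -> imports): "
        "%.4f -> %.4f -> %.4f -> %.4f",
        values.sum(), after_tax.sum(), kept.sum(), domestic.sum(),
    )
    return SectorSpend(domestic, basis=PRODUCER_DOMESTIC)


def normalize_profile(spend_by_sector, household_class: str,
                      basis: str = PURCHASER) -> ConsumptionProfile:
    """Turn nonnegative sectoral spending into a unit-sum consumption profile."""
    spend = np.asarray(spend_by_sector, dtype=float)
    if np.any(spend < 0):
        raise ValidationError("spending must be nonnegative")
    total = spend.sum()
    if total <= 0:
        raise ValidationError("total spending must be positive")
    return ConsumptionProfile(spend / total, basis=basis,
                              household_class=household_class)
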