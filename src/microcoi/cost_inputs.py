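"""Unit-cost estimation for micro-costing inputs.

Every resource consumed by a health service — drugs, disposables, durable
assets, utilities, and health-worker time — is reduced to a unit cost in
2016 Peruvian soles (PEN): per item for consumables, per minute for
durables (straight-line depreciation over useful life) and for staff
(opportunity cost of paid time). Unit costs collected from several
purchase records are summarised by their mean and sample SD after a
robust outlier screen.
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CATEGORIES",
    "ROLES",
    "CostInput",
    "PurchaseRecord",
    "DurableAsset",
    "HealthWorkerRole",
    "WorkTimeBasis",
    "AuditLog",
    "flag_outliers",
    "unit_cost_from_purchases",
    "depreciation_per_minute",
    "wage_per_minute",
    "worker_input_id",
    "load_cost_inputs",
    "load_purchases",
    "load_assets",
    "load_wages",
]

#: Seven resource categories of the per-session cost decomposition.
CATEGORIES = (
    "human_resources",
    "infrastructure",
    "equipment",
    "drugs",
    "medical_instruments",
    "disposable_materials",
    "utilities",
)

#: Six health-worker roles with clearly separated duties.
ROLES = (
    "receptionist",
    "file_staff",
    "cashier",
    "nurse",
    "physician",
    "pharmacist",
)

BASES = ("per_item", "per_minute")


class AuditLog:
    """Collects every silent correction applied by the pipeline.

    Outlier exclusions, probability renormalisations and SD fallbacks are
    recorded here so that a run report can disclose them.
    """

    def __init__(self) -> None:
        self.entries: list[str] = []

    def record(self, message: str) -> None:
        self.entries.append(message)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class WorkTimeBasis:
    """Working-time denominator used to convert salaries and asset costs to
    per-minute rates.

    Default: 8 h/day, 5 days/week, 52 weeks/year = 124,800 min/year
    (10,400 min/month), a standard full-time assumption.
    """

    hours_per_day: float = 8.0
    days_per_week: float = 5.0
    weeks_per_year: float = 52.0

    def __post_init__(self) -> None:
        for name in ("hours_per_day", "days_per_week", "weeks_per_year"):
            if getattr(self, name) <= 0:
                raise ValueError(f"WorkTimeBasis.{name} must be > 0")

    @property
    def minutes_per_year(self) -> float:
        return self.hours_per_day * 60.0 * self.days_per_week * self.weeks_per_year

    @property
    def minutes_per_month(self) -> float:
        return self.minutes_per_year / 12.0


@dataclass(frozen=True)
class PurchaseRecord:
    """One procurement record: a price paid for a volume of an input at a site."""

    input_id: str
    site: str
    price: float
    volume: float

    def __post_init__(self) -> None:
        if self.price < 0:
            raise ValueError(f"negative price for {self.input_id!r}")
        if self.volume <= 0:
            raise ValueError(f"non-positive volume for {self.input_id!r}")

    @property
    def unit_price(self) -> float:
        return self.price / self.volume


@dataclass(frozen=True)
class CostInput:
    """A priced resource with its unit-cost mean and SD (PEN 2016)."""

    input_id: str
    label: str
    category: str
    basis: str
    mean_unit_cost: float
    sd_unit_cost: float
    n_sources: int = 1

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for {self.input_id!r}; "
                f"expected one of {', '.join(CATEGORIES)}"
            )
        if self.basis not in BASES:
            raise ValueError(f"unknown basis {self.basis!r} for {self.input_id!r}")
        if self.mean_unit_cost < 0:
            raise ValueError(f"negative mean unit cost for {self.input_id!r}")
        if self.sd_unit_cost < 0:
            raise ValueError(f"negative SD for {self.input_id!r}")


@dataclass(frozen=True)
class DurableAsset:
    """A durable good costed by straight-line depreciation, no salvage value."""

    input_id: str
    total_cost: float
    useful_life: float  # years

    def __post_init__(self) -> None:
        if self.total_cost < 0:
            raise ValueError(f"negative total cost for {self.input_id!r}")
        if self.useful_life <= 0:
            raise ValueError(f"useful life must be > 0 for {self.input_id!r}")


@dataclass(frozen=True)
class HealthWorkerRole:
    """A health-worker role valued at the opportunity cost of paid time."""

    role: str
    monthly_salary: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(
                f"unknown role {self.role!r}; expected one of {', '.join(ROLES)}"
            )
        if self.monthly_salary < 0:
            raise ValueError(f"negative salary for {self.role!r}")


def worker_input_id(role: str) -> str:
    """Canonical resource identifier of a health-worker minute."""
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    return f"hcw_{role}"


def _leave_one_out_pass(values: Sequence[float]) -> list[float]:
    kept = []
    for i, v in enumerate(values):
        peers = list(values[:i]) + list(values[i + 1 :])
        if v < 3.0 * statistics.median(peers):
            kept.append(v)
    return kept


def flag_outliers(
    values: Sequence[float], log: AuditLog | None = None
) -> list[float]:
    """Drop values at least 3x the median of their peers.

    The leave-one-out screen (keep v iff v < 3 x median of the others) is
    iterated to a fixed point, so the result is idempotent. A single value
    has no peers and is always kept. If the rule would empty the list, the
    last non-empty retained set is returned and a warning is issued.
    """
    values = list(values)
    if not values:
        raise ValueError("no values")
    if any(v < 0 for v in values):
        raise ValueError("negative cost values")
    if len(values) == 1:
        return values

    current = values
    while True:
        kept = _leave_one_out_pass(current)
        if not kept:
            msg = f"outlier rule would discard all of {current}; keeping them"
            warnings.warn(msg)
            if log is not None:
                log.record(msg)
            return list(values) if current is values else current
        if len(kept) == len(current):
            return kept
        if log is not None:
            dropped = len(current) - len(kept)
            log.record(f"outlier rule dropped {dropped} value(s)")
        if len(kept) == 1:
            return kept
        current = kept


def unit_cost_from_purchases(
    records: Sequence[PurchaseRecord], log: AuditLog | None = None
) -> tuple[float, float, int]:
    """Summarise purchase records of one input into (mean, SD, n).

    Per-record unit prices (price/volume) are screened with
    :func:`flag_outliers`, then summarised by the mean and sample SD
    (n-1 denominator; SD is 0 when a single record is retained).
    """
    if not records:
        raise ValueError("no purchase records")
    ids = {r.input_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"mixed input_ids in purchase records: {sorted(ids)}")
    prices = [r.unit_price for r in records]
    retained = flag_outliers(prices, log=log)
    mean = statistics.fmean(retained)
    sd = statistics.stdev(retained) if len(retained) > 1 else 0.0
    return mean, sd, len(retained)


def depreciation_per_minute(
    asset: DurableAsset, basis: WorkTimeBasis = WorkTimeBasis()
) -> float:
    """Straight-line depreciation of a durable asset per working minute."""
    return asset.total_cost / (asset.useful_life * basis.minutes_per_year)


def wage_per_minute(
    role: HealthWorkerRole, basis: WorkTimeBasis = WorkTimeBasis()
) -> float:
    """Opportunity cost of one paid minute of a health worker."""
    return role.monthly_salary / basis.minutes_per_month


# ---------------------------------------------------------------------------
# CSV loaders
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path.name}: no records")
    return df


def _collect(path: Path, rows: Iterable, builder) -> list:
    """Build records row by row, reporting 1-based CSV line numbers on failure."""
    out, errors = [], []
    for idx, row in rows:
        try:
            out.append(builder(row))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {idx + 2}: {exc}")  # +2: header + 0-base
    if errors:
        raise ValueError(f"{path.name}: " + "; ".join(errors))
    return out


def load_cost_inputs(path: str | Path) -> list[CostInput]:
    """Read ``inputs.csv`` (input_id,label,category,basis,mean_unit_cost,
    sd_unit_cost,n_sources)."""
    cols = [
        "input_id",
        "label",
        "category",
        "basis",
        "mean_unit_cost",
        "sd_unit_cost",
        "n_sources",
    ]
    df = _read_csv(path, cols)
    return _collect(
        Path(path),
        df.iterrows(),
        lambda r: CostInput(
            input_id=str(r["input_id"]),
            label=str(r["label"]),
            category=str(r["category"]),
            basis=str(r["basis"]),
            mean_unit_cost=float(r["mean_unit_cost"]),
            sd_unit_cost=float(r["sd_unit_cost"]),
            n_sources=int(r["n_sources"]),
        ),
    )


def load_purchases(path: str | Path) -> list[PurchaseRecord]:
    """Read ``purchases.csv`` (input_id,site,price,volume)."""
    df = _read_csv(path, ["input_id", "site", "price", "volume"])
    return _collect(
        Path(path),
        df.iterrows(),
        lambda r: PurchaseRecord(
            input_id=str(r["input_id"]),
            site=str(r["site"]),
            price=float(r["price"]),
            volume=float(r["volume"]),
        ),
    )


def load_assets(path: str | Path) -> list[DurableAsset]:
    """Read ``assets.csv`` (input_id,total_cost,useful_life_years)."""
    df = _read_csv(path, ["input_id", "total_cost", "useful_life_years"])
    return _collect(
        Path(path),
        df.iterrows(),
        lambda r: DurableAsset(
            input_id=str(r["input_id"]),
            total_cost=float(r["total_cost"]),
            useful_life=float(r["useful_life_years"]),
        ),
    )


def load_wages(path: str | Path) -> list[HealthWorkerRole]:
    """Read ``wages.csv`` (role,monthly_salary)."""
    df = _read_csv(path, ["role", "monthly_salary"])
    return _collect(
        Path(path),
        df.iterrows(),
        lambda r: HealthWorkerRole(
            role=str(r["role"]), monthly_salary=float(r["monthly_salary"])
        ),
    )


def summarize_purchases(
    records: Sequence[PurchaseRecord],
    labels: Mapping[str, str] | None = None,
    categories: Mapping[str, str] | None = None,
    log: AuditLog | None = None,
) -> list[CostInput]:
    """Group purchase records by input and summarise each into a CostInput.

    ``categories`` maps input_id to its cost category (required); ``labels``
    is optional free text.
    """
    if categories is None:
        raise ValueError("categories mapping is required")
    by_id: dict[str, list[PurchaseRecord]] = {}
    for r in records:
        by_id.setdefault(r.input_id, []).append(r)
    out = []
    for input_id in sorted(by_id):
        mean, sd, n = unit_cost_from_purchases(by_id[input_id], log=log)
        out.append(
            CostInput(
                input_id=input_id,
                label=(labels or {}).get(input_id, input_id),
                category=categories[input_id],
                basis="per_item",
                mean_unit_cost=mean,
                sd_unit_cost=sd,
                n_sources=n,
            )
        )
    return out
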