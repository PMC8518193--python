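"""Per-session costing of the diagnosis appointment and the six treatments.

A service is an ordered list of activities; each activity consumes
resources (items, equipment-minutes, worker-minutes). The cost of one
session is the sum-product of resource quantities and unit costs,
decomposed into the seven cost categories. Point estimates use mean unit
costs; the Monte Carlo layer re-evaluates the identical sum-product on
each simulated unit-cost draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cost_inputs import CATEGORIES, ROLES, CostInput, worker_input_id

__all__ = [
    "SERVICES",
    "TREATMENTS",
    "Activity",
    "Service",
    "SessionCost",
    "activity_cost",
    "session_cost",
    "service_coefficients",
    "load_services",
    "session_cost_table",
]

#: The seven costed services: one diagnosis appointment plus six treatments
#: (three topical, three surgical).
SERVICES = (
    "diagnosis",
    "podophyllin",
    "imiquimod",
    "tca",
    "cryotherapy",
    "electrosurgery",
    "surgical_excision",
)

#: The six genital-warts treatment techniques.
TREATMENTS = SERVICES[1:]

#: Report labels matching the published category naming.
CATEGORY_LABELS = {
    "human_resources": "Human Resources",
    "infrastructure": "Infrastructure",
    "equipment": "Equipment",
    "drugs": "Drugs",
    "medical_instruments": "Medical instruments",
    "disposable_materials": "Disposable Materials",
    "utilities": "Water and Electricity",
}


@dataclass(frozen=True)
class Activity:
    """One step of a clinical visit, with its duration, performer and resources.

    ``resource_use`` maps input_id to the quantity consumed: units for
    per-item inputs, minutes for per-minute inputs. When ``performed_by``
    is set, the performing worker's minutes must equal ``duration``.
    """

    activity_id: str
    label: str = ""
    duration: float = 0.0
    performed_by: str | None = None
    resource_use: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError(f"negative duration in activity {self.activity_id!r}")
        for input_id, qty in self.resource_use.items():
            if qty < 0:
                raise ValueError(
                    f"negative quantity of {input_id!r} in activity {self.activity_id!r}"
                )
        if self.performed_by is not None:
            if self.performed_by not in ROLES:
                raise ValueError(
                    f"unknown role {self.performed_by!r} in activity {self.activity_id!r}"
                )
            wid = worker_input_id(self.performed_by)
            minutes = self.resource_use.get(wid)
            if minutes is not None and minutes != self.duration:
                raise ValueError(
                    f"activity {self.activity_id!r}: {wid} minutes ({minutes}) "
                    f"differ from duration ({self.duration})"
                )

    def effective_resource_use(self) -> dict[str, float]:
        """Resource use including the performer's minutes (from duration)."""
        use = dict(self.resource_use)
        if self.performed_by is not None:
            use.setdefault(worker_input_id(self.performed_by), self.duration)
        return use


@dataclass(frozen=True)
class Service:
    """A diagnosis appointment or one treatment technique."""

    service_id: str
    activities: tuple[Activity, ...]

    def __post_init__(self) -> None:
        if self.service_id not in SERVICES:
            raise ValueError(
                f"unknown service {self.service_id!r}; expected one of {SERVICES}"
            )
        if not self.activities:
            raise ValueError(f"service {self.service_id!r} has no activities")


@dataclass(frozen=True)
class SessionCost:
    """Cost of one session, total and by category; categories sum to total."""

    service_id: str
    total: float
    by_category: Mapping[str, float]

    def __post_init__(self) -> None:
        s = sum(self.by_category.values())
        if abs(s - self.total) > 1e-9 * max(1.0, abs(self.total)):
            raise ValueError(
                f"category decomposition ({s}) does not match total ({self.total})"
            )


def _index_inputs(unit_costs: Sequence[CostInput] | Mapping[str, CostInput]) -> Mapping[str, CostInput]:
    if isinstance(unit_costs, Mapping):
        return unit_costs
    return {ci.input_id: ci for ci in unit_costs}


def activity_cost(
    activity: Activity,
    unit_costs: Sequence[CostInput] | Mapping[str, CostInput],
) -> dict[str, float]:
    """Cost of one activity by category: sum of quantity x mean unit cost.

    Worker minutes accumulate into ``human_resources`` through the worker's
    per-minute CostInput.
    """
    index = _index_inputs(unit_costs)
    out = {c: 0.0 for c in CATEGORIES}
    for input_id, qty in activity.effective_resource_use().items():
        ci = index.get(input_id)
        if ci is None:
            raise KeyError(
                f"activity {activity.activity_id!r} uses unknown input {input_id!r}"
            )
        out[ci.category] += qty * ci.mean_unit_cost
    return out


def session_cost(
    service: Service,
    unit_costs: Sequence[CostInput] | Mapping[str, CostInput],
) -> SessionCost:
    """Cost of one session of a service: element-wise sum over its activities."""
    by_category = {c: 0.0 for c in CATEGORIES}
    for activity in service.activities:
        for cat, value in activity_cost(activity, unit_costs).items():
            by_category[cat] += value
    return SessionCost(
        service_id=service.service_id,
        total=sum(by_category.values()),
        by_category=by_category,
    )


def service_coefficients(
    service: Service,
    input_order: Sequence[str],
    unit_costs: Sequence[CostInput] | Mapping[str, CostInput],
) -> dict[str, np.ndarray]:
    """Per-category linear coefficients of a service's session cost.

    Returns, for each category, a vector ``a`` over ``input_order`` such that
    the category's session cost equals ``a . u`` for any unit-cost vector
    ``u``. This is what makes Monte Carlo re-evaluation a matrix product.
    """
    index = _index_inputs(unit_costs)
    pos = {input_id: i for i, input_id in enumerate(input_order)}
    coeffs = {c: np.zeros(len(input_order)) for c in CATEGORIES}
    for activity in service.activities:
        for input_id, qty in activity.effective_resource_use().items():
            ci = index.get(input_id)
            if ci is None:
                raise KeyError(
                    f"activity {activity.activity_id!r} uses unknown input {input_id!r}"
                )
            if input_id not in pos:
                raise KeyError(f"input {input_id!r} missing from input_order")
            coeffs[ci.category][pos[input_id]] += qty
    return coeffs


def load_services(path: str | Path) -> dict[str, Service]:
    """Read ``services.yaml``: per service a list of activities with
    ``duration_min``, ``performed_by`` and ``resources: {input_id: quantity}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise ValueError(f"{Path(path).name}: no services")
    services = {}
    for service_id, activities in raw.items():
        acts = []
        for i, a in enumerate(activities):
            acts.append(
                Activity(
                    activity_id=a.get("id", f"{service_id}_{i}"),
                    label=a.get("label", ""),
                    duration=float(a.get("duration_min", 0.0)),
                    performed_by=a.get("performed_by"),
                    resource_use=dict(a.get("resources", {})),
                )
            )
        services[service_id] = Service(service_id=service_id, activities=tuple(acts))
    return services


def session_cost_table(
    costs: Mapping[str, SessionCost],
    intervals: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Session-cost report: rows = seven categories + total, columns = services.

    ``intervals`` optionally carries simulated 95% bounds per service keyed
    by category name plus ``"total"``; when present, cells are rendered as
    ``point (low, high)`` strings, otherwise as numbers.
    """
    cols = [s for s in SERVICES if s in costs]
    rows = {}
    for cat in CATEGORIES:
        row = []
        for s in cols:
            point = costs[s].by_category[cat]
            if intervals is not None:
                lo, hi = intervals[s][cat]
                row.append(f"{point:.2f} ({lo:.2f}, {hi:.2f})")
            else:
                row.append(point)
        rows[CATEGORY_LABELS[cat]] = row
    total_row = []
    for s in cols:
        point = costs[s].total
        if intervals is not None:
            lo, hi = intervals[s]["total"]
            total_row.append(f"{point:.2f} ({lo:.2f}, {hi:.2f})")
        else:
            total_row.append(point)
    rows["Cost per session"] = total_row
    return pd.DataFrame(rows, index=cols).T
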