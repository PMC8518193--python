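"""The 180-compartment treatment-allocation model.

Cases are cross-classified by patient gender (2), case type (3: new,
resistant, recurrent), attending physician's specialty (5) and treatment
technique received (6), giving 2 x 3 x 5 x 6 = 180 compartments. Each
compartment carries a probability — the product of the case distribution
over (gender, case type, specialty) and the treatment-choice probability
given the physician's specialty (optionally also case type and gender) —
and an annual per-patient cost. The average annual treatment cost is the
probability-weighted average over compartments.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cost_inputs import AuditLog
from .session_costing import TREATMENTS

__all__ = [
    "GENDERS",
    "CASE_TYPES",
    "SPECIALTIES",
    "Compartment",
    "CaseDistribution",
    "TreatmentChoice",
    "TreatmentProtocol",
    "SessionCount",
    "enumerate_compartments",
    "compartment_probabilities",
    "annual_cost_per_patient",
    "average_treatment_cost",
    "table2_summaries",
    "load_case_distribution",
    "load_treatment_choice",
    "load_protocol",
]

GENDERS = ("male", "female")
CASE_TYPES = ("new", "resistant", "recurrent")
#: Five physician groups; general practitioners and family medicine are
#: merged into primary care.
SPECIALTIES = (
    "primary_care",
    "gynecology",
    "urology",
    "dermatology",
    "infectious_disease",
)


class Compartment(NamedTuple):
    gender: str
    case_type: str
    specialty: str
    treatment: str


def enumerate_compartments() -> list[Compartment]:
    """All 180 (gender, case type, specialty, treatment) combinations, in
    stable lexicographic order of the canonical category orders."""
    return [
        Compartment(g, c, s, t)
        for g, c, s, t in itertools.product(GENDERS, CASE_TYPES, SPECIALTIES, TREATMENTS)
    ]


@dataclass(frozen=True)
class CaseDistribution:
    """Probability table over (gender, case_type, specialty) triples."""

    table: Mapping[tuple[str, str, str], float]

    def __post_init__(self) -> None:
        for key, p in self.table.items():
            g, c, s = key
            if g not in GENDERS or c not in CASE_TYPES or s not in SPECIALTIES:
                raise ValueError(f"unknown case-distribution key {key}")
            if p < 0:
                raise ValueError(f"negative probability for {key}")
        if sum(self.table.values()) <= 0:
            raise ValueError("case distribution has zero total mass")

    def normalized(self) -> "CaseDistribution":
        total = sum(self.table.values())
        return CaseDistribution({k: v / total for k, v in self.table.items()})

    def prob(self, gender: str, case_type: str, specialty: str) -> float:
        return self.table.get((gender, case_type, specialty), 0.0)


@dataclass(frozen=True)
class TreatmentChoice:
    """Conditional probability of each treatment given the physician's
    specialty, optionally refined by case type and gender.

    ``conditioning`` names the keys a row conditions on, in order; coarser
    tables broadcast over the omitted keys. Each conditional row is
    normalised on access.
    """

    table: Mapping[tuple, Mapping[str, float]]
    conditioning: tuple[str, ...] = ("specialty",)

    _ALLOWED = ("specialty", "case_type", "gender")

    def __post_init__(self) -> None:
        for key in self.conditioning:
            if key not in self._ALLOWED:
                raise ValueError(f"unknown conditioning key {key!r}")
        for cond, row in self.table.items():
            if len(cond) != len(self.conditioning):
                raise ValueError(f"conditioning key {cond} has wrong arity")
            for t, p in row.items():
                if t not in TREATMENTS:
                    raise ValueError(f"unknown treatment {t!r}")
                if p < 0:
                    raise ValueError(f"negative probability for {cond}/{t}")
            if sum(row.values()) <= 0:
                raise ValueError(f"zero-mass treatment-choice row for {cond}")

    def prob(
        self, treatment: str, specialty: str, case_type: str, gender: str
    ) -> float:
        values = {"specialty": specialty, "case_type": case_type, "gender": gender}
        cond = tuple(values[k] for k in self.conditioning)
        row = self.table.get(cond)
        if row is None:
            raise KeyError(f"no treatment-choice row for {cond}")
        total = sum(row.values())
        return row.get(treatment, 0.0) / total


@dataclass(frozen=True)
class SessionCount:
    """Mean number of sessions with its (min, max) range."""

    mean: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError(
                f"session counts must satisfy min <= mean <= max, got "
                f"({self.min}, {self.mean}, {self.max})"
            )
        if self.mean < 1:
            raise ValueError("session counts are >= 1")


@dataclass(frozen=True)
class TreatmentProtocol:
    """Sessions per course by treatment and case type, and recurrent-episode
    frequency by gender.

    ``recurrent_uses`` selects which course length a recurrent episode
    follows ("new" by default). Fractional mean session counts are used
    as-is: they are expectations, not prescriptions.
    """

    sessions_new: Mapping[str, SessionCount]
    sessions_resistant: Mapping[str, SessionCount]
    episodes_recurrent_per_year: Mapping[str, float]
    recurrent_uses: str = "new"

    def __post_init__(self) -> None:
        for table in (self.sessions_new, self.sessions_resistant):
            for t in table:
                if t not in TREATMENTS:
                    raise ValueError(f"unknown treatment {t!r} in protocol")
        for g, e in self.episodes_recurrent_per_year.items():
            if g not in GENDERS:
                raise ValueError(f"unknown gender {g!r} in protocol")
            if e <= 0:
                raise ValueError("episodes per year must be positive")
        if self.recurrent_uses not in ("new", "resistant"):
            raise ValueError("recurrent_uses must be 'new' or 'resistant'")

    def sessions(self, treatment: str, case_type: str) -> float:
        if case_type == "resistant":
            table = self.sessions_resistant
        elif case_type == "new":
            table = self.sessions_new
        elif case_type == "recurrent":
            table = (
                self.sessions_new
                if self.recurrent_uses == "new"
                else self.sessions_resistant
            )
        else:
            raise ValueError(f"unknown case type {case_type!r}")
        if treatment not in table:
            raise KeyError(f"treatment {treatment!r} missing from protocol")
        return table[treatment].mean

    def episodes(self, case_type: str, gender: str) -> float:
        if case_type == "recurrent":
            if gender not in self.episodes_recurrent_per_year:
                raise KeyError(f"no recurrent episode count for gender {gender!r}")
            return self.episodes_recurrent_per_year[gender]
        return 1.0


def compartment_probabilities(
    cases: CaseDistribution,
    choice: TreatmentChoice,
    log: AuditLog | None = None,
) -> dict[Compartment, float]:
    """Compose case-distribution and treatment-choice tables into compartment
    probabilities, renormalised to sum to 1.

    A warning is signalled when the pre-normalisation total deviates from 1
    by more than 1% (normally it cannot, since both factors are normalised,
    but tables loaded from rounded published figures may).
    """
    cases = cases.normalized()
    probs = {}
    for comp in enumerate_compartments():
        p_case = cases.prob(comp.gender, comp.case_type, comp.specialty)
        p_treat = choice.prob(comp.treatment, comp.specialty, comp.case_type, comp.gender)
        probs[comp] = p_case * p_treat
    total = sum(probs.values())
    if total <= 0:
        raise ValueError("compartment probabilities have zero total mass")
    if abs(total - 1.0) > 0.01:
        msg = f"compartment probabilities summed to {total:.4f} before renormalization"
        warnings.warn(msg)
        if log is not None:
            log.record(msg)
    return {c: p / total for c, p in probs.items()}


def annual_cost_per_patient(
    c: Compartment,
    session_costs: Mapping[str, float],
    diagnosis_cost: float,
    protocol: TreatmentProtocol,
) -> float:
    """Annual cost of one patient in a compartment.

    One treatment course costs the diagnosis appointment plus sessions x
    session cost; recurrent patients repeat the course once per episode
    (gender-specific episodes per year), new and resistant patients have
    one course.
    """
    if c.treatment not in session_costs:
        raise KeyError(f"no session cost for treatment {c.treatment!r}")
    sessions = protocol.sessions(c.treatment, c.case_type)
    episodes = protocol.episodes(c.case_type, c.gender)
    return episodes * (diagnosis_cost + sessions * session_costs[c.treatment])


def average_treatment_cost(
    probabilities: Mapping[Compartment, float],
    annual_costs: Mapping[Compartment, float],
    gender: str | None = None,
) -> float:
    """Probability-weighted average annual cost over compartments.

    With ``gender`` given, conditions on that gender (renormalising the
    probabilities within it).
    """
    comps = list(probabilities)
    if set(comps) != set(annual_costs):
        raise ValueError("probabilities and annual costs cover different compartments")
    if gender is not None:
        comps = [c for c in comps if c.gender == gender]
    mass = sum(probabilities[c] for c in comps)
    if mass <= 0:
        raise ValueError("zero probability mass")
    return sum(probabilities[c] * annual_costs[c] for c in comps) / mass


def table2_summaries(
    probabilities: Mapping[Compartment, float],
    annual_costs: Mapping[Compartment, float],
    protocol: TreatmentProtocol,
) -> pd.DataFrame:
    """Per-treatment summary: sessions, conditional mean annual cost, usage.

    Usage probability is the treatment's marginal over compartments; the
    annual cost is the probability-weighted mean conditional on the
    treatment.
    """
    rows = {}
    for t in TREATMENTS:
        comps = [c for c in probabilities if c.treatment == t]
        usage = sum(probabilities[c] for c in comps)
        if usage > 0:
            mean_cost = sum(probabilities[c] * annual_costs[c] for c in comps) / usage
        else:
            mean_cost = float("nan")
        sn = protocol.sessions_new[t]
        sr = protocol.sessions_resistant[t]
        rows[t] = {
            "sessions_new_mean": sn.mean,
            "sessions_new_min": sn.min,
            "sessions_new_max": sn.max,
            "sessions_resistant_mean": sr.mean,
            "sessions_resistant_min": sr.min,
            "sessions_resistant_max": sr.max,
            "annual_cost_mean": mean_cost,
            "usage_probability": usage,
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def load_case_distribution(path: str | Path) -> CaseDistribution:
    """Read ``case_distribution.csv`` (gender,case_type,specialty,probability)."""
    df = pd.read_csv(path)
    required = ["gender", "case_type", "specialty", "probability"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing required column(s) {missing}")
    table = {
        (str(r["gender"]), str(r["case_type"]), str(r["specialty"])): float(
            r["probability"]
        )
        for _, r in df.iterrows()
    }
    return CaseDistribution(table)


def load_treatment_choice(path: str | Path) -> TreatmentChoice:
    """Read ``treatment_choice.csv`` (specialty[,case_type,gender],treatment,
    probability); conditioning keys are inferred from the columns present."""
    df = pd.read_csv(path)
    if "specialty" not in df.columns or "treatment" not in df.columns:
        raise ValueError(
            f"{Path(path).name}: needs at least 'specialty' and 'treatment' columns"
        )
    conditioning = tuple(
        k for k in ("specialty", "case_type", "gender") if k in df.columns
    )
    table: dict[tuple, dict[str, float]] = {}
    for _, r in df.iterrows():
        cond = tuple(str(r[k]) for k in conditioning)
        table.setdefault(cond, {})[str(r["treatment"])] = float(r["probability"])
    return TreatmentChoice(table=table, conditioning=conditioning)


def load_protocol(
    protocol_path: str | Path,
    episodes_path: str | Path,
    recurrent_uses: str = "new",
) -> TreatmentProtocol:
    """Read ``protocol.csv`` (per-treatment session counts with ranges) and
    ``episodes.csv`` (gender,episodes_per_year)."""
    df = pd.read_csv(protocol_path)
    new, resistant = {}, {}
    for _, r in df.iterrows():
        t = str(r["treatment"])
        new[t] = SessionCount(
            float(r["sessions_new_mean"]),
            float(r["sessions_new_min"]),
            float(r["sessions_new_max"]),
        )
        resistant[t] = SessionCount(
            float(r["sessions_resistant_mean"]),
            float(r["sessions_resistant_min"]),
            float(r["sessions_resistant_max"]),
        )
    ep = pd.read_csv(episodes_path)
    episodes = {str(r["gender"]): float(r["episodes_per_year"]) for _, r in ep.iterrows()}
    return TreatmentProtocol(
        sessions_new=new,
        sessions_resistant=resistant,
        episodes_recurrent_per_year=episodes,
        recurrent_uses=recurrent_uses,
    )
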