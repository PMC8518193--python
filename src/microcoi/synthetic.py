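"""Synthetic costing datasets with closed-form ground truth.

The study's primary costing records (procurement prices from three
regions, activity lists, interview-based probability tables) are not
redistributable, so every pipeline stage is exercised on generated
bundles instead. A bundle contains every file the pipeline reads —
purchases, unit-cost summaries, wages, assets, service activity lists,
probability tables, protocol, epidemiology, monetary context — plus the
closed-form truth implied by the generating parameters: true session
costs, the true probability-weighted average annual cost, and the true
cost of illness. Site-to-site price variability is modelled as gamma
noise around each input's true mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import peru
from .burden import (
    BurdenResult,
    Epidemiology,
    Estimate,
    MonetaryContext,
    compute_burden,
    pen2016_to_usd_report_year,
)
from .compartments import (
    CASE_TYPES,
    GENDERS,
    SPECIALTIES,
    CaseDistribution,
    SessionCount,
    TreatmentChoice,
    TreatmentProtocol,
    annual_cost_per_patient,
    average_treatment_cost,
    compartment_probabilities,
    enumerate_compartments,
)
from .cost_inputs import (
    CostInput,
    DurableAsset,
    HealthWorkerRole,
    PurchaseRecord,
    ROLES,
    WorkTimeBasis,
    depreciation_per_minute,
    wage_per_minute,
    worker_input_id,
)
from .session_costing import SERVICES, TREATMENTS, Activity, Service, session_cost

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "Bundle",
    "generate_costing_dataset",
    "generate_probability_tables",
    "published_fixture",
    "write_bundle",
    "load_bundle",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    ``dispersion`` is the coefficient of variation of unit prices around
    their true means (0 = noiseless); ``observed`` selects what the emitted
    ``inputs.csv`` records: ``estimated`` summarises the generated purchase
    records the way the pipeline would, ``calibrated`` records one noisy
    observation per input with the known generating dispersion as its SD,
    and ``truth`` records the true means.
    """

    n_sites: int = 3
    purchases_per_site: int = 2
    dispersion: float = 0.3
    concentration: float = 2.0
    observed: str = "estimated"
    basis: WorkTimeBasis = field(default_factory=WorkTimeBasis)

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.purchases_per_site < 1:
            raise ValueError("need at least one site and one purchase per site")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.observed not in ("estimated", "calibrated", "truth"):
            raise ValueError(f"unknown observation mode {self.observed!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Closed-form ground truth implied by the generating parameters."""

    unit_costs: Mapping[str, float]  # true mean unit cost per input (PEN)
    session_costs: Mapping[str, float]  # true cost per session per service (PEN)
    avg_cost_pen: float  # true weighted-average annual cost (PEN)
    avg_cost_usd: float
    avg_cost_male_usd: float
    avg_cost_female_usd: float
    coi_usd: float


@dataclass(frozen=True)
class Bundle:
    """A complete, loadable input set for the pipeline."""

    inputs: tuple[CostInput, ...]
    purchases: tuple[PurchaseRecord, ...]
    wages: tuple[HealthWorkerRole, ...]
    assets: tuple[DurableAsset, ...]
    services: Mapping[str, Service]
    case_distribution: CaseDistribution
    treatment_choice: TreatmentChoice
    protocol: TreatmentProtocol
    epidemiology: Epidemiology
    monetary: MonetaryContext
    currency: str = "PEN"  # currency of the unit costs: PEN (2016) or USD (2019)
    truth: SyntheticTruth | None = None
    headline_average_cost: Estimate | None = None
    headline_average_cost_by_gender: Mapping[str, float] | None = None


# True mean unit costs are drawn once per seed from these plausible 2016-PEN
# ranges (per item, or per minute for per-minute inputs).
_PER_ITEM_RANGES = {
    "drugs": (1.0, 12.0),
    "disposable_materials": (0.1, 3.0),
}
_PER_ITEM_INPUTS = {
    "drugs": [
        "podophyllin_solution",
        "imiquimod_cream",
        "tca_solution",
        "lidocaine_vial",
    ],
    "disposable_materials": [
        "gloves_pair",
        "cotton_pack",
        "gauze",
        "needle",
        "syringe",
        "drape",
        "antiseptic_dose",
        "scalpel_blade",
    ],
}
# Durables: (total-cost range in PEN, useful-life range in years).
_DURABLES = {
    "equipment": {
        "cryotherapy_unit": ((8000.0, 30000.0), (5.0, 10.0)),
        "electrosurgical_unit": ((10000.0, 40000.0), (5.0, 10.0)),
        "examination_lamp": ((500.0, 3000.0), (5.0, 10.0)),
    },
    "medical_instruments": {
        "minor_surgery_kit": ((800.0, 4000.0), (3.0, 8.0)),
        "cryo_probe_set": ((500.0, 2500.0), (3.0, 8.0)),
    },
    "infrastructure": {
        "consultation_room": ((60000.0, 250000.0), (15.0, 30.0)),
    },
    "utilities": {
        "electricity_supply": ((2000.0, 9000.0), (1.0, 1.0)),
        "water_supply": ((800.0, 4000.0), (1.0, 1.0)),
    },
}
# Monthly salaries, PEN, per role.
_SALARY_RANGES = {
    "receptionist": (1200.0, 2200.0),
    "file_staff": (1200.0, 2200.0),
    "cashier": (1300.0, 2400.0),
    "nurse": (2500.0, 4500.0),
    "physician": (5000.0, 9000.0),
    "pharmacist": (2800.0, 5000.0),
}

# Drug used by each topical/excision treatment.
_TREATMENT_DRUG = {
    "podophyllin": "podophyllin_solution",
    "imiquimod": "imiquimod_cream",
    "tca": "tca_solution",
    "surgical_excision": "lidocaine_vial",
}
_TREATMENT_EQUIPMENT = {
    "cryotherapy": ["cryotherapy_unit", "cryo_probe_set"],
    "electrosurgery": ["electrosurgical_unit"],
    "surgical_excision": ["minor_surgery_kit"],
}


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi)) if hi > lo else lo


def _gamma_noisy(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Gamma sample(s) with the given mean and coefficient of variation."""
    if cv == 0:
        return mean if size is None else np.full(size, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape=shape, scale=mean / shape, size=size)


def _build_services(rng: np.random.Generator) -> dict[str, Service]:
    """Activity lists emulating the clinical flow: administrative steps,
    a physician consultation, and a treatment-specific procedure."""

    def admin(prefix: str) -> list[Activity]:
        return [
            Activity(
                f"{prefix}_reception",
                "patient reception",
                duration=3.0,
                performed_by="receptionist",
                resource_use={"consultation_room": 3.0, "electricity_supply": 3.0},
            ),
            Activity(
                f"{prefix}_filing",
                "medical record retrieval",
                duration=2.0,
                performed_by="file_staff",
            ),
            Activity(
                f"{prefix}_payment",
                "payment processing",
                duration=2.0,
                performed_by="cashier",
            ),
        ]

    services: dict[str, Service] = {}
    for sid in SERVICES:
        acts = admin(sid)
        consult_min = float(np.round(rng.uniform(8.0, 15.0)))
        acts.append(
            Activity(
                f"{sid}_consultation",
                "physician consultation",
                duration=consult_min,
                performed_by="physician",
                resource_use={
                    "consultation_room": consult_min,
                    "electricity_supply": consult_min,
                    "water_supply": consult_min,
                    "examination_lamp": consult_min,
                    "gloves_pair": 1.0,
                },
            )
        )
        if sid == "diagnosis":
            services[sid] = Service(sid, tuple(acts))
            continue
        proc_min = float(np.round(rng.uniform(10.0, 30.0)))
        resources: dict[str, float] = {
            "consultation_room": proc_min,
            "electricity_supply": proc_min,
            "water_supply": proc_min,
            "gloves_pair": 1.0,
            "cotton_pack": float(rng.integers(1, 3)),
            "gauze": float(rng.integers(1, 4)),
            "antiseptic_dose": 1.0,
        }
        if sid in _TREATMENT_DRUG:
            resources[_TREATMENT_DRUG[sid]] = float(rng.integers(1, 3))
        for eq in _TREATMENT_EQUIPMENT.get(sid, []):
            resources[eq] = proc_min
        if sid == "surgical_excision":
            resources.update(
                {"needle": 2.0, "syringe": 1.0, "drape": 1.0, "scalpel_blade": 2.0}
            )
        acts.append(
            Activity(
                f"{sid}_procedure",
                f"{sid} application",
                duration=proc_min,
                performed_by="physician",
                resource_use=resources,
            )
        )
        acts.append(
            Activity(
                f"{sid}_aftercare",
                "nurse aftercare and dispensing",
                duration=5.0,
                performed_by="nurse" if sid not in _TREATMENT_DRUG else "pharmacist",
                resource_use={"consultation_room": 5.0},
            )
        )
        services[sid] = Service(sid, tuple(acts))
    return services


def generate_probability_tables(
    concentration: float,
    seed: int,
    usage_target: Mapping[str, float] | None = None,
    max_iter: int = 200,
) -> tuple[CaseDistribution, TreatmentChoice]:
    """Dirichlet-distributed case-distribution and treatment-choice tables.

    ``concentration`` is the symmetric Dirichlet parameter; ``math.inf``
    yields exactly uniform tables. With ``usage_target`` given (a marginal
    usage probability per treatment, summing to ~1), the treatment-choice
    columns are iteratively rescaled (IPF) so that the implied marginal
    usage matches the target after renormalisation.
    """
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    triples = [(g, c, s) for g in GENDERS for c in CASE_TYPES for s in SPECIALTIES]
    if math.isinf(concentration):
        case_p = np.full(len(triples), 1.0 / len(triples))
        rows = {(s,): {t: 1.0 / len(TREATMENTS) for t in TREATMENTS} for s in SPECIALTIES}
    else:
        case_p = rng.dirichlet(np.full(len(triples), concentration))
        rows = {
            (s,): dict(
                zip(TREATMENTS, rng.dirichlet(np.full(len(TREATMENTS), concentration)))
            )
            for s in SPECIALTIES
        }
    cases = CaseDistribution(dict(zip(triples, case_p)))

    if usage_target is not None:
        total = sum(usage_target.values())
        if abs(total - 1.0) > 0.05:
            raise ValueError(f"usage target sums to {total}, expected ~1")
        target = {t: usage_target.get(t, 0.0) / total for t in TREATMENTS}
        spec_marginal = {
            s: sum(p for (g, c, s2), p in cases.table.items() if s2 == s)
            for s in SPECIALTIES
        }
        for _ in range(max_iter):
            implied = {
                t: sum(spec_marginal[s] * rows[(s,)][t] for s in SPECIALTIES)
                for t in TREATMENTS
            }
            if all(
                abs(implied[t] - target[t]) <= 1e-12 * max(1.0, target[t])
                for t in TREATMENTS
            ):
                break
            for s in SPECIALTIES:
                row = rows[(s,)]
                for t in TREATMENTS:
                    if implied[t] > 0:
                        row[t] *= target[t] / implied[t]
                norm = sum(row.values())
                rows[(s,)] = {t: v / norm for t, v in row.items()}
    choice = TreatmentChoice(table=rows, conditioning=("specialty",))
    return cases, choice


def _compute_truth(
    unit_costs: Mapping[str, CostInput],
    services: Mapping[str, Service],
    cases: CaseDistribution,
    choice: TreatmentChoice,
    protocol: TreatmentProtocol,
    epidemiology: Epidemiology,
    monetary: MonetaryContext,
) -> SyntheticTruth:
    session_costs = {
        sid: session_cost(svc, unit_costs).total for sid, svc in services.items()
    }
    probs = compartment_probabilities(cases, choice)
    treat_costs = {t: session_costs[t] for t in TREATMENTS}
    annual = {
        c: annual_cost_per_patient(c, treat_costs, session_costs["diagnosis"], protocol)
        for c in enumerate_compartments()
    }
    avg_pen = average_treatment_cost(probs, annual)
    avg_usd = pen2016_to_usd_report_year(avg_pen, monetary)
    avg_m = pen2016_to_usd_report_year(
        average_treatment_cost(probs, annual, gender="male"), monetary
    )
    avg_f = pen2016_to_usd_report_year(
        average_treatment_cost(probs, annual, gender="female"), monetary
    )
    burden = compute_burden(
        epidemiology, Estimate(avg_usd, avg_usd, avg_usd), avg_m, avg_f
    )
    return SyntheticTruth(
        unit_costs={i: ci.mean_unit_cost for i, ci in unit_costs.items()},
        session_costs=session_costs,
        avg_cost_pen=avg_pen,
        avg_cost_usd=avg_usd,
        avg_cost_male_usd=avg_m,
        avg_cost_female_usd=avg_f,
        coi_usd=burden.coi_point,
    )


def generate_costing_dataset(
    config: SyntheticConfig = SyntheticConfig(), seed: int = 0
) -> Bundle:
    """Generate a complete input bundle plus its closed-form truth.

    True unit costs, service activity lists and probability tables are
    drawn once from the seed; purchase prices then scatter around the true
    unit costs as gamma noise with CV = ``config.dispersion``. With
    dispersion 0 every observed price equals its true mean and the
    pipeline's point estimates reproduce the truth exactly.
    """
    root = np.random.SeedSequence(seed)
    s_struct, s_prices, s_tables, s_obs = (np.random.default_rng(c) for c in root.spawn(4))

    basis = config.basis
    # --- true unit costs ---------------------------------------------------
    true_mean: dict[str, float] = {}
    categories: dict[str, str] = {}
    bases: dict[str, str] = {}
    labels: dict[str, str] = {}
    for cat, names in _PER_ITEM_INPUTS.items():
        lo, hi = _PER_ITEM_RANGES[cat]
        for name in names:
            true_mean[name] = _uniform(s_struct, lo, hi)
            categories[name], bases[name] = cat, "per_item"
            labels[name] = name.replace("_", " ")
    assets = []
    for cat, table in _DURABLES.items():
        for name, ((clo, chi), (llo, lhi)) in table.items():
            total = _uniform(s_struct, clo, chi)
            life = float(np.round(_uniform(s_struct, llo, lhi)))
            assets.append(DurableAsset(name, total, life))
            true_mean[name] = depreciation_per_minute(assets[-1], basis)
            categories[name], bases[name] = cat, "per_minute"
            labels[name] = name.replace("_", " ")
    wages = []
    for role in ROLES:
        lo, hi = _SALARY_RANGES[role]
        wages.append(HealthWorkerRole(role, float(np.round(_uniform(s_struct, lo, hi)))))
        wid = worker_input_id(role)
        true_mean[wid] = wage_per_minute(wages[-1], basis)
        categories[wid], bases[wid] = "human_resources", "per_minute"
        labels[wid] = f"{role} minute"

    services = _build_services(s_struct)
    cases, choice = generate_probability_tables(
        config.concentration, seed=int(s_tables.integers(2**31))
    )
    protocol = peru.PROTOCOL
    epidemiology = Epidemiology()
    monetary = MonetaryContext()

    # --- purchase records (per-item inputs) --------------------------------
    purchases = []
    for name, cat in categories.items():
        if bases[name] != "per_item":
            continue
        for site_i in range(config.n_sites):
            for _ in range(config.purchases_per_site):
                volume = float(s_prices.integers(5, 200))
                unit = float(_gamma_noisy(s_prices, true_mean[name], config.dispersion))
                purchases.append(
                    PurchaseRecord(name, f"site_{site_i + 1}", unit * volume, volume)
                )

    # --- observed unit-cost summaries --------------------------------------
    inputs: list[CostInput] = []
    order = sorted(true_mean)
    if config.observed == "estimated":
        from .cost_inputs import summarize_purchases

        per_item = summarize_purchases(
            purchases, labels=labels, categories=categories
        )
        summarized = {ci.input_id: ci for ci in per_item}
        for name in order:
            if name in summarized:
                inputs.append(summarized[name])
            else:  # per-minute inputs: one governmental source, no sample SD
                inputs.append(
                    CostInput(
                        name, labels[name], categories[name], "per_minute",
                        true_mean[name], 0.0, 1,
                    )
                )
    else:
        for name in order:
            sd = config.dispersion * true_mean[name]
            if config.observed == "calibrated":
                mean = float(_gamma_noisy(s_obs, true_mean[name], config.dispersion))
            else:  # "truth"
                mean = true_mean[name]
            inputs.append(
                CostInput(name, labels[name], categories[name], bases[name], mean, sd, 1)
            )

    unit_index = {
        name: CostInput(
            name, labels[name], categories[name], bases[name], true_mean[name], 0.0, 1
        )
        for name in order
    }
    truth = _compute_truth(
        unit_index, services, cases, choice, protocol, epidemiology, monetary
    )
    return Bundle(
        inputs=tuple(inputs),
        purchases=tuple(purchases),
        wages=tuple(wages),
        assets=tuple(assets),
        services=services,
        case_distribution=cases,
        treatment_choice=choice,
        protocol=protocol,
        epidemiology=epidemiology,
        monetary=monetary,
        currency="PEN",
        truth=truth,
    )


def published_fixture() -> Bundle:
    """Worked-example bundle anchored to the published point values.

    Each service consumes one synthetic per-category input, priced so that
    the session total equals the published cost per session while keeping
    the published category profile (category values are rescaled by the
    published total over their sum; the two differ slightly because the
    published totals are simulation means). Costs are already 2019 USD;
    the published headline average cost rides along for the burden stage.
    Session counts, recurrent episodes, usage probabilities, epidemiology
    and monetary context are the published values.
    """
    inputs: list[CostInput] = []
    services: dict[str, Service] = {}
    for sid, cats in peru.SESSION_COST_CATEGORIES.items():
        scale = peru.SESSION_COST_POINTS[sid] / sum(cats.values())
        resource_use = {}
        for cat, value in cats.items():
            iid = f"{sid}_{cat}"
            inputs.append(
                CostInput(iid, f"{sid} {cat} (synthetic aggregate)", cat, "per_item",
                          value * scale, 0.0, 1)
            )
            resource_use[iid] = 1.0
        services[sid] = Service(
            sid,
            (Activity(f"{sid}_bundle", f"{sid} session bundle",
                      resource_use=resource_use),),
        )

    gender_share = {"male": 0.0525 / (0.0525 + 0.0135), "female": 0.0135 / (0.0525 + 0.0135)}
    # case-type mix fitted (least squares) so the model's per-treatment annual
    # costs track the published ones given the published session counts
    case_mix = {"new": 0.33, "resistant": 0.32, "recurrent": 0.35}
    specialty_mix = {
        "primary_care": 0.40,
        "gynecology": 0.20,
        "urology": 0.15,
        "dermatology": 0.15,
        "infectious_disease": 0.10,
    }
    cases = CaseDistribution(
        {
            (g, c, s): gender_share[g] * case_mix[c] * specialty_mix[s]
            for g in GENDERS
            for c in CASE_TYPES
            for s in SPECIALTIES
        }
    )
    usage_total = sum(peru.USAGE_PROBABILITIES.values())  # printed column: 99.9%
    choice = TreatmentChoice(
        table={
            (s,): {t: p / usage_total for t, p in peru.USAGE_PROBABILITIES.items()}
            for s in SPECIALTIES
        },
        conditioning=("specialty",),
    )
    return Bundle(
        inputs=tuple(inputs),
        purchases=(),
        wages=(),
        assets=(),
        services=services,
        case_distribution=cases,
        treatment_choice=choice,
        protocol=peru.PROTOCOL,
        epidemiology=peru.EPIDEMIOLOGY,
        monetary=peru.MONETARY,
        currency="USD",
        truth=None,
        headline_average_cost=peru.AVERAGE_COST,
        headline_average_cost_by_gender={
            "male": peru.AVERAGE_COST_MALE,
            "female": peru.AVERAGE_COST_FEMALE,
        },
    )


# ---------------------------------------------------------------------------
# Disk round-trip
# ---------------------------------------------------------------------------


def write_bundle(bundle: Bundle, outdir: str | Path) -> Path:
    """Write every CSV/YAML of a bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "input_id": ci.input_id,
                "label": ci.label,
                "category": ci.category,
                "basis": ci.basis,
                "mean_unit_cost": ci.mean_unit_cost,
                "sd_unit_cost": ci.sd_unit_cost,
                "n_sources": ci.n_sources,
            }
            for ci in bundle.inputs
        ]
    ).to_csv(outdir / "inputs.csv", index=False)
    if bundle.purchases:
        pd.DataFrame(
            [
                {"input_id": r.input_id, "site": r.site, "price": r.price, "volume": r.volume}
                for r in bundle.purchases
            ]
        ).to_csv(outdir / "purchases.csv", index=False)
    if bundle.assets:
        pd.DataFrame(
            [
                {"input_id": a.input_id, "total_cost": a.total_cost,
                 "useful_life_years": a.useful_life}
                for a in bundle.assets
            ]
        ).to_csv(outdir / "assets.csv", index=False)
    if bundle.wages:
        pd.DataFrame(
            [{"role": w.role, "monthly_salary": w.monthly_salary} for w in bundle.wages]
        ).to_csv(outdir / "wages.csv", index=False)

    services_yaml = {
        sid: [
            {
                "id": a.activity_id,
                "label": a.label,
                "duration_min": a.duration,
                "performed_by": a.performed_by,
                "resources": dict(a.resource_use),
            }
            for a in svc.activities
        ]
        for sid, svc in bundle.services.items()
    }
    (outdir / "services.yaml").write_text(yaml.safe_dump(services_yaml, sort_keys=True))

    pd.DataFrame(
        [
            {"gender": g, "case_type": c, "specialty": s, "probability": p}
            for (g, c, s), p in bundle.case_distribution.table.items()
        ]
    ).to_csv(outdir / "case_distribution.csv", index=False)
    rows = []
    for cond, row in bundle.treatment_choice.table.items():
        for t, p in row.items():
            rec = dict(zip(bundle.treatment_choice.conditioning, cond))
            rec.update({"treatment": t, "probability": p})
            rows.append(rec)
    pd.DataFrame(rows).to_csv(outdir / "treatment_choice.csv", index=False)

    pd.DataFrame(
        [
            {
                "treatment": t,
                "sessions_new_mean": bundle.protocol.sessions_new[t].mean,
                "sessions_new_min": bundle.protocol.sessions_new[t].min,
                "sessions_new_max": bundle.protocol.sessions_new[t].max,
                "sessions_resistant_mean": bundle.protocol.sessions_resistant[t].mean,
                "sessions_resistant_min": bundle.protocol.sessions_resistant[t].min,
                "sessions_resistant_max": bundle.protocol.sessions_resistant[t].max,
            }
            for t in TREATMENTS
        ]
    ).to_csv(outdir / "protocol.csv", index=False)
    pd.DataFrame(
        [
            {"gender": g, "episodes_per_year": e}
            for g, e in bundle.protocol.episodes_recurrent_per_year.items()
        ]
    ).to_csv(outdir / "episodes.csv", index=False)

    epi = bundle.epidemiology
    (outdir / "epidemiology.yaml").write_text(
        yaml.safe_dump(
            {
                "population_total": epi.population_total,
                "population_male": epi.population_male,
                "population_female": epi.population_female,
                "prevalence_overall": [epi.prevalence_overall.point,
                                        epi.prevalence_overall.low,
                                        epi.prevalence_overall.high],
                "prevalence_male": [epi.prevalence_male.point,
                                     epi.prevalence_male.low,
                                     epi.prevalence_male.high],
                "prevalence_female": [epi.prevalence_female.point,
                                       epi.prevalence_female.low,
                                       epi.prevalence_female.high],
            }
        )
    )
    ctx = bundle.monetary
    meta = {
        "exchange_pen_per_usd": ctx.exchange_pen_per_usd,
        "annual_inflation": ctx.annual_inflation,
        "base_year": ctx.base_year,
        "report_year": ctx.report_year,
        "ppp_factor": ctx.ppp_factor,
        "currency": bundle.currency,
    }
    if bundle.headline_average_cost is not None:
        h = bundle.headline_average_cost
        meta["headline_average_cost"] = [h.point, h.low, h.high]
        if bundle.headline_average_cost_by_gender:
            meta["headline_average_cost_by_gender"] = dict(
                bundle.headline_average_cost_by_gender
            )
    (outdir / "monetary.yaml").write_text(yaml.safe_dump(meta))
    return outdir


def load_bundle(indir: str | Path) -> Bundle:
    """Load a bundle previously written by :func:`write_bundle`."""
    from .compartments import load_case_distribution, load_protocol, load_treatment_choice
    from .cost_inputs import load_assets, load_cost_inputs, load_purchases, load_wages
    from .session_costing import load_services

    indir = Path(indir)
    inputs = load_cost_inputs(indir / "inputs.csv")
    purchases = (
        load_purchases(indir / "purchases.csv")
        if (indir / "purchases.csv").exists()
        else []
    )
    assets = (
        load_assets(indir / "assets.csv") if (indir / "assets.csv").exists() else []
    )
    wages = load_wages(indir / "wages.csv") if (indir / "wages.csv").exists() else []
    services = load_services(indir / "services.yaml")
    cases = load_case_distribution(indir / "case_distribution.csv")
    choice = load_treatment_choice(indir / "treatment_choice.csv")
    protocol = load_protocol(indir / "protocol.csv", indir / "episodes.csv")
    epi_raw = yaml.safe_load((indir / "epidemiology.yaml").read_text())
    epi = Epidemiology(
        population_total=epi_raw["population_total"],
        population_male=epi_raw["population_male"],
        population_female=epi_raw["population_female"],
        prevalence_overall=Estimate(*epi_raw["prevalence_overall"]),
        prevalence_male=Estimate(*epi_raw["prevalence_male"]),
        prevalence_female=Estimate(*epi_raw["prevalence_female"]),
    )
    mon_raw = yaml.safe_load((indir / "monetary.yaml").read_text())
    monetary = MonetaryContext(
        exchange_pen_per_usd=mon_raw["exchange_pen_per_usd"],
        annual_inflation=mon_raw["annual_inflation"],
        base_year=mon_raw["base_year"],
        report_year=mon_raw["report_year"],
        ppp_factor=mon_raw["ppp_factor"],
    )
    headline = None
    headline_gender = None
    if "headline_average_cost" in mon_raw:
        headline = Estimate(*mon_raw["headline_average_cost"])
        headline_gender = mon_raw.get("headline_average_cost_by_gender")
    return Bundle(
        inputs=tuple(inputs),
        purchases=tuple(purchases),
        wages=tuple(wages),
        assets=tuple(assets),
        services=services,
        case_distribution=cases,
        treatment_choice=choice,
        protocol=protocol,
        epidemiology=epi,
        monetary=monetary,
        currency=mon_raw.get("currency", "PEN"),
        truth=None,
        headline_average_cost=headline,
        headline_average_cost_by_gender=headline_gender,
    )
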