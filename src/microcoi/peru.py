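"""Published reference inputs for the Peruvian genital-warts cost analysis.

These are the printed figures of the Peru Ministry-of-Health costing
study this package re-analyses: per-session treatment costs in 2019 USD,
treatment protocols (sessions per course, recurrent episodes per year),
marginal treatment-usage probabilities, the 2017 adult population and
survey prevalence, the monetary context, and the headline average-cost
and cost-of-illness estimates. They anchor worked examples and the
desk-check reproduction of the headline arithmetic; the raw costing
records behind them are not reproduced here.
"""

from __future__ import annotations

from .burden import Epidemiology, Estimate, MonetaryContext
from .compartments import SessionCount, TreatmentProtocol

__all__ = [
    "EPIDEMIOLOGY",
    "MONETARY",
    "SESSION_COST_POINTS",
    "SESSION_COST_INTERVALS",
    "SESSION_COST_CATEGORIES",
    "PROTOCOL",
    "USAGE_PROBABILITIES",
    "ANNUAL_COST_PER_TREATMENT",
    "AVERAGE_COST",
    "AVERAGE_COST_MALE",
    "AVERAGE_COST_FEMALE",
]

EPIDEMIOLOGY = Epidemiology()  # Peruvian defaults live on the type

MONETARY = MonetaryContext()

#: Published cost per session, 2019 USD (Monte Carlo means).
SESSION_COST_POINTS = {
    "diagnosis": 6.04,
    "podophyllin": 12.08,
    "imiquimod": 10.94,
    "tca": 10.84,
    "cryotherapy": 15.4,
    "electrosurgery": 17.44,
    "surgical_excision": 24.59,
}

#: Published 95% intervals of the cost per session, 2019 USD.
SESSION_COST_INTERVALS = {
    "diagnosis": (2.5, 11.8),
    "podophyllin": (7.4, 19.3),
    "imiquimod": (6.2, 18.3),
    "tca": (6.1, 18.2),
    "cryotherapy": (8.1, 26.8),
    "electrosurgery": (9.4, 29.3),
    "surgical_excision": (12.3, 57.6),
}

#: Published per-session category point costs, 2019 USD. Their sums differ
#: slightly from the per-session figures above (e.g. podophyllin categories
#: sum to 12.45 vs the printed 12.08 per session) — the published totals are
#: simulation means while category rows are point values; both are kept.
SESSION_COST_CATEGORIES = {
    "diagnosis": {
        "human_resources": 6.03,
        "infrastructure": 0.08,
        "disposable_materials": 0.05,
        "utilities": 0.07,
    },
    "podophyllin": {
        "human_resources": 9.21,
        "infrastructure": 0.09,
        "drugs": 1.06,
        "disposable_materials": 2.01,
        "utilities": 0.08,
    },
    "imiquimod": {
        "human_resources": 9.21,
        "infrastructure": 0.09,
        "drugs": 1.44,
        "disposable_materials": 0.46,
        "utilities": 0.08,
    },
    "tca": {
        "human_resources": 9.21,
        "infrastructure": 0.09,
        "drugs": 0.86,
        "disposable_materials": 0.93,
        "utilities": 0.08,
    },
    "cryotherapy": {
        "human_resources": 13.39,
        "infrastructure": 0.28,
        "equipment": 0.52,
        "disposable_materials": 1.47,
        "utilities": 0.22,
    },
    "electrosurgery": {
        "human_resources": 13.39,
        "infrastructure": 0.7,
        "equipment": 1.08,
        "medical_instruments": 0.19,
        "disposable_materials": 2.3,
        "utilities": 0.32,
    },
    "surgical_excision": {
        "human_resources": 13.86,
        "infrastructure": 0.44,
        "drugs": 0.96,
        "medical_instruments": 0.69,
        "disposable_materials": 9.23,
        "utilities": 0.19,
    },
}

#: Published sessions per course and recurrent-episode frequency
#: (1.7 episodes/year in males, 1.6 in females).
PROTOCOL = TreatmentProtocol(
    sessions_new={
        "podophyllin": SessionCount(3.2, 2.5, 3.7),
        "imiquimod": SessionCount(3.0, 2.5, 4.0),
        "tca": SessionCount(2.5, 1.6, 3.3),
        "cryotherapy": SessionCount(3.4, 2.8, 4.0),
        "electrosurgery": SessionCount(2.0, 1.1, 4.0),
        "surgical_excision": SessionCount(1.0, 1.0, 1.0),
    },
    sessions_resistant={
        "podophyllin": SessionCount(4.0, 4.0, 4.0),
        "imiquimod": SessionCount(2.7, 2.4, 3.0),
        "tca": SessionCount(5.3, 2.0, 8.0),
        "cryotherapy": SessionCount(5.1, 3.0, 6.2),
        "electrosurgery": SessionCount(2.1, 2.0, 2.3),
        "surgical_excision": SessionCount(1.0, 1.0, 1.0),
    },
    episodes_recurrent_per_year={"male": 1.7, "female": 1.6},
)

#: Published marginal probability of treatment usage. The printed column
#: sums to 99.9% (rounding); consumers renormalise.
USAGE_PROBABILITIES = {
    "podophyllin": 0.396,
    "imiquimod": 0.053,
    "tca": 0.164,
    "cryotherapy": 0.174,
    "electrosurgery": 0.203,
    "surgical_excision": 0.009,
}

#: Published annual average cost per treatment, 2019 USD.
ANNUAL_COST_PER_TREATMENT = {
    "podophyllin": 58.6,
    "imiquimod": 46.5,
    "tca": 52.7,
    "cryotherapy": 78.2,
    "electrosurgery": 55.5,
    "surgical_excision": 36.1,
}

#: Headline annual average treatment cost per patient, 2019 USD, with its
#: simulated 95% interval, and the gender-conditional averages.
AVERAGE_COST = Estimate(59.9, 45.5, 77.6)
AVERAGE_COST_MALE = 61.3
AVERAGE_COST_FEMALE = 58.9
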