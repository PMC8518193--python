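"""Population-level burden: prevalent cases, cost of illness, currencies.

The cost of illness (COI) under a prevalence-based approach is the product
of prevalent cases and the average annual treatment cost per patient. The
uncertainty range multiplies the lower (upper) 95% bounds of both the
prevalence and the cost. Costs collected in 2016 PEN are expressed in
report-year USD with a fixed exchange rate and constant annual inflation,
and optionally in international dollars via a PPP factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "Estimate",
    "Epidemiology",
    "MonetaryContext",
    "CaseCounts",
    "BurdenResult",
    "prevalent_cases",
    "coi_point",
    "coi_bounds",
    "pen2016_to_usd_report_year",
    "usd_to_intl_dollars",
    "compute_burden",
]


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its 95% interval."""

    point: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.point <= self.high):
            raise ValueError(
                f"interval must bracket the point: ({self.low}, {self.point}, {self.high})"
            )


@dataclass(frozen=True)
class Epidemiology:
    """Adult population by gender and genital-warts prevalence with 95% CIs.

    Defaults are the Peruvian 18-60-year-old population (2017) and the
    physician-survey prevalence estimates: 2.28% (2.02-2.56) overall,
    5.25% (4.46-6.13) in males, 1.35% (1.13-1.61) in females.
    """

    population_total: float = 18.4e6
    population_male: float = 9.3e6
    population_female: float = 9.1e6
    prevalence_overall: Estimate = field(
        default_factory=lambda: Estimate(0.0228, 0.0202, 0.0256)
    )
    prevalence_male: Estimate = field(
        default_factory=lambda: Estimate(0.0525, 0.0446, 0.0613)
    )
    prevalence_female: Estimate = field(
        default_factory=lambda: Estimate(0.0135, 0.0113, 0.0161)
    )

    def __post_init__(self) -> None:
        for name in ("prevalence_overall", "prevalence_male", "prevalence_female"):
            est = getattr(self, name)
            if not (0 <= est.low and est.high <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.population_total <= 0:
            raise ValueError("population must be positive")


@dataclass(frozen=True)
class MonetaryContext:
    """Fixed PEN/USD exchange, constant inflation, and PPP factor.

    Defaults: 3.3 PEN/USD, 2.5%/year inflation from base year 2016 to
    report year 2019, PPP factor 1.74 USD -> international dollars.
    """

    exchange_pen_per_usd: float = 3.3
    annual_inflation: float = 0.025
    base_year: int = 2016
    report_year: int = 2019
    ppp_factor: float = 1.74

    def __post_init__(self) -> None:
        if self.exchange_pen_per_usd <= 0 or self.ppp_factor <= 0:
            raise ValueError("exchange rate and PPP factor must be positive")
        if self.report_year < self.base_year:
            raise ValueError("report year precedes base year")


@dataclass(frozen=True)
class CaseCounts:
    male: float
    female: float

    @property
    def total(self) -> float:
        return self.male + self.female


ApportionMode = Literal["prevalence_ratio", "population_weighted_rescaled"]


def prevalent_cases(
    epi: Epidemiology, apportion: ApportionMode = "prevalence_ratio"
) -> CaseCounts:
    """Prevalent cases by gender.

    Total cases = population x overall prevalence. The default apportions
    the total between genders in the ratio of the gender-specific
    prevalences with equal gender weights (prevalence_ratio); the
    alternative weights each gender's prevalence by its own population and
    rescales to the same total. Counts are kept fractional; rounding to
    whole persons happens only at reporting.
    """
    total = epi.population_total * epi.prevalence_overall.point
    pm, pf = epi.prevalence_male.point, epi.prevalence_female.point
    if apportion == "prevalence_ratio":
        share_male = pm / (pm + pf)
    elif apportion == "population_weighted_rescaled":
        raw_m = epi.population_male * pm
        raw_f = epi.population_female * pf
        share_male = raw_m / (raw_m + raw_f)
    else:
        raise ValueError(f"unknown apportion mode {apportion!r}")
    return CaseCounts(male=total * share_male, female=total * (1 - share_male))


def coi_point(cases: float, avg_cost: float) -> float:
    """Cost of illness: prevalent cases x average annual cost per patient."""
    if cases < 0 or avg_cost < 0:
        raise ValueError("cases and cost must be non-negative")
    return cases * avg_cost


def coi_bounds(
    epi: Epidemiology, cost_interval: tuple[float, float]
) -> tuple[float, float]:
    """Product-of-bounds uncertainty range of the COI.

    Lower bound: population x prevalence 95% lower x cost 95% lower;
    upper bound analogously with the upper bounds.
    """
    cost_low, cost_high = cost_interval
    if cost_low > cost_high:
        raise ValueError("inverted cost interval")
    low = epi.population_total * epi.prevalence_overall.low * cost_low
    high = epi.population_total * epi.prevalence_overall.high * cost_high
    return low, high


def pen2016_to_usd_report_year(amount: float, ctx: MonetaryContext = MonetaryContext()) -> float:
    """Convert 2016 PEN to report-year USD: divide by the fixed exchange rate
    and inflate at the constant annual rate. Under a fixed rate the order of
    the two steps is immaterial."""
    if amount < 0:
        raise ValueError("negative amount")
    years = ctx.report_year - ctx.base_year
    return (amount / ctx.exchange_pen_per_usd) * (1 + ctx.annual_inflation) ** years


def usd_to_intl_dollars(amount: float, ctx: MonetaryContext = MonetaryContext()) -> float:
    """Convert USD to international dollars via the PPP factor."""
    if amount < 0:
        raise ValueError("negative amount")
    return amount * ctx.ppp_factor


@dataclass(frozen=True)
class BurdenResult:
    """Prevalent cases and the COI with its uncertainty range, in USD.

    ``to_intl`` rescales every money field by the PPP factor.
    """

    cases_male: float
    cases_female: float
    coi_point: float
    coi_low: float
    coi_high: float
    coi_male: float
    coi_female: float
    currency: str = "USD"

    def __post_init__(self) -> None:
        if not (self.coi_low <= self.coi_point <= self.coi_high):
            raise ValueError("COI bounds must bracket the point estimate")

    @property
    def cases_total(self) -> float:
        return self.cases_male + self.cases_female

    def to_intl(self, ctx: MonetaryContext = MonetaryContext()) -> "BurdenResult":
        if self.currency != "USD":
            raise ValueError("PPP conversion starts from USD")
        return replace(
            self,
            coi_point=usd_to_intl_dollars(self.coi_point, ctx),
            coi_low=usd_to_intl_dollars(self.coi_low, ctx),
            coi_high=usd_to_intl_dollars(self.coi_high, ctx),
            coi_male=usd_to_intl_dollars(self.coi_male, ctx),
            coi_female=usd_to_intl_dollars(self.coi_female, ctx),
            currency="intl.D",
        )


def compute_burden(
    epi: Epidemiology,
    avg_cost_usd: Estimate,
    avg_cost_male_usd: float | None = None,
    avg_cost_female_usd: float | None = None,
    apportion: ApportionMode = "prevalence_ratio",
) -> BurdenResult:
    """Assemble the burden summary from epidemiology and USD average costs.

    Gender-specific averages default to the overall point estimate.
    """
    cases = prevalent_cases(epi, apportion=apportion)
    male_cost = avg_cost_male_usd if avg_cost_male_usd is not None else avg_cost_usd.point
    female_cost = (
        avg_cost_female_usd if avg_cost_female_usd is not None else avg_cost_usd.point
    )
    low, high = coi_bounds(epi, (avg_cost_usd.low, avg_cost_usd.high))
    return BurdenResult(
        cases_male=cases.male,
        cases_female=cases.female,
        coi_point=coi_point(cases.total, avg_cost_usd.point),
        coi_low=low,
        coi_high=high,
        coi_male=coi_point(cases.male, male_cost),
        coi_female=coi_point(cases.female, female_cost),
    )
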