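# Methods

## Unit costs

Every resource is priced in 2016 PEN on one of two bases: per item
(consumed whole in a session — no reuse partitioning of disposables) or
per minute (durables and staff).

- **Purchases.** A unit price is price/volume per procurement record.
  Records for one input are screened for outliers — a value is dropped
  when it is at least 3× the median of the other values — and then
  summarised by the mean and sample SD (n−1 denominator; SD = 0 for a
  single retained record). The outlier rule names a threshold but not a
  reference statistic; we use the leave-one-out peer median, iterated to
  a fixed point so the screen is idempotent, with a guard that never
  returns an empty set (the previous retained set, with a warning, if the
  rule would discard everything). The mean/SD are computed over all
  records pooled across sites; site identity is kept only as provenance.
- **Durables.** Straight-line depreciation with zero salvage value:
  total cost / (useful life × minutes per year).
- **Staff.** Opportunity cost of paid time: monthly salary / minutes per
  month, for six roles (receptionist, file staff, cashier, nurse,
  physician, pharmacist).
- **Working-time basis.** The minutes denominator is not dictated by the
  data; the default is a standard full-time assumption of 8 h/day ×
  5 days/week × 52 weeks/year = 124,800 min/year (10,400 min/month),
  configurable via `WorkTimeBasis`.

## Session costing

A service is an ordered list of activities; each activity has a duration,
an optional performing health worker (whose minutes equal the duration),
and a resource-use vector. The session cost is the sum-product of
quantities and mean unit costs, accumulated into seven categories that
exactly conserve the total. Costs are linear in unit costs, which the
Monte Carlo layer exploits: per-category coefficients are assembled once
and each draw is a matrix product.

## Uncertainty propagation

Unit costs are simulated from gamma distributions matched to (mean, SD)
by the method of moments — the unique two-parameter solution. Inputs
with no sample variability (single source) get SD = 10⁻⁹, which makes
their simulated distribution numerically degenerate at the mean; SDs
below that floor are treated identically. Zero-mean inputs are carried
as constants, not gamma. 1,000 draws per input by default; each input
has its own deterministic substream spawned from the master seed
(`numpy` `SeedSequence`), so results are reproducible and adding an input
does not perturb the others' draws. Draws are independent across inputs:
no cost-correlation structure is imposed.

Summaries are the empirical 2.5% and 97.5% percentiles with linear
interpolation between order statistics (the 1 + (n−1)p convention; at
n = 1,000 the difference between quantile conventions is below reporting
precision), plus skewness and Pearson kurtosis (normal = 3), reported as
"95% uncertainty interval". With every SD at the floor, all simulated
summaries collapse onto the point estimate within 10⁻⁶ relative — the
deterministic limit. In degenerate runs the collapsed interval is widened
by a few ULP where necessary so that low ≤ point ≤ high always holds.

## Compartment model

180 compartments = gender (2) × case type (3) × specialty (5) ×
treatment (6). (Primary care merges general practitioners and family
medicine, hence five specialty groups.) Compartment probability is the
product of the case-distribution mass over (gender, case type,
specialty) and the treatment-choice probability conditioned on specialty
— the schema also accepts conditioning on specialty × case type × gender;
coarser tables broadcast. The product is renormalised to sum to 1 and a
warning is logged when the pre-normalisation total is off by more than 1%.

The annual per-patient cost of a compartment is
episodes × (diagnosis cost + sessions × session cost). Sessions per
course come from the protocol (fractional means used as-is — they are
expectations); new and resistant cases have one course per year,
recurrent cases repeat a course per episode (1.7/year male, 1.6 female),
each beginning with a diagnosis appointment. Recurrent episodes follow
the new-case course length by default (`recurrent_uses="new"`,
configurable to "resistant"): session counts are defined only for new
and resistant cases, and a recurrence is a new episode. The average
annual treatment cost is the probability-weighted average over
compartments, also available conditioned by gender (renormalising within
gender).

## Burden and currencies

Total prevalent cases = population × overall prevalence
(18.4M × 2.28% = 419,520 under the default Peruvian inputs). Gender
apportionment splits this total in the ratio of the gender-specific
prevalences with equal gender weights (5.25 : 1.35 → 333,709 male,
85,811 female). The alternative — weighting each gender's prevalence by
its own population and rescaling — is available as
`population_weighted_rescaled`; the two disagree because the
population-weighted gender prevalences imply ~611k cases, inconsistent
with the overall prevalence total, so the ratio split is the default and
the discrepancy is the user's to choose. Counts stay fractional
internally; rounding to whole persons happens at reporting.

COI point = total cases × average cost. The uncertainty range multiplies
the 95% bounds of prevalence and cost (lower×lower, upper×upper). This
product-of-bounds range is wider than a joint simulation interval would
be; it is the reporting convention adopted here.

Money: 2016 PEN → report-year USD by dividing by a fixed 3.3 PEN/USD and
inflating at 2.5%/year over 2016→2019 (order immaterial under a fixed
rate); USD → international dollars by the PPP factor 1.74. Reporting
precision: per-patient costs to 0.1 USD, COI to 0.1 million, cases to
whole persons.

## Synthetic data

The generator emulates the structure of a primary costing collection:

- ~26 inputs across the seven categories with true mean unit costs drawn
  once per seed from plausible 2016-PEN ranges (drugs 1–12 per unit,
  disposables 0.1–3, salaries 1,200–9,000/month, durables via
  depreciation), chosen so that human resources carry the bulk of a
  session's cost and the implied average annual cost lands in the tens
  of USD;
- purchase records at three sites, two per site, with unit prices
  gamma-distributed around the true mean at CV = `dispersion`
  (default 0.3; 0 = noiseless);
- fixed activity structures per service (reception, filing, payment,
  consultation, a treatment-specific procedure, aftercare/dispensing)
  with seeded durations and quantities;
- Dirichlet probability tables (symmetric concentration, default 2.0;
  infinite concentration yields exactly uniform tables), with optional
  iterative proportional fitting so the implied marginal treatment usage
  matches a supplied target vector.

Each bundle carries its closed-form truth (true session costs, weighted
average, COI), so the pipeline is checked by parameter recovery: at
dispersion 0 the point estimates reproduce the truth to 10⁻⁹ relative.

Three observation modes control what `inputs.csv` records: `estimated`
(summarise the generated purchases the way the pipeline would — the
default), `truth` (true means), and `calibrated` (one noisy observation
per input as the mean, with the known generating dispersion recorded as
the SD). The calibrated mode is the one-source situation in which the
gamma interval is frequentist-calibrated: the estimation error of the
recorded mean then matches the dispersion fed to the simulation, so the
95% percentile interval of the simulated average covers the true average
at close to the nominal rate (checked: 93–97% over 500 replications).
Under the default estimated mode the simulated spread reflects the full
price SD while the mean's sampling error shrinks with the number of
records, so that interval over-covers the truth — a property of this
class of probabilistic sensitivity analysis, not a defect of the
implementation.

What the generator does not emulate: real procurement records have
skewed volumes, site-level fixed effects (ours is independent noise
around a shared mean), correlated prices within supplier, and activity
lists vetted by clinical interviews. Passing recovery tests therefore
shows the arithmetic chain is right, not that the fixtures are clinically
faithful.

## The published-values fixture

`published_fixture()` builds a bundle whose session costs equal the
published per-session figures exactly (one aggregate input per service ×
category, rescaled so categories keep their published profile while
summing to the published total — the published category rows sum slightly
above the published per-session values, e.g. 12.45 vs 12.08 for
podophyllin, because the latter are simulation means). Protocol, episode
counts, usage probabilities (renormalised from the printed 99.9% total),
epidemiology and monetary context are the published values. The
case-type mix (new 0.33 / resistant 0.32 / recurrent 0.35) and an
illustrative specialty mix were fitted once, by least squares, so the
model's per-treatment annual costs track the published ones; the
case-distribution and treatment-choice detail behind the published
summaries is not public, so the fixture's model-implied average lands
near (≈58.8 USD) but deliberately not at the published 59.9 — the
published summary tables themselves do not reproduce that average by
sum-product. For that reason the fixture also carries the published
headline average (59.9, 95% UI 45.5–77.6; 61.3 male / 58.9 female),
which the burden stage uses when present (logged in the run report), so
the worked example reproduces the published burden arithmetic exactly.

## Numerical and design choices

- All randomness flows from one master seed; reports are byte-identical
  across runs of the same config, whose hash is embedded in the report.
- Every silent correction — outlier removals, SD flooring, probability
  renormalisation, headline substitution — is collected in the report's
  warning list.
- Problem sizes used by the shipped analyses: 1,000 draws per
  simulation, 500 replications × 1,000 draws for the coverage check,
  ~26 inputs and 72 purchase records per synthetic bundle. These keep
  any single analysis under a few seconds while leaving Monte Carlo
  error well inside the tolerances asserted.
- Currency toggling (`usd`/`intl`) rescales money fields only.

## Limitations

- Payer perspective only: no out-of-pocket, societal, or non-public-
  provider costs.
- Only unit costs are simulated; session counts, probabilities and
  prevalence enter as fixed values (prevalence uncertainty enters only
  through the product-of-bounds range).
- Untreated cases (≈0.2%) are ignored; treatments other than the six
  modelled are out of scope.
- The fixture reproduces published point values, not the underlying raw
  records; category-level resource lists are illustrative.
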