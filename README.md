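# microcoi — micro-costing and cost-of-illness of genital-warts treatment

`microcoi` implements an activity-based (micro-costing) and
prevalence-based cost-of-illness (COI) analysis of treating genital warts
(GW) in Peru's public healthcare sector, as a tested, reusable pipeline.
It is aimed at health economists and epidemiologists who want to audit,
re-run or adapt this kind of payer-perspective burden estimate.

## The model

A health service (a diagnosis appointment, or one session of six
treatment techniques: podophyllin, imiquimod, trichloroacetic acid,
cryotherapy, electrosurgery, surgical excision) is decomposed into
activities that consume resources. The cost per session is the
sum-product

&nbsp;&nbsp;&nbsp;&nbsp;C_s = Σ_i q_{s,i} · u_i

of resource quantities q and unit costs u (2016 PEN), decomposed into
seven categories (human resources, infrastructure, equipment, drugs,
medical instruments, disposable materials, water/electricity). Unit
costs come from purchase records (mean and sample SD after a 3×-the-peer-
median outlier screen), straight-line depreciation per minute for
durables, and the opportunity cost of paid health-worker time.

Uncertainty is propagated by Monte Carlo: each u_i gets a gamma
distribution matched to its mean and SD by moments (shape = m²/s²,
scale = s²/m; s = 10⁻⁹ when an input has a single source), and the whole
chain is re-evaluated on 1,000 draws, summarised by 2.5%/97.5%
percentiles.

Cases are cross-classified into 180 compartments — gender (2) × case
type (new / resistant / recurrent, 3) × physician specialty (5) ×
treatment (6) — each with probability p_c (case distribution × treatment
choice given specialty) and an annual per-patient cost

&nbsp;&nbsp;&nbsp;&nbsp;A_c = e_c · (C_diag + n_c · C_t(c)),

where n_c is the sessions per course and e_c the episodes per year
(1 for new/resistant; 1.7 male / 1.6 female for recurrent). The average
annual treatment cost is the weighted average Σ_c p_c A_c, and the COI is

&nbsp;&nbsp;&nbsp;&nbsp;COI = population × prevalence × average cost,

with a range from the product of the 95% bounds of prevalence and cost.
Results convert to 2019 USD (3.3 PEN/USD, 2.5%/yr inflation) and to
international dollars (PPP factor 1.74).

Because the study's raw costing records are not redistributable, the
package ships a synthetic-data generator that emulates them (gamma price
noise across three collection sites, Dirichlet probability tables with
optional pinning to published usage margins) together with the
closed-form truth each bundle implies — so every stage is testable by
parameter recovery.

## Worked example

```python
from microcoi import RunConfig, published_fixture, run_pipeline

report = run_pipeline(RunConfig(bundle=published_fixture(), seed=11))
b = report.burden
print(f"COI: {b['coi_point_usd']/1e6:.1f}M USD "
      f"(range {b['coi_low_usd']/1e6:.1f}, {b['coi_high_usd']/1e6:.1f})")
print(f"COI: {b['coi_point_intl']/1e6:.1f}M intl.D")
```

prints

```
COI: 25.1M USD (range 16.9, 36.6)
COI: 43.7M intl.D
```

i.e. about 419,520 prevalent adult cases (333,709 male, 85,811 female)
at an average of 59.9 USD per patient-year cost the payer ~25.1 million
USD per year, between 16.9M and 36.6M under joint prevalence/cost
uncertainty — about 43.7 million international dollars.

The numbered drivers under `analysis/` run the full story on synthetic
data and on the published-values fixture:

```sh
python analysis/01_generate_data.py   # synthetic bundles + ground truth
python analysis/02_session_costs.py   # per-session costs with 95% intervals
python analysis/03_average_cost.py    # 180-compartment weighted average
python analysis/04_burden.py          # prevalent cases and the COI
```

Each writes its tables under `results/`. The same pipeline is scriptable
from the shell: `microcoi synth --out DIR --seed N` then
`microcoi run --config run.yaml --out DIR [--report usd|intl]`.

## Layout

- `src/microcoi/` — the library: `cost_inputs` (unit costs), `session_costing`,
  `uncertainty` (gamma Monte Carlo), `compartments`, `burden`, `synthetic`
  (data generator + published-values fixture), `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers.
- `tests/` — pytest suite (unit, property and acceptance tests).
- `docs/methods.md` — modelling assumptions, parameters, and limitations.
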