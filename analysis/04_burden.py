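#!/usr/bin/env python
"""Population burden: prevalent cases and the cost of illness.

Applies the Peruvian epidemiology (18.4M adults, prevalence 2.28%,
5.25%/1.35% by gender) to the published headline average cost, and prints
the COI in USD and international dollars, with the product-of-bounds
uncertainty range.
"""

from pathlib import Path

import pandas as pd

from microcoi import RunConfig, published_fixture, run_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"

r = run_pipeline(RunConfig(bundle=published_fixture(), seed=11))
b = r.burden
print(f"prevalent cases: {b['cases_male']:,.0f} male + {b['cases_female']:,.0f} female "
      f"= {b['cases_total']:,.0f}")
print(f"COI: {b['coi_point_usd']/1e6:.1f}M USD "
      f"(range {b['coi_low_usd']/1e6:.1f}, {b['coi_high_usd']/1e6:.1f}); "
      f"male {b['coi_male_usd']/1e6:.1f}M, female {b['coi_female_usd']/1e6:.1f}M")
print(f"COI: {b['coi_point_intl']/1e6:.1f}M intl.D "
      f"(range {b['coi_low_intl']/1e6:.1f}, {b['coi_high_intl']/1e6:.1f})")
pd.Series(b, name="value").to_csv(RESULTS / "burden_summary.csv")
for w in r.warnings:
    print("note:", w)
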