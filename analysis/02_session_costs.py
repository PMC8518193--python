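#!/usr/bin/env python
"""Per-session costs with Monte Carlo 95% intervals.

Runs the pipeline on the default synthetic bundle written by
01_generate_data.py and on the published-values fixture, and writes the
session-cost tables (seven categories + total by seven services) under
results/.
"""

from pathlib import Path

from microcoi import RunConfig, published_fixture, render_tables, run_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 11

syn = run_pipeline(RunConfig(bundle_dir=str(RESULTS / "bundle_default"), seed=SEED))
render_tables(syn, RESULTS / "synthetic", fmt="csv")
print("synthetic bundle, cost per session (USD, point / 95% interval):")
for sid, costs in syn.session_costs.items():
    lo, hi = syn.session_intervals[sid]["total"]
    print(f"  {sid:18s} {costs['total']:7.2f}  ({lo:.2f}, {hi:.2f})")

fix = run_pipeline(RunConfig(bundle=published_fixture(), seed=SEED))
render_tables(fix, RESULTS / "fixture", fmt="csv")
print("published-values fixture, cost per session (USD):")
for sid, costs in fix.session_costs.items():
    print(f"  {sid:18s} {costs['total']:7.2f}")
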