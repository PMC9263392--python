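#!/usr/bin/env python
"""Cohort-level statistics on the simulated study.

Baseline between-group comparisons (pooled t / chi-square), per-group
improvement rates, and the OLS outcome model of mGOS on the eight C-ApEn
cells plus clinical covariates, with tolerance/VIF diagnostics.
"""

import importlib
import sys

simulate = importlib.import_module("01_simulate_cohort")

from capeneeg.pipeline import cmd_cohort_stats

if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    cfg = simulate.config(seed)
    out = cmd_cohort_stats(cfg)
    print("baseline comparisons:")
    print(out["baseline"].to_string(index=False))
    print("\nimprovement rates:")
    print(out["improvement"].to_string(index=False))
    print("\noutcome model (significant rows):")
    reg = out["regression"]
    print(reg[reg["p"] < 0.05].to_string(index=False))
    print(f"\ntables -> {cfg.out_dir}/baseline.csv, improvement.csv, regression.csv")
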