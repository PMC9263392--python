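#!/usr/bin/env python
"""Extract C-ApEn cortical-network features from the simulated recordings.

Reads every patient's three condition recordings, computes the ten
pair-by-condition epoch-mean C-ApEn cells, and derives the Cu-FPu
pain-minus-rest difference statistic D for each patient.
"""

import importlib
import sys

simulate = importlib.import_module("01_simulate_cohort")

from capeneeg.pipeline import cmd_features

if __name__ == "__main__":
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    cfg = simulate.config(seed)
    summary = cmd_features(cfg)
    print(f"features for {len(summary)} patients")
    print(f"D: mean {summary['D'].mean():.4f}, min {summary['D'].min():.4f}, "
          f"max {summary['D'].max():.4f}")
    print(f"tables -> {cfg.out_dir}/features.csv, {cfg.out_dir}/summary.csv")
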