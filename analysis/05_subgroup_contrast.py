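#!/usr/bin/env python
"""Two-group contrast: does a log Bayes factor separate distinct regimes?

Group A draws active durations from a pure power law (alpha = 3.19, the
bipolar-like regime); group B from the composite exponential + truncated
power-law (the psychosis-like regime).  The contrast compares the evidence
of separate composite fits against a single pooled fit; as a control, two
cohorts from the SAME exponential law should pool (negative LogBF).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from actibout import distmodels as dm
from actibout.groupsel import compare_groups_logbf, logbf_verbal_scale
from actibout.studies import subgroup_contrast_study
from actibout.synthetic import sample_durations

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
OUT.mkdir(parents=True, exist_ok=True)

res = subgroup_contrast_study(seed=13, n_replicates=10, n_per_group=5000)
pd.DataFrame({"replicate": range(len(res["log_bayes_factors"])),
              "log_bayes_factor": res["log_bayes_factors"]}).to_csv(
    OUT / "subgroup_logbf.csv", index=False)

print(f"Distinct regimes: median LogBF = {res['median_logbf']:.1f} "
      f"({logbf_verbal_scale(res['median_logbf'])} evidence); "
      f"{100 * res['frac_strong']:.0f}% of replicates exceed the strong-"
      "evidence bar of 5.")

# control: same generative law in both groups -> pooling preferred
spec = dm.ModelSpec("exponential", {"lam": 0.3}, 1.0)
ctrl = [compare_groups_logbf(sample_durations(spec, 2000, seed=2 * s),
                             sample_durations(spec, 2000, seed=2 * s + 1),
                             "exponential")
        for s in range(5)]
print(f"Control (identical laws): median LogBF = {np.median(ctrl):.1f} "
      "(negative, i.e. the extra-parameter penalty favors pooling).")
print(f"Wrote {OUT / 'subgroup_logbf.csv'}")
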