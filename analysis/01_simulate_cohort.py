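#!/usr/bin/env python
"""Simulate the synthetic study cohort and summarize its event structure.

Generates the default 20-subject graded-amplitude cohort (alternating
active/inactive renewal process; composite exponential + truncated
power-law active durations, truncated power-law inactive waiting times),
extracts events at each subject's mean-of-nonzero-counts threshold, and
writes a per-subject summary with the generative truth alongside.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from actibout.events import activity_threshold, extract_events
from actibout.studies import COHORT_KWARGS
from actibout.synthetic import SyntheticCohortConfig, generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
OUT.mkdir(parents=True, exist_ok=True)

config = SyntheticCohortConfig(n_subjects=20, total_duration_per_subject=200_000,
                               master_seed=1, **COHORT_KWARGS)
rows = []
for series, truth in generate_cohort(config):
    thr = activity_threshold(series)
    es = extract_events(series, thr)
    rows.append({
        "subject_id": truth.subject_id,
        "threshold_cps": round(thr, 3),
        "n_active": es.active.size,
        "n_inactive": es.inactive.size,
        "mean_active_s": round(float(es.active.mean()), 2),
        "mean_inactive_s": round(float(es.inactive.mean()), 2),
        "max_inactive_s": float(es.inactive.max()),
        "true_active_alpha": round(truth.active_model.params["alpha"], 3),
        "true_inactive_alpha": round(truth.inactive_model.params["alpha"], 3),
    })
df = pd.DataFrame(rows)
df.to_csv(OUT / "cohort_summary.csv", index=False)

print(f"Simulated {len(df)} subjects of 200,000 s each (master seed 1).")
print(f"Data-driven thresholds span {df.threshold_cps.min():.2f}-"
      f"{df.threshold_cps.max():.2f} cps.")
print(f"Median events per subject: {df.n_active.median():.0f} active / "
      f"{df.n_inactive.median():.0f} inactive; inactive waiting times reach "
      f"{df.max_inactive_s.max():.0f} s, two orders of magnitude above the "
      f"mean active bout ({df.mean_active_s.mean():.1f} s) - the heavy-tail "
      "signature the fits must capture.")
print(f"Wrote {OUT / 'cohort_summary.csv'}")
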