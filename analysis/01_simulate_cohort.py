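#!/usr/bin/env python
"""Simulate the study cohort: participant table + 7-day epoch recordings.

Generates 100 RA participants and an 800-participant control pool with
Table-1-style demographics, applies the eligibility filters (comorbidity
history, rheumatoid factor > 20 IU/mL in controls, diagnosis after the
recording period, duplicate-diagnosis resolution), simulates each
remaining participant's activity-state labels and epoch magnitudes with
the standard RA effect injected for cases, and writes the participant
table plus a small epoch-CSV excerpt under results/analysis/.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

import json
from pathlib import Path

from actipat.pipeline import RunConfig, STAGES, run_pipeline

OUT = Path("results/analysis")
SEED = 7

config = RunConfig(
    seed=SEED,
    out_dir=str(OUT),
    n_ra=100,
    n_pool=800,
    days=7,
)
config.stages = {s: s in ("simulate", "preprocess", "label") for s in STAGES}

art = run_pipeline(config)
config.to_yaml(OUT / "run_config.yaml")

n_ra = sum(p.group == "RA" for p in art["profiles"])
n_ctrl = len(art["profiles"]) - n_ra
print(f"simulated {n_ra} RA + {n_ctrl} control participants after filters")
print("exclusions:", json.dumps(art["exclusion_log"], indent=2))
print(f"{len(art['recordings'])} recordings meet the 72-h wear minimum")

# a small excerpt so the epoch format is inspectable without a big file
from actipat.labeling import LabelSeries
from actipat.pipeline import write_epoch_csv
from actipat.preprocess import EpochSeries

pid, (series, labels) = next(iter(art["recordings"].items()))
day = EpochSeries(
    series.start_time, series.epoch_seconds,
    series.values[:2880], series.wear_mask[:2880],
)
day_labels = LabelSeries(labels.start_time, labels.epoch_seconds, labels.codes[:2880])
write_epoch_csv({pid: (day, day_labels)}, OUT / "epochs_excerpt.csv")
print(f"wrote participant table and a one-day epoch excerpt to {OUT}/")
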