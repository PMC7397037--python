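#!/usr/bin/env python
"""Simulate the demonstration cohorts.

Generates two equatorial-section cohorts at full confocal geometry
(0.2 µm pixels, ~60 µm ooplasm radius, 2000 granules): a low-competence
group with a weak peripheral placement bias and a high-competence group
with a stronger one.  Images + ground truth land under scratch/ (they are
regenerable binaries); the manifest path is printed for the next step.
"""

import shutil
from pathlib import Path

from cgdist.studies import DEMO_HIGH_COMPETENCE, DEMO_LOW_COMPETENCE
from cgdist.simulate import simulate_cohort

OUT = Path("scratch/demo_cohort")
N_PER_GROUP = 10
SEED = 20260201

if OUT.exists():
    shutil.rmtree(OUT)

manifest = simulate_cohort(
    {"low_competence": DEMO_LOW_COMPETENCE, "high_competence": DEMO_HIGH_COMPETENCE},
    n_per_group=N_PER_GROUP,
    seed=SEED,
    out_dir=OUT,
)
print(f"simulated {len(manifest)} oocytes into {OUT}")
print(manifest.groupby("group")["true_count"].describe()[["count", "mean"]])
print(f"\nnext: python analysis/02_icgd_comparison.py")
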