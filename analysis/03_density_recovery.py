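#!/usr/bin/env python
"""Density recovery through the spot-detection pipeline.

Simulates cortical-surface fields spanning 20-100 granules per 100 µm²,
detects granules with the multi-scale LoG detector, measures density with
the three-window protocol, and tabulates recovery error against the
generative truth.
"""

from pathlib import Path

from cgdist.studies import density_recovery_study

RESULTS = Path("results")
RESULTS.mkdir(exist_ok=True)

df = density_recovery_study(n_fields=25, seed=20260203)
df.to_csv(RESULTS / "density_recovery.csv", index=False)

print(df.groupby("target_density")[["true_density", "measured_density", "rel_error"]]
      .mean().round(3))
print(f"\nmedian relative error over {len(df)} fields: {df['rel_error'].median():.3f}")
print(f"wrote {RESULTS/'density_recovery.csv'}")
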