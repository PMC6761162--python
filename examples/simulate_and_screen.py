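"""Simulate a dissection survey with reagent contamination and screen it out.

Builds a community table with 30 spiked contaminants whose share scales
inversely with sample biomass, generates negative controls, and runs the
prevalence-based contaminant test at the conventional 0.1 threshold.
"""

import numpy as np
import pandas as pd

from colonscape.sim import CommunitySimParams, simulate_community, simulate_negative_controls
from colonscape.tables import AsvTable, prevalence_contaminant_test, remove_features

params = CommunitySimParams(
    n_taxa=300, n_contaminants=30, contaminant_scale=0.01,
    n_controls=10, n_mice=2, seed=0, track_variance_fractions=False,
)
table, metadata, truth = simulate_community(params)
controls, _ = simulate_negative_controls(params, truth)

merged = AsvTable(pd.concat([table.counts, controls.counts], axis=1))
is_control = np.array([s.startswith("NEGCTRL") for s in merged.sample_ids])
report = prevalence_contaminant_test(merged, is_control, threshold=0.1)

flagged = set(report.contaminant_ids)
truth_set = set(truth.contaminant_ids)
clean, removed_fraction = remove_features(table, report.contaminant_ids)

print(f"simulated {table.shape[0]} features x {table.shape[1]} samples, "
      f"{len(truth_set)} spiked contaminants")
print(f"flagged {len(flagged)} features; "
      f"sensitivity {len(flagged & truth_set) / len(truth_set):.2f}, "
      f"false flags {len(flagged - truth_set)}")
print(f"mean removed read fraction {removed_fraction.mean():.3%}")
print("A sensitivity near 1 with no false flags means the screen separates "
      "reagent contaminants (control-enriched, biomass-inverse) from the "
      "real community.")
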