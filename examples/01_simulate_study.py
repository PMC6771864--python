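"""Simulate a two-stage liability cohort and inspect its clinical structure.

Builds the default synthetic study (770 target subjects, 3,000 discovery
subjects, 1,000 SNPs in LD blocks with an APOE-like locus), then prints the
diagnosis-trajectory table and the amyloid-status cross-tabulation.  The
trajectory counts mirror a longitudinal AD cohort: most subjects are stable,
a block of MCI subjects converts to AD, and a few atypical paths are
excluded from analysis.
"""

import pandas as pd

from prsdissect import cohort
from prsdissect.synthio import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=1))
visits = study.target_cohort

labels = cohort.classify_trajectory(visits)
amyloid = cohort.assign_amyloid(visits)

print("Diagnosis trajectories (baseline -> final; analysis label):")
traj = labels.groupby(["BASELINE_DX", "FINAL_DX", "LABEL"]).size().rename("n")
print(traj.to_string(), "\n")

merged = labels.merge(amyloid, on="IID")
print("Amyloid status by analysis label (SUVR threshold 1.11):")
print(pd.crosstab(merged["AMYLOID"], merged["LABEL"]).to_string(), "\n")

cons = cohort.build_contrasts(labels, amyloid)
for name, con in cons.items():
    print(f"contrast {name:11s}: {con.n_case} cases vs {con.n_control} controls")
print("\nThe four contrasts above are the analysis frames: AD vs control,")
print("MCI vs control, amyloid-positive vs -negative, and conversion among")
print("amyloid-positive baseline-MCI subjects.")
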