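"""Build a polygenic risk score step by step and watch the variant counts.

Runs the scoring pipeline on a synthetic study: per-variant QC (missingness,
Hardy-Weinberg, allele frequency), harmonization of discovery weights onto
target alleles, p <= 0.5 selection, greedy LD clumping (r^2 = 0.1, 1,000 kb),
APOE-region exclusion, and the weighted dosage sum with PC adjustment.
The printed counts show how many variants each stage retains.
"""

import numpy as np

from prsdissect import prscore
from prsdissect.synthio import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=2))
target = study.target

qc = prscore.variant_qc(target)
geno = target.subset_variants(qc.keep)
print(f"QC: kept {qc.n_kept}/{target.n_variants} variants "
      f"(missingness {qc.n_missingness}, HWE {qc.n_hwe}, MAF {qc.n_maf})")

weights = prscore.match_alleles(geno.variants, study.sumstats)
print(f"harmonized to discovery summary statistics: {len(weights)} variants")

weights = prscore.select_by_p(weights, 0.5)
print(f"p <= 0.5 selection: {len(weights)} variants")

clumped = prscore.ld_clump(weights, geno, r2_max=0.1, window_kb=1000)
print(f"LD clumping: {len(clumped)} index variants")

final = prscore.exclude_region(clumped, prscore.APOE_REGION)
print(f"APOE region excluded: {len(final)} variants in the final score")

raw = prscore.compute_raw_prs(geno, final)
pcs = prscore.compute_pcs(geno.subset_variants(geno.variants["id"].isin(clumped["id"]).to_numpy()), k=8)
std = prscore.adjust_standardize(raw, pcs)
print(f"\nstandardized PRS: mean {std.mean():.2e}, SD {std.std(ddof=1):.4f} "
      f"(adjusted for 8 PCs, then z-scored)")

# the APOE term enters separately, as epsilon allele counts
v = study.genotypes.variants
eps4_id = v.loc[v["is_apoe_slot"] & (v["alt"] == "C"), "id"].iloc[0]
eps2_id = v.loc[v["is_apoe_slot"] & (v["alt"] == "T"), "id"].iloc[0]
apoe = prscore.apoe_allele_counts(target, eps4_id, eps2_id)
print(f"epsilon4 allele frequency: {apoe['EPS4'].mean() / 2:.3f}, "
      f"epsilon2: {apoe['EPS2'].mean() / 2:.3f}")
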