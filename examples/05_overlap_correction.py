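"""Discovery-target sample overlap: inflation and its simulation correction.

When some target subjects also sit in the discovery GWAS, discovery betas
are partly fitted to the target's noise and the naive PRS AUC is inflated.
This example plants a 30% case overlap, measures the inflation against a
held-out disjoint discovery, then applies the two-stage correction:
estimate the overlap-induced effect-size variability c by leave-overlap-out
refits, then average the AUC over summary statistics re-drawn from
Normal(beta, c * SE) with re-selection and re-clumping each draw.
"""

from prsdissect import overlapsim

df = overlapsim.run_overlap_experiment(n_replicates=5, seed=11)

print(df.round(3).to_string(index=False))
print(f"\nmean naive AUC     {df['auc_naive'].mean():.3f}   (overlap-inflated)")
print(f"mean corrected AUC {df['auc_corrected'].mean():.3f}   (two-stage correction)")
print(f"mean disjoint AUC  {df['auc_disjoint'].mean():.3f}   (held-out truth)")
print(f"mean c             {df['c'].mean():.3f}")
print("\nThe corrected mean sits between the naive and disjoint values:")
print("perturbing betas by their overlap-induced variability dilutes part")
print("of the noise-fitted advantage while keeping the real signal.")
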