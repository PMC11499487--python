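"""Estimate cell-type proportions from bulk TPM and score the recovery.

Non-negative least squares of each bulk profile on the cell-type signature
matrix, renormalized to the simplex, compared against the generator's true
proportions.
"""

import cellfate as cf

cohort = cf.generate_cohort(cf.CohortConfig(rng_seed=3))
tpm = cf.counts_to_tpm(cohort.counts, cohort.annotation)
estimated = cf.estimate_proportions(tpm, cohort.truth.signature_matrix)
recovery = cf.evaluate_recovery(estimated, cohort.truth.true_proportions)

print(recovery.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\nworst per-type Pearson r: {recovery.pearson_r.min():.3f}")
# At the default 10% multiplicative noise, every cell type's estimate
# should correlate with truth at r > 0.95.
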