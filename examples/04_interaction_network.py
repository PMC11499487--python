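"""Build the stage-wise Mantel network between death programs and cell types.

For each stage, every (death mode, cell type) pair gets a Mantel test:
1 - Pearson distances of the program's log-TPM profiles against
|delta proportion| distances of the cell type, 1,000 permutations, BH
adjustment within the stage.  The planted necroptosis-neuron coupling in
BLB6 should surface as the dominant significant record.
"""

import cellfate as cf

cohort = cf.generate_cohort(cf.CohortConfig(
    coupling_specs=(cf.PlantedCoupling("BLB6", "necroptosis", "neurons", 0.8),),
    rng_seed=4))
tpm = cf.counts_to_tpm(cf.filter_genes(cohort.counts, cohort.annotation),
                       cohort.annotation)
props = cf.estimate_proportions(tpm, cohort.truth.signature_matrix)
records = cf.build_interaction_network(
    tpm, props, cohort.catalog, cohort.metadata,
    cf.PipelineConfig(n_permutations=1000, rng_seed=4))

sig = records[records.significant].sort_values("p_adjust")
print(f"{len(records)} records ({len(sig)} significant)")
print(sig[["stage", "death_mode", "cell_type", "mantel_r", "p_value",
           "p_adjust", "strong"]].to_string(index=False))
# 'strong' marks Mantel R > 0.5; the planted BLB6 necroptosis-neurons pair
# should appear here with R well above that bar.
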