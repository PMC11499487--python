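"""Track how death-route interactions shift across disease stages.

Plants a necroptosis coupling that grows with stage (0 -> 0.4 -> 0.8) and a
ferroptosis coupling that shrinks (0.8 -> 0.4 -> 0), then summarizes the
interaction network per stage: the change table should read necroptosis =
increase, ferroptosis = decrease.
"""

import cellfate as cf

cohort = cf.generate_cohort(cf.CohortConfig(
    n_samples_per_stage={"BLB0": 30, "BLB5": 30, "BLB6": 30},
    coupling_specs=(
        cf.PlantedCoupling("BLB5", "necroptosis", "neurons", 0.4),
        cf.PlantedCoupling("BLB6", "necroptosis", "neurons", 0.8),
        cf.PlantedCoupling("BLB0", "ferroptosis", "microglia", 0.8),
        cf.PlantedCoupling("BLB5", "ferroptosis", "microglia", 0.4),
    ),
    rng_seed=5))
tpm = cf.counts_to_tpm(cf.filter_genes(cohort.counts, cohort.annotation),
                       cohort.annotation)
props = cf.estimate_proportions(tpm, cohort.truth.signature_matrix)
records = cf.build_interaction_network(tpm, props, cohort.catalog,
                                       cohort.metadata,
                                       cf.PipelineConfig(rng_seed=5))
stages = cohort.metadata.stages_present()

summary = cf.count_interactions(records, stages)
print("significant interactions per stage and mode:")
print(summary.to_string())

changes = cf.classify_changes(summary, stages)
print("\nchanges between consecutive stages:")
print(changes.to_string(index=False))

traj = cf.strength_trajectory(records, "necroptosis", stages)
print("\nnecroptosis Mantel-R trajectory (neurons row should rise):")
print(traj.round(3).to_string())
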