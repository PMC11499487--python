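"""Correlate NOS-family expression with necroptosis genes, stage by stage.

NOS1-3 produce nitric oxide; coupling both the NOS set and the necroptosis
program to the same cell type in the last stage makes their gene pairs
co-vary there.  Signed significant counts should therefore tilt positive
in BLB6.
"""

import pandas as pd

import cellfate as cf

cohort = cf.generate_cohort(cf.CohortConfig(
    coupling_specs=(
        cf.PlantedCoupling("BLB6", "necroptosis", "neurons", 0.8),
        cf.PlantedCoupling("BLB6", "nos", "neurons", 0.8),
    ),
    rng_seed=6))
tpm = cf.counts_to_tpm(cohort.counts, cohort.annotation)

tables = [
    cf.nos_correlation_matrix(tpm, cohort.metadata, cohort.catalog["nos"],
                              cohort.catalog["necroptosis"], stage)
    for stage in cohort.metadata.stages_present()
]
table = pd.concat(tables, ignore_index=True)

starred = table[table.stars != ""]
print(f"{len(table)} gene pairs tested; {len(starred)} starred")
print(starred[["stage", "gene_a", "gene_b", "pearson_r", "p_value", "stars"]]
      .head(12).to_string(index=False))

print("\nsigned significant counts per stage:")
print(cf.count_signed_significant(table).to_string())
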