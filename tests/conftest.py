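"""Shared fixtures: small synthetic cohorts and toy tables."""

import numpy as np
import pandas as pd
import pytest

import cellfate as cf


@pytest.fixture(scope="session")
def small_cohort() -> cf.SyntheticCohort:
    """A 3-stage, 12-samples-per-stage cohort with one strong planted
    necroptosis-neuron coupling in the last stage."""
    config = cf.CohortConfig(
        n_samples_per_stage={"BLB0": 12, "BLB5": 12, "BLB6": 12},
        n_genes_background=200,
        coupling_specs=(cf.PlantedCoupling("BLB6", "necroptosis", "neurons", 0.8),),
        rng_seed=7,
    )
    return cf.generate_cohort(config)


@pytest.fixture(scope="session")
def small_tpm(small_cohort) -> cf.ExpressionMatrix:
    filtered = cf.filter_genes(small_cohort.counts, small_cohort.annotation)
    return cf.counts_to_tpm(filtered, small_cohort.annotation)


@pytest.fixture(scope="session")
def small_network(small_cohort, small_tpm) -> pd.DataFrame:
    props = cf.estimate_proportions(small_tpm, small_cohort.truth.signature_matrix)
    # n_perm >= 999 so the permutation-p floor can clear BH across 50 pairs
    config = cf.PipelineConfig(n_permutations=999, rng_seed=7)
    return cf.build_interaction_network(
        small_tpm, props, small_cohort.catalog, small_cohort.metadata, config)


@pytest.fixture()
def toy_counts() -> cf.ExpressionMatrix:
    data = pd.DataFrame(
        [[10.0, 20.0], [90.0, 40.0], [5.0, 0.0]],
        index=["gA", "gB", "gC"], columns=["s1", "s2"])
    return cf.ExpressionMatrix(data, "counts")


@pytest.fixture()
def toy_annotation() -> cf.GeneAnnotation:
    return cf.GeneAnnotation(pd.DataFrame(
        {"biotype": ["protein_coding", "protein_coding", "lncRNA"],
         "length_bp": [1000, 2000, 1500]},
        index=["gA", "gB", "gC"]))


def random_distance_pair(rng: np.random.Generator, n: int):
    """Two independent random Euclidean distance matrices over n items."""
    xs = rng.normal(size=(n, 3))
    ys = rng.normal(size=(n, 3))
    from scipy.spatial.distance import pdist

    ids = [f"S{i}" for i in range(n)]
    return (cf.DistanceMatrix(ids, pdist(xs)), cf.DistanceMatrix(ids, pdist(ys)))
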