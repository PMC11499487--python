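"""Mantel machinery: distances, statistic, permutation test, network."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import cellfate as cf
from cellfate.interactions import (
    DistanceMatrix,
    build_interaction_network,
    distance_from_geneset,
    distance_from_scalar,
    mantel_statistic,
    mantel_test,
    mantel_test_exhaustive,
    spearman_mode_type_matrix,
)
from cellfate.io import ValidationError
from conftest import random_distance_pair


def brute_force_mantel(d1: DistanceMatrix, d2: DistanceMatrix):
    """Independent oracle: enumerate all permutations with plain numpy."""
    sq2 = squareform(d2.condensed)
    r_obs = np.corrcoef(d1.condensed, d2.condensed)[0, 1]
    hits = total = 0
    for perm in itertools.permutations(range(d1.n)):
        perm = list(perm)
        permuted = squareform(sq2[np.ix_(perm, perm)], checks=False)
        r = np.corrcoef(d1.condensed, permuted)[0, 1]
        hits += r >= r_obs
        total += 1
    return r_obs, hits / total


def _tpm(data: np.ndarray, genes=None, samples=None) -> cf.ExpressionMatrix:
    genes = genes or [f"g{i}" for i in range(data.shape[0])]
    samples = samples or [f"s{j}" for j in range(data.shape[1])]
    return cf.ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples),
                               "TPM", strict_tpm=False)


class TestDistanceConstructors:
    def test_identical_profiles_have_zero_distance(self):
        data = np.tile(np.array([[1.0], [10.0], [100.0]]), (1, 3))
        d = distance_from_geneset(_tpm(data), [f"g{i}" for i in range(3)])
        np.testing.assert_allclose(d.condensed, 0, atol=1e-12)

    def test_anticorrelated_profiles_reach_two(self):
        # log10(x+1) of these two columns are exactly anti-correlated
        col_a = np.array([10 ** 1 - 1, 10 ** 2 - 1, 10 ** 3 - 1])
        col_b = col_a[::-1]
        data = np.column_stack([col_a, col_b, col_a])
        d = distance_from_geneset(_tpm(data), [f"g{i}" for i in range(3)])
        sq = d.square()
        assert sq[0, 1] == pytest.approx(2.0)
        assert sq[0, 2] == pytest.approx(0.0)

    def test_condensed_matches_hand_pearson(self):
        rng = np.random.default_rng(0)
        data = rng.lognormal(2, 1, (5, 4))
        d = distance_from_geneset(_tpm(data), [f"g{i}" for i in range(5)])
        profiles = np.log10(data + 1).T
        expected = [1 - np.corrcoef(profiles[i], profiles[j])[0, 1]
                    for i in range(4) for j in range(i + 1, 4)]
        np.testing.assert_allclose(d.condensed, expected, atol=1e-12)

    def test_absent_genes_dropped_but_two_required(self):
        data = np.random.default_rng(1).lognormal(2, 1, (3, 4))
        tpm = _tpm(data)
        d = distance_from_geneset(tpm, ["g0", "g1", "ghost"])
        assert d.n == 4
        with pytest.raises(ValidationError, match=">= 2 set genes"):
            distance_from_geneset(tpm, ["g0", "ghost"])

    def test_zero_variance_profile_names_sample(self):
        data = np.array([[1.0, 5.0], [1.0, 50.0], [1.0, 500.0]])
        with pytest.raises(ValidationError, match="'s0'"):
            distance_from_geneset(_tpm(np.column_stack([data, data[:, :1]])),
                                  ["g0", "g1", "g2"])

    def test_scalar_distance_arithmetic(self):
        d = distance_from_scalar(np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(d.condensed, [0.5, 1.0, 0.5])

    def test_scalar_distance_translation_invariant(self):
        v = np.array([0.1, 0.4, 0.2, 0.9])
        d1 = distance_from_scalar(v)
        d2 = distance_from_scalar(v + 3.7)
        np.testing.assert_allclose(d1.condensed, d2.condensed, atol=1e-12)

    def test_scalar_distance_rejects_missing(self):
        with pytest.raises(ValidationError, match="missing"):
            distance_from_scalar(np.array([0.1, np.nan, 0.3]))


class TestMantelStatistic:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(2)
        d1, _ = random_distance_pair(rng, 6)
        assert mantel_statistic(d1, d1) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        d1, _ = random_distance_pair(rng, 6)
        d2 = DistanceMatrix(d1.ids, 0.3 + 2.5 * d1.condensed)
        assert mantel_statistic(d1, d2) == pytest.approx(1.0)

    def test_matches_hand_computation_on_four_items(self):
        d1 = DistanceMatrix(list("abcd"), np.array([1.0, 2, 3, 4, 5, 6]))
        d2 = DistanceMatrix(list("abcd"), np.array([2.0, 1, 4, 3, 6, 5]))
        expected = np.corrcoef(d1.condensed, d2.condensed)[0, 1]
        assert mantel_statistic(d1, d2) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        d1 = DistanceMatrix(list("abc"), np.array([1.0, 1.0, 1.0]))
        d2 = DistanceMatrix(list("abc"), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValidationError, match="zero variance"):
            mantel_statistic(d1, d2)

    def test_mismatched_ids_rejected(self):
        d1 = DistanceMatrix(list("abc"), np.array([1.0, 2.0, 3.0]))
        d2 = DistanceMatrix(list("abd"), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValidationError, match="same samples"):
            mantel_statistic(d1, d2)


class TestMantelTest:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        d1, d2 = random_distance_pair(rng, 10)
        assert mantel_test(d1, d2, 500, seed=9) == mantel_test(d1, d2, 500, seed=9)

    def test_p_floor_at_add_one_rule(self):
        ids = [f"S{i}" for i in range(10)]
        v = np.arange(10.0)
        d1 = distance_from_scalar(v, ids)
        r, p = mantel_test(d1, d1, n_perm=1000, seed=0)
        assert r == pytest.approx(1.0)
        assert p >= 1 / 1001

    def test_consistent_relabeling_preserves_r(self):
        rng = np.random.default_rng(5)
        d1, d2 = random_distance_pair(rng, 8)
        perm = rng.permutation(8)
        sq1, sq2 = d1.square()[np.ix_(perm, perm)], d2.square()[np.ix_(perm, perm)]
        ids = [d1.ids[i] for i in perm]
        d1p = DistanceMatrix(ids, squareform(sq1, checks=False))
        d2p = DistanceMatrix(ids, squareform(sq2, checks=False))
        assert mantel_statistic(d1p, d2p) == pytest.approx(
            mantel_statistic(d1, d2), rel=1e-12)

    def test_cross_check_against_skbio(self):
        import skbio

        rng = np.random.default_rng(6)
        d1, d2 = random_distance_pair(rng, 12)
        r_ours, p_ours = mantel_test(d1, d2, n_perm=999, seed=1)
        r_skbio, p_skbio, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(d1.square(), ids=d1.ids),
            skbio.DistanceMatrix(d2.square(), ids=d2.ids),
            method="pearson", permutations=999, alternative="greater")
        assert r_ours == pytest.approx(r_skbio, rel=1e-10)
        assert abs(p_ours - p_skbio) < 0.08  # independent permutation streams


class TestMantelExhaustive:
    @pytest.mark.parametrize("n", [4, 5])
    def test_matches_independent_brute_force(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d1, d2 = random_distance_pair(rng, n)
            r, p = mantel_test_exhaustive(d1, d2)
            r_bf, p_bf = brute_force_mantel(d1, d2)
            assert r == pytest.approx(r_bf, rel=1e-10)
            assert p == pytest.approx(p_bf, abs=1e-12)

    def test_identity_included_so_p_has_floor(self):
        rng = np.random.default_rng(7)
        d1, _ = random_distance_pair(rng, 5)
        _, p = mantel_test_exhaustive(d1, d1)
        assert p >= 1 / math.factorial(5)

    def test_too_many_items_rejected(self):
        rng = np.random.default_rng(8)
        d1, d2 = random_distance_pair(rng, 8)
        with pytest.raises(ValidationError, match="limited to 7"):
            mantel_test_exhaustive(d1, d2)

    def test_monte_carlo_converges_to_exact(self):
        rng = np.random.default_rng(9)
        d1, d2 = random_distance_pair(rng, 6)
        _, p_exact = mantel_test_exhaustive(d1, d2)
        _, p_mc = mantel_test(d1, d2, n_perm=4000, seed=3)
        mcse = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(p_mc - p_exact) < 3 * mcse + 1e-3


class TestInteractionNetwork:
    def test_record_count_is_modes_times_types_per_stage(self, small_cohort,
                                                         small_network):
        n_modes, n_types = 5, 10
        stages = small_cohort.metadata.stages_present()
        assert len(small_network) == len(stages) * n_modes * n_types
        assert set(small_network.columns) >= {
            "stage", "death_mode", "cell_type", "mantel_r", "p_value",
            "p_adjust", "significant", "strong"}

    def test_planted_coupling_is_flagged(self, small_network):
        target = small_network[
            (small_network.stage == "BLB6")
            & (small_network.death_mode == "necroptosis")
            & (small_network.cell_type == "neurons")]
        assert bool(target.significant.iloc[0])
        assert target.mantel_r.iloc[0] > 0

    def test_bh_flags_monotone_in_adjusted_p(self, small_network):
        for _, group in small_network.groupby("stage", observed=True):
            sig_max = group.loc[group.significant, "p_adjust"].max()
            ns_min = group.loc[~group.significant, "p_adjust"].min()
            if np.isfinite(sig_max) and np.isfinite(ns_min):
                assert sig_max <= ns_min

    def test_empty_catalog_gives_empty_records(self, small_cohort, small_tpm):
        props = cf.estimate_proportions(small_tpm,
                                        small_cohort.truth.signature_matrix)
        empty = cf.GeneSetCatalog()
        records = build_interaction_network(
            small_tpm, props, empty, small_cohort.metadata)
        assert len(records) == 0

    def test_reproducible_given_config(self, small_cohort, small_tpm):
        props = cf.estimate_proportions(small_tpm,
                                        small_cohort.truth.signature_matrix)
        config = cf.PipelineConfig(n_permutations=99, rng_seed=3)
        a = build_interaction_network(small_tpm, props, small_cohort.catalog,
                                      small_cohort.metadata, config)
        b = build_interaction_network(small_tpm, props, small_cohort.catalog,
                                      small_cohort.metadata, config)
        pd.testing.assert_frame_equal(a, b)


class TestSpearmanMatrix:
    def test_activity_tracking_proportion_gives_rho_one(self, small_cohort):
        # single-gene "set" whose TPM is a monotone function of the neuron
        # proportion -> Spearman rho must be exactly 1
        props = small_cohort.truth.true_proportions
        samples = small_cohort.metadata.samples_in_stage("BLB0")
        p = props.data.loc[samples, "neurons"].to_numpy()
        data = np.vstack([1000.0 * p + 5.0, np.full(len(p), 50.0)])
        tpm = _tpm(data, genes=["trk1", "trk2"], samples=samples)
        catalog = cf.GeneSetCatalog()
        catalog.add("tracker", ["trk1"], role="death_mode")
        rho, pval = spearman_mode_type_matrix(
            tpm, props, catalog, small_cohort.metadata, "BLB0")
        assert rho.loc["tracker", "neurons"] == pytest.approx(1.0)

    def test_rho_invariant_under_monotone_transform_of_activity(self, small_cohort):
        props = small_cohort.truth.true_proportions
        samples = small_cohort.metadata.samples_in_stage("BLB0")
        p = props.data.loc[samples, "neurons"].to_numpy()
        base = 1000.0 * p + 5.0
        catalog = cf.GeneSetCatalog()
        catalog.add("tracker", ["trk1"], role="death_mode")
        rhos = []
        for row in (base, base ** 2.5):  # strictly monotone transform
            tpm = _tpm(row[None, :], genes=["trk1"], samples=samples)
            rho, _ = spearman_mode_type_matrix(
                tpm, props, catalog, small_cohort.metadata, "BLB0")
            rhos.append(rho)
        pd.testing.assert_frame_equal(rhos[0], rhos[1])
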