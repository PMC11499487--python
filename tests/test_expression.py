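"""Filtering, differential expression, ordination, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.special import comb

import cellfate as cf
from cellfate.expression import (
    _pseudo_f,
    count_degs,
    differential_expression,
    filter_genes,
    ora_enrichment,
    pcoa,
    permutation_group_test,
)
from cellfate.io import ValidationError


def _tpm_from_groups(values_a: np.ndarray, values_b: np.ndarray):
    """Build a padded TPM matrix whose first rows carry the given group data."""
    n_a, n_b = values_a.shape[1], values_b.shape[1]
    data = np.vstack([np.hstack([values_a, values_b])])
    # pad with a filler gene so columns can be normalized to 1e6
    filler = np.maximum(1e6 - data.sum(axis=0), 0)[None, :]
    full = np.vstack([data, filler])
    genes = [f"g{i}" for i in range(data.shape[0])] + ["filler"]
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    tpm = cf.ExpressionMatrix(pd.DataFrame(full, index=genes, columns=samples), "TPM")
    meta = cf.SampleMetadata(
        pd.DataFrame({"stage": ["BLB0"] * n_a + ["BLB6"] * n_b}, index=samples))
    return tpm, meta


class TestFilterGenes:
    def test_lncrna_and_low_count_removal(self, toy_counts, toy_annotation):
        kept = filter_genes(toy_counts, toy_annotation, min_count=15,
                            min_samples=1, drop_biotypes=("lncRNA",))
        # gC is lncRNA; gA reaches 20 in s2; gB reaches 90
        assert kept.gene_ids == ["gA", "gB"]

    def test_min_count_zero_keeps_everything_but_biotype(self, toy_counts,
                                                         toy_annotation):
        kept = filter_genes(toy_counts, toy_annotation, min_count=0,
                            min_samples=0, drop_biotypes=())
        assert kept.gene_ids == toy_counts.gene_ids

    def test_empty_result_advises(self, toy_counts, toy_annotation):
        with pytest.raises(ValidationError, match="relax"):
            filter_genes(toy_counts, toy_annotation, min_count=10 ** 9,
                         min_samples=1)


class TestDifferentialExpression:
    def test_fold_change_closed_form(self):
        a = np.full((1, 4), 1.0)
        b = np.full((1, 4), 127.0)
        tpm, meta = _tpm_from_groups(a, b)
        deg = differential_expression(tpm, meta, "BLB0", "BLB6")
        assert deg.loc[deg.gene_id == "g0", "log2fc"].iloc[0] == pytest.approx(6.0)

    def test_identical_groups_are_ns(self):
        values = np.tile(np.array([[5.0, 7.0, 9.0]]), (1, 2))
        tpm, meta = _tpm_from_groups(values, values)
        deg = differential_expression(tpm, meta, "BLB0", "BLB6")
        row = deg[deg.gene_id == "g0"].iloc[0]
        assert row.log2fc == 0.0
        assert row.direction == "ns"

    def test_direction_flips_with_group_swap(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(1, 100, (30, 5))
        b = a * rng.choice([0.2, 5.0], size=(30, 1))
        tpm, meta = _tpm_from_groups(a, b)
        fwd = differential_expression(tpm, meta, "BLB0", "BLB6")
        rev = differential_expression(tpm, meta, "BLB6", "BLB0")
        flipped = fwd.direction.map({"up": "down", "down": "up", "ns": "ns"})
        assert (rev.direction == flipped).all()

    def test_null_pvalues_reject_at_nominal_rate(self):
        rng = np.random.default_rng(3)
        null = rng.lognormal(3, 1, (2000, 30))
        tpm, meta = _tpm_from_groups(null[:, :15], null[:, 15:])
        deg = differential_expression(tpm, meta, "BLB0", "BLB6")
        frac = (deg.p_value.iloc[:2000] <= 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_small_group_rejected(self):
        tpm, meta = _tpm_from_groups(np.full((1, 1), 2.0), np.full((1, 4), 2.0))
        with pytest.raises(ValidationError, match=">= 2 samples"):
            differential_expression(tpm, meta, "BLB0", "BLB6")

    def test_count_degs_tallies_and_ignores_order(self):
        records = pd.DataFrame({"direction": ["up"] * 3 + ["down"] * 2 + ["ns"] * 5})
        assert count_degs(records) == (3, 2)
        assert count_degs(records.sample(frac=1, random_state=0)) == (3, 2)
        assert count_degs(records.iloc[:0]) == (0, 0)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg: q_(i) = min_{j>=i} p_(j) m / j, clip 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBenjaminiHochberg:
    def test_matches_brute_force_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], bh_oracle(p), atol=1e-12)


class TestPcoa:
    def _random_tpm(self, n_genes, n_samples, seed):
        rng = np.random.default_rng(seed)
        raw = rng.lognormal(3, 1, (n_genes, n_samples))
        tpm = raw / raw.sum(axis=0) * 1e6
        return cf.ExpressionMatrix(pd.DataFrame(
            tpm, index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)]), "TPM")

    def test_matches_pca_scores_up_to_sign(self):
        from sklearn.decomposition import PCA

        tpm = self._random_tpm(10, 6, seed=1)
        res = pcoa(tpm, k=3)
        profiles = np.log10(tpm.values + 1).T
        scores = PCA(n_components=3).fit_transform(profiles)
        np.testing.assert_allclose(np.abs(res.coordinates.to_numpy()),
                                   np.abs(scores), atol=1e-8)

    def test_identical_samples_coincide(self):
        tpm = self._random_tpm(8, 4, seed=2)
        data = tpm.data.copy()
        data["s1"] = data["s0"]
        res = pcoa(cf.ExpressionMatrix(data, "TPM"), k=2)
        np.testing.assert_allclose(res.coordinates.loc["s0"],
                                   res.coordinates.loc["s1"], atol=1e-8)

    def test_eigenvalues_non_increasing(self):
        res = pcoa(self._random_tpm(12, 7, seed=3), k=5)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()

    def test_k_bounds_enforced(self):
        tpm = self._random_tpm(5, 4, seed=4)
        with pytest.raises(ValidationError, match="k must lie"):
            pcoa(tpm, k=4)


class TestPermutationGroupTest:
    def test_separated_clouds_reach_minimal_p(self):
        rng = np.random.default_rng(0)
        # groups large enough that a random permutation essentially never
        # reproduces the exact partition (which would tie with F_obs)
        x = np.vstack([rng.normal(0, 0.01, (8, 2)), rng.normal(100, 0.01, (12, 2))])
        p = permutation_group_test(pdist(x), ["a"] * 8 + ["b"] * 12,
                                   n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)

    def test_p_respects_add_one_floor(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 2))
        p = permutation_group_test(pdist(x), ["a"] * 4 + ["b"] * 4,
                                   n_perm=99, seed=2)
        assert p >= 1 / 100

    def test_pseudo_f_matches_skbio_permanova(self):
        import skbio

        rng = np.random.default_rng(6)
        x = rng.normal(size=(12, 3))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        sq = squareform(pdist(x))
        ours = _pseudo_f(sq ** 2, (labels == "b").astype(int), 2)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(sq), labels, permutations=0)["test statistic"]
        assert ours == pytest.approx(theirs, rel=1e-10)

    def test_null_rejection_rate_is_nominal(self):
        rng = np.random.default_rng(8)
        hits = 0
        n_sim = 200
        for i in range(n_sim):
            x = rng.normal(size=(10, 2))
            p = permutation_group_test(pdist(x), ["a"] * 5 + ["b"] * 5,
                                       n_perm=99, seed=i)
            hits += p <= 0.05
        # binomial(200, 0.05): mean 10, sd ~3.1
        assert 1 <= hits <= 22

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValidationError, match=">= 2 groups"):
            permutation_group_test(pdist(np.eye(4)), ["a", "a", "a", "a"])


class TestOraEnrichment:
    def _catalog(self, sets):
        catalog = cf.GeneSetCatalog()
        for name, genes in sets.items():
            catalog.add(name, genes)
        return catalog

    def test_full_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        catalog = self._catalog({"s": universe[:5]})
        res = ora_enrichment(universe[:5], catalog, universe)
        assert res.p_value.iloc[0] == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_disjoint_set_is_null(self):
        universe = [f"g{i}" for i in range(10)]
        catalog = self._catalog({"s": ["x1", "x2", "x3"]})
        res = ora_enrichment(universe[:4], catalog, universe)
        assert res.overlap.iloc[0] == 0
        assert res.p_value.iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        from itertools import combinations

        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(12)]
        set_genes = list(rng.choice(universe, size=5, replace=False))
        catalog = self._catalog({"s": set_genes})
        deg = list(rng.choice(universe, size=4, replace=False))
        res = ora_enrichment(deg, catalog, universe)
        k_obs = len(set(deg) & set(set_genes))
        total = hits = 0
        for draw in combinations(universe, len(deg)):
            total += 1
            hits += len(set(draw) & set(set_genes)) >= k_obs
        assert res.p_value.iloc[0] == pytest.approx(hits / total, rel=1e-9)

    def test_requires_subset_and_universe(self):
        catalog = self._catalog({"s": ["a"]})
        with pytest.raises(ValidationError, match="empty universe"):
            ora_enrichment([], catalog, [])
        with pytest.raises(ValidationError, match="subset"):
            ora_enrichment(["zzz"], catalog, ["a", "b"])
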