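"""Preprocessing, differential expression, ordination and enrichment.

Differential expression uses the field-standard significance criteria
|log2FC| >= 1 and P <= 0.05 on TPM, with the fold change computed on group
means with a pseudocount of 1 TPM and the p-value from a two-sided
Mann-Whitney rank test.  The test engine is deliberately pluggable (pass
``test=``): the downstream stages consume only the thresholded records, not
the internals of any particular DEG engine.

Ordination is classical PCoA (metric MDS) on Euclidean distances of
log10(TPM + 1) sample profiles — equivalent to PCA scores up to axis sign —
with a PERMANOVA-style permutation test for group separation.
Over-representation of DEG lists in gene programs is a one-sided
hypergeometric test with Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io import (
    ExpressionMatrix,
    GeneAnnotation,
    PipelineConfig,
    SampleMetadata,
    GeneSetCatalog,
    ValidationError,
    log10_tpm,
)

__all__ = [
    "DEG_COLUMNS",
    "OrdinationResult",
    "filter_genes",
    "differential_expression",
    "count_degs",
    "pcoa",
    "permutation_group_test",
    "ora_enrichment",
]

#: schema of a differential-expression record table
DEG_COLUMNS = ("gene_id", "log2fc", "p_value", "q_value", "direction")


def filter_genes(counts: ExpressionMatrix, annotation: GeneAnnotation,
                 min_count: int = 10, min_samples: int = 2,
                 drop_biotypes: Sequence[str] = ("lncRNA",)) -> ExpressionMatrix:
    """Drop low-count genes and unwanted biotypes (lncRNAs by default).

    A gene is kept when its count is >= ``min_count`` in at least
    ``min_samples`` samples and its biotype is not in ``drop_biotypes``.
    Gene order is preserved.
    """
    biotypes = annotation.biotype(counts.gene_ids)
    keep_biotype = ~biotypes.isin(list(drop_biotypes)).to_numpy()
    keep_count = (counts.values >= min_count).sum(axis=1) >= min_samples
    keep = keep_biotype & keep_count
    if not keep.any():
        raise ValidationError(
            "no genes survive filtering; relax min_count/min_samples or drop_biotypes"
        )
    return ExpressionMatrix(counts.data.loc[keep], counts.unit_kind)


def _mann_whitney_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney p per row; degenerate (all-tied) rows -> 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(b, a, axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue, float)
    p[~np.isfinite(p)] = 1.0
    return np.clip(p, np.nextafter(0, 1), 1.0)


def differential_expression(tpm: ExpressionMatrix, metadata: SampleMetadata,
                            group_a: str, group_b: str,
                            config: PipelineConfig | None = None,
                            test: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
                            ) -> pd.DataFrame:
    """Differential expression of ``group_b`` versus ``group_a``.

    Per gene: log2fc = log2((mean TPM_b + 1) / (mean TPM_a + 1)); p from the
    rank test (or an injected ``test``); q = BH over all tested genes.
    ``direction`` is ``up`` when log2fc >= log2fc_min and p <= p_max,
    ``down`` when log2fc <= -log2fc_min and p <= p_max, else ``ns``.
    """
    config = config or PipelineConfig()
    samples_a = metadata.samples_in_stage(group_a)
    samples_b = metadata.samples_in_stage(group_b)
    samples_a = [s for s in samples_a if s in tpm.data.columns]
    samples_b = [s for s in samples_b if s in tpm.data.columns]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError(
            f"each group needs >= 2 samples (got {len(samples_a)} in {group_a!r}, "
            f"{len(samples_b)} in {group_b!r})")
    a = tpm.data[samples_a].to_numpy(float)
    b = tpm.data[samples_b].to_numpy(float)
    pseudo = 1.0
    log2fc = np.log2((b.mean(axis=1) + pseudo) / (a.mean(axis=1) + pseudo))
    p = (test or _mann_whitney_rows)(a, b)
    q = multipletests(p, method=config.fdr_method)[1]
    direction = np.where(
        (log2fc >= config.log2fc_min) & (p <= config.p_max), "up",
        np.where((log2fc <= -config.log2fc_min) & (p <= config.p_max), "down", "ns"))
    return pd.DataFrame({
        "gene_id": tpm.gene_ids,
        "log2fc": log2fc,
        "p_value": p,
        "q_value": q,
        "direction": direction,
    })


def count_degs(records: pd.DataFrame) -> tuple[int, int]:
    """(n_up, n_down) over a DEG record table."""
    if len(records) == 0:
        return (0, 0)
    counts = records["direction"].value_counts()
    return int(counts.get("up", 0)), int(counts.get("down", 0))


@dataclass
class OrdinationResult:
    """PCoA coordinates with eigenvalues, axes by decreasing eigenvalue."""

    coordinates: pd.DataFrame  # samples x axes, centred
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    group_p_value: float | None = None


def _log_profiles(matrix: ExpressionMatrix) -> np.ndarray:
    """Samples x genes array on the pipeline's log scale."""
    if matrix.unit_kind == "TPM":
        return log10_tpm(matrix).to_numpy(float).T
    return matrix.values.astype(float).T


def pcoa(tpm_subset: ExpressionMatrix, k: int = 2) -> OrdinationResult:
    """Classical metric MDS of Euclidean sample-sample distances.

    On Euclidean distances of log10(TPM + 1) this equals PCA scores of the
    same profiles up to axis sign.
    """
    n = len(tpm_subset.sample_ids)
    if n < 3:
        raise ValidationError("PCoA needs >= 3 samples")
    if not 1 <= k <= n - 1:
        raise ValidationError(f"k must lie in [1, {n - 1}], got {k}")
    import skbio

    profiles = _log_profiles(tpm_subset)
    dm = skbio.DistanceMatrix(squareform(pdist(profiles)), ids=tpm_subset.sample_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = skbio.stats.ordination.pcoa(dm, number_of_dimensions=k)
    coords = res.samples.iloc[:, :k].copy()
    coords.columns = [f"PCo{i + 1}" for i in range(k)]
    coords.index = tpm_subset.sample_ids
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=res.eigvals.to_numpy()[:k],
        proportion_explained=res.proportion_explained.to_numpy()[:k],
    )


def _pseudo_f(sq_dist: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """PERMANOVA pseudo-F from a squared-distance matrix and group codes."""
    n = sq_dist.shape[0]
    ss_total = sq_dist[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.where(codes == g)[0]
        block = sq_dist[np.ix_(members, members)]
        ss_within += block[np.triu_indices(len(members), 1)].sum() / len(members)
    ss_among = ss_total - ss_within
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permutation_group_test(distances: np.ndarray | ExpressionMatrix,
                           labels: Sequence[str], n_perm: int = 999,
                           seed: int = 0) -> float:
    """PERMANOVA permutation p-value for group separation.

    ``distances`` may be a condensed vector, a square distance matrix, or an
    ExpressionMatrix (Euclidean distances of log profiles are then used).
    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    if isinstance(distances, ExpressionMatrix):
        distances = pdist(_log_profiles(distances))
    distances = np.asarray(distances, float)
    square = squareform(distances) if distances.ndim == 1 else distances
    labels = np.asarray([str(x) for x in labels])
    if square.shape[0] != len(labels):
        raise ValidationError("labels do not match the distance matrix")
    names, codes = np.unique(labels, return_inverse=True)
    if len(names) < 2 or np.bincount(codes).min() < 2:
        raise ValidationError("need >= 2 groups with >= 2 samples each")
    sq = square ** 2
    f_obs = _pseudo_f(sq, codes, len(names))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _pseudo_f(sq, rng.permutation(codes), len(names)) >= f_obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def ora_enrichment(deg_genes: Sequence[str], catalog: GeneSetCatalog,
                   universe: Sequence[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each catalog set.

    Upper-tail p for an overlap >= k when drawing ``len(deg_genes)`` genes
    from the universe; BH adjustment across sets.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("empty universe")
    deg_set = set(deg_genes)
    if not deg_set <= universe_set:
        raise ValidationError("deg_genes must be a subset of the universe")
    m = len(universe_set)
    n_draw = len(deg_set)
    rows = []
    for name, genes in catalog.sets.items():
        in_universe = universe_set & set(genes)
        overlap = len(deg_set & in_universe)
        p = stats.hypergeom.sf(overlap - 1, m, len(in_universe), n_draw) \
            if in_universe else 1.0
        rows.append((name, len(in_universe), overlap, float(min(p, 1.0))))
    out = pd.DataFrame(rows, columns=["set_name", "n_set", "overlap", "p_value"])
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1] if len(out) else []
    return out
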