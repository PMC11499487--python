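"""Stage-wise Mantel interaction networks between death programs and cell types.

This is the analytical core of the package.  For every disease stage, each
cell-death gene program is turned into a sample-sample distance matrix
(1 - Pearson correlation of log10(TPM + 1) profiles restricted to the
program's genes) and each cell type's estimated proportion into a scalar
distance matrix (|delta proportion|).  The association between a program and
a cell type within a stage is the Mantel statistic — the Pearson correlation
of the two condensed distance vectors — with a one-sided (greater)
permutation p-value over 1,000 label permutations by default.  P-values are
Benjamini-Hochberg adjusted across all (mode x type) pairs within each
stage; a record is flagged ``significant`` at adjusted p <= 0.05 and
``strong`` at Mantel R > 0.5.

An exhaustive-enumeration variant (all n! permutations, n <= 7) serves as a
brute-force oracle for the Monte-Carlo test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .io import (
    ExpressionMatrix,
    GeneSetCatalog,
    PipelineConfig,
    ProportionMatrix,
    SampleMetadata,
    ValidationError,
    log10_tpm,
)

__all__ = [
    "DistanceMatrix",
    "INTERACTION_COLUMNS",
    "distance_from_geneset",
    "distance_from_scalar",
    "mantel_statistic",
    "mantel_test",
    "mantel_test_exhaustive",
    "build_interaction_network",
    "spearman_mode_type_matrix",
]

logger = logging.getLogger(__name__)

#: schema of an interaction record table
INTERACTION_COLUMNS = ("stage", "death_mode", "cell_type", "mantel_r",
                       "p_value", "p_adjust", "significant", "strong")

#: permuted statistics within this absolute tolerance of the observed r count
#: as ties (>=); guards the inclusive tie rule against floating-point jitter
_R_TIE_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Pairwise sample distances in condensed form (length n(n-1)/2)."""

    ids: list[str]
    condensed: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(x) for x in self.ids]
        self.condensed = np.asarray(self.condensed, float)
        n = len(self.ids)
        if self.condensed.shape != (n * (n - 1) // 2,):
            raise ValidationError(
                f"condensed length {self.condensed.shape} does not match {n} ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def square(self) -> np.ndarray:
        return squareform(self.condensed)


def distance_from_geneset(tpm: ExpressionMatrix, gene_set: Sequence[str]) -> DistanceMatrix:
    """1 - Pearson distance between sample profiles restricted to a gene set.

    Absent genes are dropped with a warning; at least two set genes must be
    present and at least three samples.  Distances lie in [0, 2].
    """
    present = [g for g in gene_set if g in set(tpm.gene_ids)]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        logger.warning("distance_from_geneset: %d/%d genes absent (e.g. %s)",
                       len(missing), len(gene_set), missing[:3])
    if len(present) < 2:
        raise ValidationError(
            f"need >= 2 set genes present in the matrix, found {len(present)}")
    if len(tpm.sample_ids) < 3:
        raise ValidationError("need >= 3 samples")
    profiles = log10_tpm(tpm.subset_genes(present)).to_numpy(float).T
    flat = np.where(profiles.std(axis=1) == 0)[0]
    if flat.size:
        raise ValidationError(
            f"sample {tpm.sample_ids[flat[0]]!r} has a zero-variance profile "
            "on the gene set")
    return DistanceMatrix(tpm.sample_ids, pdist(profiles, metric="correlation"))


def distance_from_scalar(values: pd.Series | np.ndarray,
                         ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Absolute-difference distance |v_i - v_j| of a per-sample scalar."""
    if isinstance(values, pd.Series):
        ids = list(values.index) if ids is None else list(ids)
        values = values.to_numpy(float)
    else:
        values = np.asarray(values, float)
        ids = [f"S{i}" for i in range(len(values))] if ids is None else list(ids)
    if np.isnan(values).any():
        raise ValidationError("scalar values contain missing entries")
    if len(values) < 3:
        raise ValidationError("need >= 3 samples")
    return DistanceMatrix(ids, pdist(values[:, None], metric="cityblock"))


def _check_aligned(d1: DistanceMatrix, d2: DistanceMatrix) -> None:
    if d1.ids != d2.ids:
        raise ValidationError("distance matrices are not over the same samples "
                              "in the same order")


def _condensed_corr_parts(x: np.ndarray) -> tuple[np.ndarray, float]:
    centred = x - x.mean()
    norm = float(np.sqrt((centred ** 2).sum()))
    if norm == 0:
        raise ValidationError("distance vector has zero variance; "
                              "Mantel statistic undefined")
    return centred, norm


def mantel_statistic(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Pearson correlation of the two condensed distance vectors."""
    _check_aligned(d1, d2)
    c1, n1 = _condensed_corr_parts(d1.condensed)
    c2, n2 = _condensed_corr_parts(d2.condensed)
    return float(c1 @ c2 / (n1 * n2))


def _permuted_condensed(square: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Condensed vectors of the square matrix under each row/col permutation."""
    n = square.shape[0]
    iu, ju = np.triu_indices(n, 1)
    return square[perms[:, iu], perms[:, ju]]


def _perm_r(d1: DistanceMatrix, d2: DistanceMatrix, perms: np.ndarray) -> tuple[float, np.ndarray]:
    c1, n1 = _condensed_corr_parts(d1.condensed)
    r_obs = mantel_statistic(d1, d2)
    permuted = _permuted_condensed(d2.square(), perms)
    centred = permuted - permuted.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred ** 2).sum(axis=1))
    r_perm = centred @ c1 / (norms * n1)
    return r_obs, r_perm


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 1000,
                seed: int = 0) -> tuple[float, float]:
    """Mantel permutation test, one-sided (greater).

    Sample labels of ``d2`` are permuted (simultaneous row/column
    permutation) ``n_perm`` times;
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1).  Deterministic given seed;
    ties count as exceedances (conservative).
    """
    _check_aligned(d1, d2)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    # argsort of uniforms -> independent uniform permutations, vectorized
    perms = np.argsort(rng.random((n_perm, d1.n)), axis=1)
    r_obs, r_perm = _perm_r(d1, d2, perms)
    p = (1 + int((r_perm >= r_obs - _R_TIE_TOL).sum())) / (n_perm + 1)
    return r_obs, p


def mantel_test_exhaustive(d1: DistanceMatrix, d2: DistanceMatrix) -> tuple[float, float]:
    """Exact Mantel p over all n! permutations (identity included); n <= 7."""
    _check_aligned(d1, d2)
    if d1.n > 7:
        raise ValidationError(f"exhaustive enumeration limited to 7 items, got {d1.n}")
    perms = np.array(list(itertools.permutations(range(d1.n))))
    r_obs, r_perm = _perm_r(d1, d2, perms)
    p = int((r_perm >= r_obs - _R_TIE_TOL).sum()) / math.factorial(d1.n)
    return r_obs, p


def _aligned_stage_samples(tpm: ExpressionMatrix, proportions: ProportionMatrix,
                           metadata: SampleMetadata, stage: str) -> list[str]:
    in_stage = metadata.samples_in_stage(stage)
    cols = set(tpm.sample_ids) & set(proportions.sample_ids)
    return [s for s in in_stage if s in cols]


def build_interaction_network(tpm: ExpressionMatrix, proportions: ProportionMatrix,
                              catalog: GeneSetCatalog, metadata: SampleMetadata,
                              config: PipelineConfig | None = None) -> pd.DataFrame:
    """Mantel test for every stage x death-mode x cell-type triple.

    BH adjustment is applied across all (mode x type) pairs within each
    stage.  Stages with fewer than three aligned samples are skipped with a
    warning.  Permutation seeds derive stably from ``config.rng_seed`` and
    the record's position, so results are reproducible record-by-record.
    """
    config = config or PipelineConfig(stage_order=metadata.stage_order)
    modes = catalog.names_with_role("death_mode")
    rows = []
    for si, stage in enumerate(metadata.stages_present()):
        samples = _aligned_stage_samples(tpm, proportions, metadata, stage)
        if len(samples) < 3:
            logger.warning("stage %s skipped: only %d aligned samples",
                           stage, len(samples))
            continue
        stage_tpm = tpm.subset_samples(samples)
        mode_dist = {m: distance_from_geneset(stage_tpm, catalog[m]) for m in modes}
        type_dist = {
            t: distance_from_scalar(proportions.data.loc[samples, t])
            for t in proportions.cell_types
        }
        for mi, mode in enumerate(modes):
            for ti, cell_type in enumerate(proportions.cell_types):
                seed_seq = np.random.SeedSequence(
                    entropy=config.rng_seed, spawn_key=(si, mi, ti))
                seed = int(seed_seq.generate_state(1)[0])
                r, p = mantel_test(mode_dist[mode], type_dist[cell_type],
                                   n_perm=config.n_permutations, seed=seed)
                rows.append((stage, mode, cell_type, r, p))
    records = pd.DataFrame(rows, columns=["stage", "death_mode", "cell_type",
                                          "mantel_r", "p_value"])
    if len(records) == 0:
        return records.assign(p_adjust=[], significant=[], strong=[])
    records["p_adjust"] = np.nan
    for stage in records["stage"].unique():
        mask = records["stage"] == stage
        records.loc[mask, "p_adjust"] = multipletests(
            records.loc[mask, "p_value"], method=config.fdr_method)[1]
    records["significant"] = records["p_adjust"] <= config.p_max
    records["strong"] = records["mantel_r"] > config.mantel_r_min
    return records


def spearman_mode_type_matrix(tpm: ExpressionMatrix, proportions: ProportionMatrix,
                              catalog: GeneSetCatalog, metadata: SampleMetadata,
                              stage: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho (and two-sided p) between per-sample death-mode activity
    and each cell type's proportion within one stage.

    Activity of a mode = mean log10(TPM + 1) over its genes present in the
    matrix.  Constant vectors yield NaN (undefined correlation).
    """
    samples = _aligned_stage_samples(tpm, proportions, metadata, stage)
    if len(samples) < 3:
        raise ValidationError(f"stage {stage!r} has fewer than 3 aligned samples")
    stage_tpm = tpm.subset_samples(samples)
    log_table = log10_tpm(stage_tpm)
    modes = catalog.names_with_role("death_mode")
    rho = pd.DataFrame(index=modes, columns=proportions.cell_types, dtype=float)
    pval = rho.copy()
    for mode in modes:
        present = [g for g in catalog[mode] if g in set(stage_tpm.gene_ids)]
        if not present:
            continue
        activity = log_table.loc[present].mean(axis=0).to_numpy()
        for cell_type in proportions.cell_types:
            prop = proportions.data.loc[samples, cell_type].to_numpy()
            if activity.std() == 0 or prop.std() == 0:
                continue  # leaves NaN: correlation undefined
            res = stats.spearmanr(activity, prop)
            rho.loc[mode, cell_type] = float(res.statistic)
            pval.loc[mode, cell_type] = float(res.pvalue)
    return rho, pval
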