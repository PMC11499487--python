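"""Stage-stratified NOS-family / necroptosis gene-pair correlations.

Nitric oxide synthases (NOS1, NOS2, NOS3) are the enzymatic sources of NO;
the question this module answers is whether their expression tracks the
necroptosis program's key genes within each disease stage (or cohort
label).  Each (NOS gene, necroptosis gene) pair gets a Pearson r on
log10(TPM + 1) with a two-sided p from the exact t transform
t = r * sqrt((n - 2) / (1 - r^2)), annotated with the conventional
significance stars (* p < 0.05, ** p < 0.01, *** p < 0.001).  Raw-p stars
match figure-legend convention; BH-adjusted q-values are exported alongside
for stricter use.  The engine is cohort-agnostic: any grouping label works
as ``stage``.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleMetadata, ValidationError, log10_tpm

__all__ = ["significance_stars", "nos_correlation_matrix", "count_signed_significant"]

logger = logging.getLogger(__name__)


def significance_stars(p: float) -> str:
    """'***' p < 0.001, '**' p < 0.01, '*' p < 0.05, '' otherwise/NaN."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def nos_correlation_matrix(tpm: ExpressionMatrix, metadata: SampleMetadata,
                           nos_genes: Sequence[str], necro_genes: Sequence[str],
                           stage: str) -> pd.DataFrame:
    """Pearson correlation of every (NOS gene, necroptosis gene) pair in a stage.

    Missing genes are logged and skipped; zero-variance genes yield an
    undefined (NaN) correlation for their pairs.  Returns columns
    stage, gene_a, gene_b, n, pearson_r, p_value, q_value, stars.
    """
    samples = [s for s in metadata.samples_in_stage(stage) if s in set(tpm.sample_ids)]
    if len(samples) < 3:
        raise ValidationError(f"stage {stage!r} has fewer than 3 samples")
    log_table = log10_tpm(tpm.subset_samples(samples))

    def _present(genes: Sequence[str], label: str) -> list[str]:
        present = [g for g in genes if g in log_table.index]
        if len(present) < len(genes):
            logger.warning("%s genes absent from matrix: %s", label,
                           sorted(set(genes) - set(present))[:5])
        return present

    nos_present = _present(nos_genes, "NOS")
    necro_present = _present(necro_genes, "necroptosis")
    n = len(samples)
    rows = []
    for a in nos_present:
        va = log_table.loc[a].to_numpy(float)
        for b in necro_present:
            vb = log_table.loc[b].to_numpy(float)
            if a == b:
                r, p = 1.0, 0.0
            elif va.std() == 0 or vb.std() == 0:
                r, p = float("nan"), float("nan")
            else:
                r = float(np.corrcoef(va, vb)[0, 1])
                if abs(r) >= 1.0:
                    p = 0.0
                else:
                    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
                    p = float(2 * stats.t.sf(abs(t), df=n - 2))
            rows.append((stage, a, b, n, r, p))
    out = pd.DataFrame(rows, columns=["stage", "gene_a", "gene_b", "n",
                                      "pearson_r", "p_value"])
    finite = np.isfinite(out["p_value"])
    out["q_value"] = np.nan
    if finite.any():
        out.loc[finite, "q_value"] = multipletests(
            out.loc[finite, "p_value"], method="fdr_bh")[1]
    out["stars"] = out["p_value"].map(significance_stars)
    return out


def count_signed_significant(correlations: pd.DataFrame) -> pd.DataFrame:
    """Per-stage counts of significantly positive / negative pairs (p < 0.05).

    Returns a DataFrame indexed by stage with columns ``n_positive`` and
    ``n_negative``; an empty input yields an empty (all-zero) frame.
    """
    if len(correlations) == 0:
        return pd.DataFrame(columns=["n_positive", "n_negative"],
                            index=pd.Index([], name="stage"), dtype=int)
    sig = correlations[(correlations["p_value"] < 0.05)
                       & np.isfinite(correlations["pearson_r"])]
    stages = pd.Index(dict.fromkeys(correlations["stage"]), name="stage")
    out = pd.DataFrame(0, index=stages, columns=["n_positive", "n_negative"])
    for stage, group in sig.groupby("stage", observed=True):
        out.loc[stage, "n_positive"] = int((group["pearson_r"] > 0).sum())
        out.loc[stage, "n_negative"] = int((group["pearson_r"] < 0).sum())
    return out
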