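"""Cell-type proportion estimation from bulk TPM.

The pipeline needs one thing from this stage: a sample x cell-type
proportion matrix on the probability simplex.  The estimator here is
non-negative least squares of each bulk TPM profile on the cell-type
signature matrix over their shared genes, followed by renormalization to
the simplex.  The solver sits behind a stable contract (bulk + signature in,
simplex proportions out), so a learned deconvolver can be dropped in
without touching downstream stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import ExpressionMatrix, ProportionMatrix, ValidationError

__all__ = ["estimate_proportions", "evaluate_recovery"]


def _check_rank(sig: np.ndarray, cell_types: list[str]) -> None:
    rank = np.linalg.matrix_rank(sig)
    if rank < sig.shape[1]:
        corr = np.corrcoef(sig.T)
        pairs = [
            f"{cell_types[i]}~{cell_types[j]}"
            for i in range(len(cell_types)) for j in range(i + 1, len(cell_types))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValidationError(
            "signature matrix is rank-deficient on shared genes"
            + (f"; collinear columns: {', '.join(pairs)}" if pairs else "")
        )


def estimate_proportions(bulk_tpm: ExpressionMatrix,
                         signature: pd.DataFrame) -> ProportionMatrix:
    """Estimate per-sample cell-type proportions by NNLS + renormalization.

    Scale-invariant in the bulk sample (multiplying a sample by a positive
    constant leaves its estimate unchanged) and exact on noiseless
    identifiable mixtures.  Genes are matched by exact identifier.
    """
    shared = [g for g in signature.index if g in set(bulk_tpm.gene_ids)]
    if not shared:
        raise ValidationError("no shared genes between bulk and signature")
    sig = signature.loc[shared].to_numpy(float)
    cell_types = list(signature.columns)
    _check_rank(sig, cell_types)
    bulk = bulk_tpm.data.loc[shared].to_numpy(float)
    out = np.empty((bulk.shape[1], sig.shape[1]))
    for j in range(bulk.shape[1]):
        x, _ = nnls(sig, bulk[:, j])
        total = x.sum()
        if total <= 0:
            raise ValidationError(
                f"sample {bulk_tpm.sample_ids[j]!r} yields an all-zero fit")
        out[j] = x / total
    return ProportionMatrix(pd.DataFrame(out, index=bulk_tpm.sample_ids,
                                         columns=cell_types))


def evaluate_recovery(estimated: ProportionMatrix,
                      truth: ProportionMatrix) -> pd.DataFrame:
    """Per-cell-type RMSE and Pearson r between estimate and ground truth.

    r is reported as NaN when either vector is constant, except in the
    degenerate-but-exact case (estimate identical to a varying truth is
    impossible to reach with a constant estimate, so exact equality with
    positive variance reports r = 1).
    """
    if estimated.sample_ids != truth.sample_ids:
        raise ValidationError("sample mismatch between estimate and truth")
    if estimated.cell_types != truth.cell_types:
        raise ValidationError("cell-type mismatch between estimate and truth")
    est, tru = estimated.values, truth.values
    rows = []
    for j, cell_type in enumerate(estimated.cell_types):
        e, t = est[:, j], tru[:, j]
        rmse = float(np.sqrt(np.mean((e - t) ** 2)))
        if np.allclose(e, t) and t.std() > 0:
            r = 1.0
        elif e.std() == 0 or t.std() == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(e, t)[0, 1])
        rows.append((cell_type, rmse, r))
    return pd.DataFrame(rows, columns=["cell_type", "rmse", "pearson_r"])
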