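"""Multifactorial logistic regression + ROC for marker-based stratification.

The question: do the necroptosis marker genes, taken jointly, separate
disease from control samples?  A plain maximum-likelihood logistic
regression (iteratively reweighted least squares, no regularization by
default; an optional ridge penalty is exposed for separable designs) is fit
on marker log-expression, and the fitted probabilities are evaluated by ROC:
AUC by the trapezoid rule — asserted internally against the tie-corrected
Mann-Whitney U equivalence — with the operating point chosen by Youden's J
(sensitivity + specificity - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io import ExpressionMatrix, SampleMetadata, ValidationError, log10_tpm

__all__ = ["LogisticFit", "ROCResult", "fit_logistic", "roc_curve", "marker_roc"]


@dataclass
class LogisticFit:
    """Coefficients (intercept first) with convergence/separation diagnostics."""

    coef: pd.Series
    converged: bool
    n_iter: int
    separated: bool
    std_err: pd.Series | None = None

    def predict_proba(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        x = features.to_numpy(float) if hasattr(features, "to_numpy") else np.asarray(features, float)
        eta = self.coef.iloc[0] + x @ self.coef.iloc[1:].to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(features: pd.DataFrame | np.ndarray, labels: Sequence[int],
                 ridge: float = 0.0, max_iter: int = 100,
                 tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS (Newton-Raphson).

    Converged when the maximum absolute score (gradient) falls below ``tol``
    or after ``max_iter`` iterations.  Perfect separation is detected (fitted
    log-odds diverging while classifying perfectly) and reported on the
    result rather than raised.  ``ridge`` > 0 adds an L2 penalty on the
    non-intercept coefficients.
    """
    if hasattr(features, "to_numpy"):
        names = [str(c) for c in features.columns]
        x = features.to_numpy(float)
    else:
        x = np.atleast_2d(np.asarray(features, float))
        if x.shape[0] == 1 and np.asarray(labels).size != 1:
            x = x.T
        names = [f"x{j}" for j in range(x.shape[1])]
    y = np.asarray(labels, float)
    classes = np.unique(y)
    if classes.size != 2 or not set(classes) <= {0.0, 1.0}:
        raise ValidationError("labels must contain both classes, coded 0/1")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValidationError("each class needs >= 2 samples")
    design = np.column_stack([np.ones(len(y)), x])
    penalty = np.zeros(design.shape[1])
    penalty[1:] = ridge
    beta = np.zeros(design.shape[1])
    converged, it = False, 0
    for it in range(1, max_iter + 1):
        eta = np.clip(design @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = design.T @ (y - mu) - penalty * beta
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        hessian = design.T @ (design * w[:, None]) + np.diag(penalty)
        # pinv-based solve: degenerate columns (e.g. all-zero features) get
        # the minimum-norm update instead of blowing up
        beta = beta + np.linalg.pinv(hessian) @ score
    eta = design @ beta
    separated = bool(
        not converged or np.max(np.abs(eta)) > 25
    ) and bool(np.all((eta > 0) == (y == 1)))
    if separated:
        warnings.warn("perfect separation detected: coefficients diverge; "
                      "consider ridge > 0", stacklevel=2)
    w = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30))), 1e-12, 1 - 1e-12)
    fisher = design.T @ (design * (w * (1 - w))[:, None]) + np.diag(penalty)
    with np.errstate(invalid="ignore"):
        cov = np.linalg.pinv(fisher)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    index = ["intercept", *names]
    return LogisticFit(coef=pd.Series(beta, index=index), converged=converged,
                       n_iter=it, separated=separated,
                       std_err=pd.Series(se, index=index))


@dataclass
class ROCResult:
    """ROC sweep with AUC and the Youden-J operating point."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    coefficients: pd.Series | None = None
    extras: dict = field(default_factory=dict)


def _pair_count_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC: U / (n_pos * n_neg)."""
    ranks = rankdata(scores)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC over the unique-score threshold sweep (ties grouped).

    AUC is the trapezoidal integral of the curve and must agree with the
    tie-corrected Mann-Whitney AUC (internal consistency check).  The
    reported sensitivity/specificity are taken at the Youden point.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    if set(np.unique(labels)) != {0.0, 1.0}:
        raise ValidationError("labels must contain both classes, coded 0/1")
    if np.ptp(scores) == 0:
        # all scores tied: the only non-trivial operating points are the
        # corners; tie-corrected AUC is 1/2
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
        thresholds = np.array([np.inf, scores[0]])
    else:
        fpr, tpr, thresholds = _sk_roc_curve(labels, scores,
                                             drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    mwu_auc = _pair_count_auc(scores, labels)
    if not np.isclose(auc, mwu_auc, atol=1e-10):
        raise AssertionError(
            f"trapezoid AUC {auc} != Mann-Whitney AUC {mwu_auc}")
    youden = tpr - fpr
    best = int(np.argmax(youden))
    return ROCResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc,
        youden_threshold=float(thresholds[best]),
        sensitivity=float(tpr[best]), specificity=float(1.0 - fpr[best]),
    )


def marker_roc(tpm: ExpressionMatrix, metadata: SampleMetadata,
               marker_genes: Sequence[str], label_column: str = "group",
               ridge: float = 0.0) -> ROCResult:
    """Fit markers jointly and evaluate the fitted probabilities by ROC.

    Features are log10(TPM + 1) of the marker genes; labels come from the
    binary ``label_column`` of the metadata.  The in-sample ROC of the
    fitted model is returned with its coefficients attached.
    """
    if label_column not in metadata.data.columns:
        raise ValidationError(f"metadata has no column {label_column!r}")
    samples = [s for s in metadata.sample_ids if s in set(tpm.sample_ids)]
    present = [g for g in marker_genes if g in set(tpm.gene_ids)]
    if not present:
        raise ValidationError("no marker genes found in the expression matrix")
    log_table = log10_tpm(tpm.subset_samples(samples))
    features = log_table.loc[present].T
    labels = metadata.data.loc[samples, label_column].to_numpy(int)
    fit = fit_logistic(features, labels, ridge=ridge)
    result = roc_curve(fit.predict_proba(features), labels)
    result.coefficients = fit.coef
    result.extras.update(converged=fit.converged, separated=fit.separated)
    return result
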