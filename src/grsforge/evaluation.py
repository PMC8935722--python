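"""Association testing and predictive evaluation of fitted risk scores.

A fitted GRS model returns raw risks in [0, 1].  For association testing,
raw risks are moved to the linear-predictor scale with the logit (after
clipping at 1e-6) and used as the single predictor of a univariate
logistic regression on the independent test outcomes; a two-sided Wald
test on its slope decides significance.  Aggregating significance
fractions over replicates of influential (null) generating models yields
power (type I error) estimates.  Predictive strength is measured by the
Mann-Whitney AUC with half credit for ties, which the discrete nature of
genotype-based scores makes essential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import rankdata

__all__ = [
    "CLIP_EPS",
    "AssociationResult",
    "EvaluationResult",
    "logit_transform_grs",
    "fit_association_model",
    "fit_adjusted_gxe_model",
    "auc",
    "classification_metrics",
    "estimate_power",
    "estimate_type1",
    "evaluate_grs",
]

CLIP_EPS = 1e-6


@dataclass
class AssociationResult:
    """Univariate logistic fit of outcome on a logit-transformed GRS."""

    intercept: float
    grs_coefficient: float
    wald_p: float
    degenerate: bool = False


@dataclass
class EvaluationResult:
    """Per-split evaluation of one fitted GRS."""

    auc: float
    wald_p: float
    accuracy: float
    sensitivity: float
    specificity: float
    split_role: str = "test"
    degenerate: bool = False


def logit_transform_grs(raw: np.ndarray, eps: float = CLIP_EPS) -> np.ndarray:
    """logit of raw risks, clipped to [eps, 1-eps] so 0/1 risks stay finite."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0) or np.any(raw > 1):
        raise ValueError("raw risks must lie in [0, 1]")
    return logit(np.clip(raw, eps, 1.0 - eps))


def _check_binary_both_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    return y.astype(float)


def fit_association_model(grs_scores: np.ndarray, outcome: np.ndarray) -> AssociationResult:
    """Fit logit(P(Y=1)) = b0 + b1 * GRS and Wald-test b1 (two-sided).

    ``grs_scores`` are logit-scale scores (see :func:`logit_transform_grs`).
    A constant score carries no evidence: the result is flagged degenerate
    with b1 = 0 and p = 1.
    """
    y = _check_binary_both_classes(outcome)
    s = np.asarray(grs_scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and outcome must have equal length")
    if np.ptp(s) == 0.0:
        return AssociationResult(intercept=logit(max(min(y.mean(), 1 - CLIP_EPS), CLIP_EPS)),
                                 grs_coefficient=0.0, wald_p=1.0, degenerate=True)
    X = sm.add_constant(s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return AssociationResult(intercept=float(fit.params[0]),
                             grs_coefficient=float(fit.params[1]),
                             wald_p=float(fit.pvalues[1]))


def fit_adjusted_gxe_model(
    grs_scores: np.ndarray,
    environment: np.ndarray,
    outcome: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    covariate_names: Optional[Sequence[str]] = None,
):
    """Multivariable logistic model b0 + b1*GRS + b2*E + b3*GRS*E + sum g_i*C_i.

    Returns a dict of per-term (coefficient, wald_p) entries keyed by
    "GRS", "E", "GRS:E" and the covariate names.
    """
    y = _check_binary_both_classes(outcome)
    s = np.asarray(grs_scores, dtype=float)
    e = np.asarray(environment, dtype=float)
    cols = [np.ones_like(s), s, e, s * e]
    names = ["const", "GRS", "E", "GRS:E"]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(s):
            C = C.T
        for i in range(C.shape[1]):
            cols.append(C[:, i])
            names.append(covariate_names[i] if covariate_names else f"C{i + 1}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear = [names[j] for j in range(X.shape[1])
                     if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {collinear}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return {name: {"coefficient": float(fit.params[j]), "wald_p": float(fit.pvalues[j])}
            for j, name in enumerate(names)}


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_case > score_control) + 0.5 * P(equal).

    Computed from average ranks, which gives exact half credit for ties
    and invariance under strictly monotone score transformations.
    """
    y = _check_binary_both_classes(labels)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def classification_metrics(predicted_risk: np.ndarray, labels: np.ndarray,
                           threshold: float = 0.5) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) of hard classification at a threshold."""
    y = _check_binary_both_classes(labels).astype(int)
    pred = (np.asarray(predicted_risk, dtype=float) > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / max(int((y == 1).sum()), 1)
    specificity = tn / max(int((y == 0).sum()), 1)
    return float(accuracy), float(sensitivity), float(specificity)


def _significance_fraction(p_values: Sequence[float], level: float) -> tuple[float, float]:
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    frac = float(np.mean(p < level))
    se = float(np.sqrt(frac * (1 - frac) / p.size))
    return frac, se


def estimate_power(p_values: Sequence[float], level: float = 0.05) -> tuple[float, float]:
    """Fraction of replicates with a significant test (plus binomial SE)."""
    return _significance_fraction(p_values, level)


def estimate_type1(p_values: Sequence[float], level: float = 0.05) -> tuple[float, float]:
    """Rejection fraction on null replicates (plus binomial SE)."""
    return _significance_fraction(p_values, level)


def evaluate_grs(raw_risks: np.ndarray, outcome: np.ndarray,
                 split_role: str = "test", threshold: float = 0.5) -> EvaluationResult:
    """Full per-split evaluation: association Wald p, AUC and hard-classification metrics.

    The classification metrics are computed on the predicted probabilities
    of the fitted association model, matching the association-based
    evaluation pipeline.
    """
    scores = logit_transform_grs(raw_risks)
    assoc = fit_association_model(scores, outcome)
    model_risk = expit(assoc.intercept + assoc.grs_coefficient * scores)
    accuracy, sensitivity, specificity = classification_metrics(model_risk, outcome, threshold)
    return EvaluationResult(auc=auc(scores, outcome), wald_p=assoc.wald_p,
                            accuracy=accuracy, sensitivity=sensitivity,
                            specificity=specificity, split_role=split_role,
                            degenerate=assoc.degenerate)
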