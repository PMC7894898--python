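"""Benchmark metrics: PCER, confusion rates, FDP-TPR curves and AUC.

Conventions: the per-comparison error rate uses *unadjusted* p-values (a gene
is declared DE when p <= alpha), while the FDP-TPR curve and the ROC AUC are
computed from BH-adjusted p-values, scored as ``1 - p_adj``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class EvalResult:
    pcer: float | None
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN
    tpr: float | None
    fpr: float
    fdp: float
    fdp_tpr_curve: list[tuple[float, float]]
    auc: float | None


def pcer(pvalues: np.ndarray, alpha: float = 0.05) -> float:
    """Fraction of genes declared DE (unadjusted p <= alpha) on null data."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(np.mean(p <= alpha))


def confusion_and_rates(
    padj: np.ndarray, truth: np.ndarray, threshold: float = 0.05
):
    """(TP, FP, TPR, FPR, FDP) at a declaration threshold on adjusted p-values.

    ``FDP = FP / max(1, FP + TP)`` so that zero declared positives give 0;
    TPR is None when the truth has no positives.
    """
    padj = np.asarray(padj, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if padj.shape != truth.shape:
        raise ValueError("padj and truth must have equal length")
    declared = padj <= threshold
    tp = int(np.sum(declared & truth))
    fp = int(np.sum(declared & ~truth))
    pos = int(truth.sum())
    neg = truth.size - pos
    tpr = tp / pos if pos > 0 else None
    fpr = fp / neg if neg > 0 else 0.0
    fdp = fp / max(1, fp + tp)
    return tp, fp, tpr, fpr, fdp


def fdp_tpr_curve(padj: np.ndarray, truth: np.ndarray) -> list[tuple[float, float]]:
    """One (FDP, TPR) point per distinct adjusted-p threshold, ascending."""
    padj = np.asarray(padj, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if padj.shape != truth.shape:
        raise ValueError("padj and truth must have equal length")
    pos = truth.sum()
    curve = []
    for thr in np.unique(padj):
        tp, fp, tpr, _, fdp = confusion_and_rates(padj, truth, thr)
        curve.append((fdp, tpr if tpr is not None else 0.0))
    return curve


def auc(padj: np.ndarray, truth: np.ndarray) -> float:
    """Tie-aware ROC AUC of ``1 - padj`` as a score for the DE truth."""
    padj = np.asarray(padj, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("AUC needs at least one positive and one negative gene")
    return float(roc_auc_score(truth, 1.0 - padj))


def evaluate(
    pvalues: np.ndarray,
    padj: np.ndarray,
    truth: np.ndarray,
    alpha: float = 0.05,
) -> EvalResult:
    """Bundle all metrics for one result table against ground truth."""
    truth = np.asarray(truth, dtype=bool)
    tp, fp, tpr, fpr, fdp = confusion_and_rates(padj, truth, alpha)
    pos = int(truth.sum())
    neg = truth.size - pos
    tn = neg - fp
    fn = pos - tp
    return EvalResult(
        pcer=pcer(pvalues, alpha),
        confusion=(tp, fp, tn, fn),
        tpr=tpr,
        fpr=fpr,
        fdp=fdp,
        fdp_tpr_curve=fdp_tpr_curve(padj, truth),
        auc=auc(padj, truth) if 0 < pos < truth.size else None,
    )
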