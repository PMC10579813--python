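"""Multi-label evaluation measures.

Six rank/label measures (hamming loss, one-error, coverage, ranking loss,
average precision, macro-AUC) and five instance-set overlap measures
(mlACC, mlPRE, mlREC, mlF1, exact-match ACC).

Conventions, applied consistently everywhere:

* ranks are 1-based, descending by score; score ties are broken by lowest
  label index;
* coverage is normalized by ``n * m`` (the form this implementation targets);
  pass ``conventional=True`` for the usual ``1/n`` normalization;
* in ranking loss and macro-AUC an exact score tie between a positive and a
  negative label counts fully against the model; ``half_credit=True`` awards
  ties 1/2 instead (the usual AUC convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "hamming_loss",
    "one_error",
    "coverage",
    "ranking_loss",
    "average_precision",
    "macro_auc",
    "set_measures",
    "ranking_report",
    "RANKING_MEASURES",
    "MEASURE_DIRECTIONS",
]

# direction: -1 = lower is better, +1 = higher is better
MEASURE_DIRECTIONS = {
    "hamming_loss": -1,
    "one_error": -1,
    "coverage": -1,
    "ranking_loss": -1,
    "average_precision": +1,
    "macro_auc": +1,
}
RANKING_MEASURES = tuple(MEASURE_DIRECTIONS)


def _check_2d(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")
    (shape,) = shapes
    if len(shape) != 2 or 0 in shape:
        raise ValueError(f"expected nonempty n x m arrays, got shape {shape}")


def _ranks(f_row: np.ndarray) -> np.ndarray:
    """1-based rank of every label: rank 1 = highest score, ties -> lowest index."""
    m = len(f_row)
    order = np.lexsort((np.arange(m), -f_row))  # sort by -score, then index
    ranks = np.empty(m, dtype=np.int64)
    ranks[order] = np.arange(1, m + 1)
    return ranks


def hamming_loss(Y: np.ndarray, H: np.ndarray) -> float:
    """Fraction of label decisions that disagree with the truth."""
    Y, H = np.asarray(Y), np.asarray(H)
    _check_2d(Y, H)
    return float(np.mean(Y != H))


def one_error(Y: np.ndarray, F: np.ndarray) -> float:
    """Fraction of instances whose top-ranked label is not a true label."""
    Y, F = np.asarray(Y), np.asarray(F)
    _check_2d(Y, F)
    if np.any(Y.sum(axis=1) == 0):
        raise ValueError("every instance needs at least one positive label")
    top = np.argmax(F, axis=1)  # argmax takes the lowest index on ties
    return float(np.mean(Y[np.arange(len(Y)), top] == 0))


def coverage(Y: np.ndarray, F: np.ndarray, conventional: bool = False) -> float:
    """How deep the ranking must go to cover all true labels.

    Per instance the term is (worst rank among true labels) - 1; the sum is
    divided by ``n*m`` (or by ``n`` with ``conventional=True``).
    """
    Y, F = np.asarray(Y), np.asarray(F)
    _check_2d(Y, F)
    if np.any(Y.sum(axis=1) == 0):
        raise ValueError("every instance needs at least one positive label")
    n, m = Y.shape
    total = 0.0
    for i in range(n):
        ranks = _ranks(F[i])
        total += ranks[Y[i] == 1].max() - 1
    return float(total / (n if conventional else n * m))


def ranking_loss(Y: np.ndarray, F: np.ndarray, half_credit: bool = False) -> float:
    """Mean fraction of (positive, negative) label pairs ranked in the wrong order.

    A positive scoring <= a negative counts as a violation (ties included);
    with ``half_credit`` ties count 1/2. Rows with no negative labels are
    skipped with a warning.
    """
    Y, F = np.asarray(Y), np.asarray(F)
    _check_2d(Y, F)
    if np.any(Y.sum(axis=1) == 0):
        raise ValueError("every instance needs at least one positive label")
    terms = []
    n_skipped = 0
    for yi, fi in zip(Y, F):
        pos, neg = fi[yi == 1], fi[yi == 0]
        if len(neg) == 0:
            n_skipped += 1
            continue
        lt = np.sum(pos[:, None] < neg[None, :])
        eq = np.sum(pos[:, None] == neg[None, :])
        bad = lt + (0.5 * eq if half_credit else eq)
        terms.append(bad / (len(pos) * len(neg)))
    if n_skipped:
        warnings.warn(f"ranking_loss: skipped {n_skipped} rows with no negative label")
    if not terms:
        raise ValueError("no instance has both positive and negative labels")
    return float(np.mean(terms))


def average_precision(Y: np.ndarray, F: np.ndarray) -> float:
    """Mean over instances and true labels of precision at the label's rank."""
    Y, F = np.asarray(Y), np.asarray(F)
    _check_2d(Y, F)
    if np.any(Y.sum(axis=1) == 0):
        raise ValueError("every instance needs at least one positive label")
    terms = []
    for yi, fi in zip(Y, F):
        ranks = _ranks(fi)
        pos_ranks = ranks[yi == 1]
        # precision at rank r: true labels ranked at or above r, over r
        prec = [(pos_ranks <= r).sum() / r for r in pos_ranks]
        terms.append(np.mean(prec))
    return float(np.mean(terms))


def macro_auc(Y: np.ndarray, F: np.ndarray, half_credit: bool = False) -> tuple[float, np.ndarray]:
    """Per-label pairwise AUC, macro-averaged over evaluable labels.

    AUC for label j is the fraction of (positive instance, negative instance)
    pairs where the positive strictly outscores the negative; ties earn
    nothing unless ``half_credit``. Labels with a single class are excluded
    (their slot in the returned per-label vector is NaN).

    Returns ``(macro_average, per_label_auc)``.
    """
    Y, F = np.asarray(Y), np.asarray(F)
    _check_2d(Y, F)
    m = Y.shape[1]
    per_label = np.full(m, np.nan)
    for j in range(m):
        pos, neg = F[Y[:, j] == 1, j], F[Y[:, j] == 0, j]
        if len(pos) == 0 or len(neg) == 0:
            continue
        gt = np.sum(pos[:, None] > neg[None, :])
        eq = np.sum(pos[:, None] == neg[None, :])
        good = gt + (0.5 * eq if half_credit else 0.0)
        per_label[j] = good / (len(pos) * len(neg))
    evaluable = ~np.isnan(per_label)
    if not evaluable.any():
        raise ValueError("no label has both positive and negative instances")
    if not evaluable.all():
        warnings.warn(f"macro_auc: excluded {int((~evaluable).sum())} single-class labels")
    return float(per_label[evaluable].mean()), per_label


@dataclass(frozen=True)
class SetMeasures:
    mlacc: float
    mlpre: float
    mlrec: float
    mlf1: float
    acc: float


def set_measures(Y: np.ndarray, H: np.ndarray) -> SetMeasures:
    """Instance-set overlap measures between true and predicted label sets.

    mlACC = mean Jaccard, mlPRE = mean |Y∩H|/|H| (0 when H empty),
    mlREC = mean |Y∩H|/|Y|, mlF1 = harmonic mean of the aggregate mlPRE and
    mlREC, ACC = exact-match rate.
    """
    Y, H = np.asarray(Y), np.asarray(H)
    _check_2d(Y, H)
    if np.any(Y.sum(axis=1) == 0):
        raise ValueError("every instance needs at least one true label")
    inter = np.sum((Y == 1) & (H == 1), axis=1)
    union = np.sum((Y == 1) | (H == 1), axis=1)
    ysz, hsz = Y.sum(axis=1), H.sum(axis=1)
    mlacc = float(np.mean(inter / union))
    mlpre = float(np.mean(np.divide(inter, hsz, out=np.zeros(len(Y)), where=hsz > 0)))
    mlrec = float(np.mean(inter / ysz))
    mlf1 = 0.0 if mlpre + mlrec == 0 else 2 * mlpre * mlrec / (mlpre + mlrec)
    acc = float(np.mean(np.all(Y == H, axis=1)))
    return SetMeasures(mlacc, mlpre, mlrec, mlf1, acc)


def ranking_report(Y: np.ndarray, H: np.ndarray, F: np.ndarray) -> dict[str, float]:
    """All eleven measures in one dict (macro-AUC reported as its mean)."""
    sm = set_measures(Y, H)
    auc, _ = macro_auc(Y, F)
    return {
        "hamming_loss": hamming_loss(Y, H),
        "one_error": one_error(Y, F),
        "coverage": coverage(Y, F),
        "ranking_loss": ranking_loss(Y, F),
        "average_precision": average_precision(Y, F),
        "macro_auc": auc,
        "mlacc": sm.mlacc,
        "mlpre": sm.mlpre,
        "mlrec": sm.mlrec,
        "mlf1": sm.mlf1,
        "acc": sm.acc,
    }
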