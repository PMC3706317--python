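"""Single-scale validation of a continuous score map against observations.

The workflow mirrors standard species-distribution-model practice: a ROC
curve over all valid grid cells gives a threshold-independent AUC; the
species presence threshold (SPT) is the score at the ROC point farthest
from the 1:1 line, i.e. the maximiser of Youden's J = TPR - FPR; the score
map dichotomised at the SPT is then scored against the observed
presence/absence map with Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import BinaryMap, ScoreMap, assert_coregistered

__all__ = [
    "RocCurve",
    "ConfusionCounts",
    "ValidationRecord",
    "roc_curve",
    "auc",
    "spt_threshold",
    "dichotomize",
    "confusion",
    "cohen_kappa",
]


@dataclass(frozen=True)
class RocCurve:
    """ROC curve as parallel arrays over strictly decreasing thresholds.

    The first point is (fpr, tpr) = (0, 0) (threshold above every score)
    and the last is (1, 1); tpr and fpr are non-decreasing along the curve.
    A cell is predicted present when its score is >= the threshold.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray

    def __post_init__(self) -> None:
        for name in ("thresholds", "tpr", "fpr"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not (np.diff(self.thresholds) < 0).all():
            raise ValueError("thresholds must be strictly decreasing")
        if (np.diff(self.tpr) < 0).any() or (np.diff(self.fpr) < 0).any():
            raise ValueError("tpr and fpr must be non-decreasing")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 contingency counts over valid cells."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ValidationRecord:
    """One Table-1-style row: AUC, SPT, pixel kappa and profile-mean kappa."""

    auc: float
    spt: float
    kappa_0: float
    kappa_mean: float


def roc_curve(scores: ScoreMap, observed: BinaryMap) -> RocCurve:
    """ROC of ``scores`` against a presence/absence map over valid cells.

    Candidate thresholds are the unique valid score values plus a sentinel
    above the maximum (the (0, 0) end of the curve); prediction rule is
    ``score >= threshold``.
    """
    assert_coregistered(scores, observed)
    s = scores.valid_values()
    y = observed.valid_values().astype(bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "observed map has a single class among valid cells; ROC undefined"
        )
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # last index of each tied block of scores
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = (distinct + 1) - tps
    thresholds = np.r_[s_sorted[0] + 1.0, s_sorted[distinct]]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC.

    Equals the Mann-Whitney concordance probability with ties counted 1/2.
    Reported raw even when below 0.5.
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def spt_threshold(curve: RocCurve) -> float:
    """Species presence threshold: ROC point farthest from the 1:1 line.

    Maximises Youden's J = tpr - fpr over the candidate thresholds; ties
    are broken toward the smallest threshold (the more inclusive range).
    """
    j = curve.tpr - curve.fpr
    winners = np.nonzero(j == j.max())[0]
    return float(curve.thresholds[winners].min())


def dichotomize(scores: ScoreMap, threshold: float) -> BinaryMap:
    """Presence wherever ``score >= threshold``; mask unchanged."""
    vals = (scores.values >= threshold).astype(np.int8)
    return BinaryMap(scores.meta, vals, scores.mask.copy())


def confusion(pred: BinaryMap, obs: BinaryMap) -> ConfusionCounts:
    """Contingency counts over valid cells only."""
    assert_coregistered(pred, obs)
    p = pred.valid_values().astype(bool)
    o = obs.valid_values().astype(bool)
    return ConfusionCounts(
        tp=int((p & o).sum()),
        fp=int((p & ~o).sum()),
        fn=int((~p & o).sum()),
        tn=int((~p & ~o).sum()),
    )


def cohen_kappa(counts: ConfusionCounts) -> float:
    """Chance-corrected agreement, (p_o - p_e) / (1 - p_e), in [-1, 1].

    When p_e = 1 (both maps constant, same class) the ratio is 0/0; we
    define the result as 1 for identical maps and 0 otherwise.  Small
    moving windows hit this case routinely, and a finite value keeps
    profile averages well defined.
    """
    n = counts.n
    if n < 1:
        raise ValueError("kappa needs at least one counted cell")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)
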