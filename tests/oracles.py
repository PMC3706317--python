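"""Independent brute-force oracles used to cross-check the fast paths.

Everything here enumerates explicitly: windows are materialised as cell
lists, AUC is counted pair by pair, the SPT is found by trying every
threshold.  These functions must stay naive — they are the reference the
package is tested against, not part of it.
"""

from __future__ import annotations

import math

import numpy as np


def disc_offsets(scale: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-scale, scale + 1)
        for dc in range(-scale, scale + 1)
        if dr * dr + dc * dc <= scale * scale
    ]


def kappa_from_counts(tp: int, fp: int, fn: int, tn: int) -> float:
    """Cohen's kappa with the constant-maps convention (1 if identical, else 0)."""
    n = tp + fp + fn + tn
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def brute_monoscale(
    a: np.ndarray,
    b: np.ndarray,
    mask: np.ndarray,
    scale: int,
    index: str,
    min_valid_fraction: float = 0.5,
) -> np.ndarray:
    """Window-by-window recomputation of one monoscale map."""
    nr, nc = mask.shape
    offsets = disc_offsets(scale)
    quota = max(3, math.ceil(min_valid_fraction * len(offsets)))
    out = np.full((nr, nc), np.nan)
    for r in range(nr):
        for c in range(nc):
            if not mask[r, c]:
                continue
            cells = [
                (r + dr, c + dc)
                for dr, dc in offsets
                if 0 <= r + dr < nr and 0 <= c + dc < nc and mask[r + dr, c + dc]
            ]
            if len(cells) < quota:
                continue
            av = np.array([a[i, j] for i, j in cells], dtype=float)
            bv = np.array([b[i, j] for i, j in cells], dtype=float)
            if index == "kappa":
                tp = int(((av == 1) & (bv == 1)).sum())
                fp = int(((av == 1) & (bv == 0)).sum())
                fn = int(((av == 0) & (bv == 1)).sum())
                tn = int(((av == 0) & (bv == 0)).sum())
                out[r, c] = kappa_from_counts(tp, fp, fn, tn)
            elif index == "D":
                out[r, c] = np.abs(av - bv).mean()
            elif index == "CC":
                if av.std() == 0 or bv.std() == 0:
                    continue
                out[r, c] = np.corrcoef(av, bv)[0, 1]
            else:
                raise ValueError(index)
    return out


def mann_whitney_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Concordance probability by exhaustive pair counting, ties = 1/2."""
    wins = 0.0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


def exhaustive_spt(scores: np.ndarray, labels: np.ndarray) -> float:
    """Try every candidate threshold; max of tpr - fpr, ties -> smallest."""
    labels = labels.astype(bool)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    candidates = sorted(set(scores.tolist())) + [scores.max() + 1.0]
    best_j, best_t = -np.inf, None
    for t in candidates:
        pred = scores >= t
        tpr = (pred & labels).sum() / n_pos
        fpr = (pred & ~labels).sum() / n_neg
        j = tpr - fpr
        if j > best_j or (j == best_j and t < best_t):
            best_j, best_t = j, t
    return float(best_t)
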