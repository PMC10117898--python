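"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the RMSD oracle is a
generic numeric minimization over rigid motions, the auROC oracle is the
pairwise Mann-Whitney statistic, and the AP oracle sums precision over
explicit per-threshold confusion tabulation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_rmsd(A: np.ndarray, B: np.ndarray, restarts: int = 6, seed: int = 0) -> float:
    """Minimum RMSD of B onto A over all proper rigid motions, by numeric
    optimization of (rotation-vector, translation) from multiple starts."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)

    def msd(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        d = B @ R.T + x[3:] - A
        return float(np.sum(d * d) / len(A))

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.zeros(3)] + [rng.uniform(-np.pi, np.pi, 3) for _ in range(restarts)]
    for rv in starts:
        R0 = Rotation.from_rotvec(rv).as_matrix()
        t0 = A.mean(axis=0) - B.mean(axis=0) @ R0.T
        res = minimize(msd, np.r_[rv, t0], method="BFGS",
                       options={"gtol": 1e-14, "maxiter": 2000})
        best = min(best, res.fun)
    return float(np.sqrt(max(best, 0.0)))


def mann_whitney_auc(scores, labels) -> float:
    """Pairwise probability that a positive outscores a negative (ties 0.5)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def stepwise_ap(scores, labels) -> float:
    """Average precision by explicit confusion tabulation at every distinct
    threshold, descending."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    P = int(y.sum())
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(s), reverse=True):
        pred = s >= t
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        recall = tp / P
        precision = tp / (tp + fp) if tp + fp else 0.0
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def textbook_pearson(x, y) -> float:
    """Pearson r by the sum-of-products formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(n * np.sum(x * x) - np.sum(x) ** 2) * np.sqrt(
        n * np.sum(y * y) - np.sum(y) ** 2
    )
    return float(num / den)


def midrank(values) -> np.ndarray:
    """Average ranks computed by explicit enumeration (independent of
    scipy.stats.rankdata)."""
    v = np.asarray(values, float)
    out = np.empty(len(v))
    for i, x in enumerate(v):
        less = np.sum(v < x)
        equal = np.sum(v == x)
        out[i] = less + (equal + 1) / 2.0
    return out
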