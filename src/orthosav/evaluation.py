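"""Evaluation statistics for variant-effect predictors.

Classification metrics treat clinically pathogenic variants as positives:
confusion counts at a threshold, the area under the ROC curve (trapezoidal
over all distinct score thresholds, so tied scores receive the Mann-Whitney
half-credit), and the step-wise average precision.  Association metrics are
Pearson's r (two-sided p from the t-distribution with n - 2 df) and
Spearman's rho (Pearson on mid-ranks), used e.g. to test whether predictor
scores rise with -log10 allele frequency, the signature of purifying
selection, or with evolutionary conservation.

The auROC here is computed from integer cumulative true/false-positive
counts with a single final division, which makes it *exactly* the
Mann-Whitney pairwise statistic rather than agreeing only approximately.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import UndefinedMetricError, ValidationError
from .predictor_io import (
    FLAG,
    LOWER_IS_DAMAGING,
    PATHOGENIC,
    BENIGN,
    LabeledVariantSet,
    PredictorScoreTable,
    neglog10_af,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN at one threshold; positives are pathogenic variants."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def rates(self) -> Dict[str, Optional[float]]:
        """TPR (= recall), FPR and precision; None where the denominator is 0."""
        tpr = self.TP / (self.TP + self.FN) if self.TP + self.FN else None
        fpr = self.FP / (self.TN + self.FP) if self.TN + self.FP else None
        prec = self.TP / (self.TP + self.FP) if self.TP + self.FP else None
        if tpr is None:
            logger.warning("no positive labels: TPR undefined")
        return {"TPR": tpr, "FPR": fpr, "precision": prec}


def _as_arrays(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be aligned 1-D arrays")
    if not np.all(np.isfinite(s)):
        raise ValidationError("scores must be finite")
    return s, y


def confusion_at_threshold(scores, labels, t: float, direction: str = "ge") -> ConfusionCounts:
    """Confusion counts calling damaging where score >= t (or <= t for
    ``direction='le'``)."""
    s, y = _as_arrays(scores, labels)
    pred = s >= t if direction == "ge" else s <= t
    return ConfusionCounts(
        TP=int(np.sum(pred & y)),
        FP=int(np.sum(pred & ~y)),
        TN=int(np.sum(~pred & ~y)),
        FN=int(np.sum(~pred & y)),
    )


def _ranked_counts(scores, labels):
    """Cumulative TP/FP at each distinct score threshold, descending."""
    s, y = _as_arrays(scores, labels)
    P, N = int(y.sum()), int((~y).sum())
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    # indices of the last element of each tie group
    boundaries = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    ends = np.r_[boundaries, s.size - 1]
    tp = np.cumsum(y)[ends]
    fp = np.cumsum(~y)[ends]
    return np.r_[0, tp], np.r_[0, fp], P, N


def auroc(scores, labels) -> float:
    """Area under the ROC curve, trapezoidal over distinct thresholds.

    Tied scores enter the curve simultaneously, which credits half a pair
    per tie; the result equals the Mann-Whitney statistic
    mean([s_pos > s_neg] + 0.5 [s_pos == s_neg]) exactly.
    """
    tp, fp, P, N = _ranked_counts(scores, labels)
    if P == 0 or N == 0:
        raise UndefinedMetricError("auROC needs at least one positive and one negative")
    # integer twice-area: sum of trapezoids (dFP) * (TP_i + TP_{i-1})
    area2 = int(np.sum(np.diff(fp) * (tp[1:] + tp[:-1])))
    return area2 / (2 * P * N)


def average_precision(scores, labels) -> float:
    """Step-wise (non-interpolated) average precision over the descending
    score ranking: AP = sum_k (R_k - R_{k-1}) * P_k at distinct thresholds."""
    tp, fp, P, N = _ranked_counts(scores, labels)
    if P == 0:
        raise UndefinedMetricError("average precision needs at least one positive")
    recall = tp / P
    with np.errstate(invalid="ignore"):
        precision = tp / np.maximum(tp + fp, 1)
    return float(np.sum(np.diff(recall) * precision[1:]))


def _t_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_r(x, y, method: str = "t") -> Tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value.

    ``method='t'`` uses the t-transform with n - 2 df; ``method='permutation'``
    enumerates all permutations exactly (only sensible for n <= 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("pearson_r needs >= 3 aligned pairs")
    xc, yc = x - x.mean(), y - y.mean()
    sx = float(np.sqrt(np.sum(xc**2)))
    sy = float(np.sqrt(np.sum(yc**2)))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedMetricError("correlation undefined for zero-variance input")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if method == "t":
        return r, _t_pvalue(r, x.size)
    if method == "permutation":
        if x.size > 10:
            raise ValidationError("exact permutation p-value limited to n <= 10")
        count = total = 0
        for perm in itertools.permutations(range(x.size)):
            yp = yc[list(perm)]
            rp = float(np.sum(xc * yp) / (sx * sy))
            count += abs(rp) >= abs(r) - 1e-12
            total += 1
        return r, count / total
    raise ValidationError(f"unknown p-value method {method!r}")


def spearman_rho(x, y, method: str = "t") -> Tuple[float, float]:
    """Spearman rank correlation: Pearson's r of mid-ranks (ties get
    average ranks), with the same p-value options as :func:`pearson_r`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("spearman_rho needs >= 3 aligned pairs")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    return pearson_r(rx, ry, method=method)


# ---------------------------------------------------------------------------
# Report over a score table + annotations
# ---------------------------------------------------------------------------

def _oriented_scores(table: PredictorScoreTable, name: str) -> pd.Series:
    """Scores oriented so that higher = more damaging."""
    col = table.scores[name]
    if table.meta[name].directionality == LOWER_IS_DAMAGING:
        return -col
    return col


def evaluate_predictors(
    table: PredictorScoreTable,
    annotations: LabeledVariantSet,
) -> pd.DataFrame:
    """Per-predictor evaluation report.

    For each score column: auROC and average precision against
    pathogenic/benign labels (scores oriented to higher-is-damaging), Pearson
    r of the score vs -log10 allele frequency (AF = 0 or missing excluded,
    logged), and Spearman rho vs conservation.  Metrics whose preconditions
    fail (one-class labels, < 3 pairs) are reported as NaN with a warning
    rather than raising.
    """
    ann = annotations.frame.reindex(table.scores.index)
    rows = []
    for name in table.predictors:
        oriented = _oriented_scores(table, name)
        entry: Dict[str, float] = {"predictor": name}
        labeled = ann["label"].isin([PATHOGENIC, BENIGN]) & oriented.notna()
        y = (ann.loc[labeled, "label"] == PATHOGENIC).to_numpy()
        s = oriented[labeled].to_numpy(dtype=float)
        try:
            entry["auroc"] = auroc(s, y)
            entry["average_precision"] = average_precision(s, y)
        except (UndefinedMetricError, ValidationError) as exc:
            logger.warning("%s: classification metrics undefined (%s)", name, exc)
            entry["auroc"] = np.nan
            entry["average_precision"] = np.nan
        af = ann["allele_frequency"]
        usable = oriented.notna() & af.notna() & (af > 0)
        n_zero = int((af == 0).sum())
        if n_zero:
            logger.info("%s: excluded %d zero-AF variants from correlation", name, n_zero)
        try:
            r, p = pearson_r(
                oriented[usable].to_numpy(dtype=float),
                np.array([neglog10_af(a) for a in af[usable]]),
            )
            entry["pearson_r_neglog10_af"], entry["pearson_p"] = r, p
        except (UndefinedMetricError, ValidationError) as exc:
            logger.warning("%s: AF correlation undefined (%s)", name, exc)
            entry["pearson_r_neglog10_af"] = entry["pearson_p"] = np.nan
        cons = ann["conservation"]
        usable = oriented.notna() & cons.notna()
        try:
            rho, p = spearman_rho(
                oriented[usable].to_numpy(dtype=float),
                cons[usable].to_numpy(dtype=float),
            )
            entry["spearman_rho_conservation"], entry["spearman_p"] = rho, p
        except (UndefinedMetricError, ValidationError) as exc:
            logger.warning("%s: conservation correlation undefined (%s)", name, exc)
            entry["spearman_rho_conservation"] = entry["spearman_p"] = np.nan
        rows.append(entry)
    return pd.DataFrame(rows).set_index("predictor")


def write_report(report: pd.DataFrame, tsv_path: str | Path, json_path: Optional[str | Path] = None) -> None:
    out = report.copy()
    out.insert(0, "predictor", out.index)
    out.to_csv(tsv_path, sep="\t", index=False, na_rep=".")
    if json_path is not None:
        Path(json_path).write_text(report.to_json(orient="index", indent=2))
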