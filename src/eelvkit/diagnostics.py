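"""Change-detection diagnostics: ROC, AUC with DeLong CI, Youden cutoffs.

How well does a change in the bedside reading (|delta EELV_WI-WO|, the
*score*) detect a true change in lung volume (|delta EELV_CT| above a
threshold, the *label*)?  For each true-change threshold the empirical ROC
curve is computed over all observed score values, the area under it (AUC)
with a 95% DeLong confidence interval, and the Youden-optimal cutoff with
the full set of confusion-table metrics (sensitivity, specificity,
predictive values, likelihood ratios, Youden J).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from eelvkit.errors import DegenerateDataError, DomainError
from eelvkit.trending import DeltaPair


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC for one true-change threshold."""

    threshold_true_change: float      # mL
    auc: float
    auc_ci_95: tuple[float, float]
    fpr: np.ndarray                   # 1 - specificity per candidate cutoff
    tpr: np.ndarray                   # sensitivity per candidate cutoff
    cutoffs: np.ndarray               # score cutoffs (descending)
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class CutpointMetrics:
    """Confusion-derived metrics at one score cutoff.

    Ratios with a zero denominator are reported as ``nan`` (missing),
    never as infinity.
    """

    cutoff: float   # mL
    se: float
    sp: float
    ppv: float
    npv: float
    plr: float
    nlr: float
    youden: float

    def to_dict(self) -> dict:
        return {
            "cutoff_mL": self.cutoff,
            "se": self.se,
            "sp": self.sp,
            "ppv": self.ppv,
            "npv": self.npv,
            "plr": self.plr,
            "nlr": self.nlr,
            "youden": self.youden,
        }


# ---------------------------------------------------------------------------
# operations


def roc_auc(scores, labels, threshold_true_change: float = float("nan")) -> RocResult:
    """Empirical ROC and AUC (trapezoidal / midrank convention) with a 95%
    DeLong confidence interval.

    ``labels`` are booleans (true change present); ``scores`` are the
    detector outputs (larger = more likely changed).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise DomainError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError(
            f"both classes required (positives={n_pos}, negatives={n_neg})"
        )
    fpr, tpr, cutoffs = roc_curve(labels, scores)
    auc, ci = _delong_auc_ci(scores, labels)
    return RocResult(
        threshold_true_change=threshold_true_change,
        auc=auc,
        auc_ci_95=ci,
        fpr=fpr,
        tpr=tpr,
        cutoffs=cutoffs,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def _delong_auc_ci(scores, labels, level: float = 0.95):
    """AUC and DeLong variance-based CI.

    The AUC equals the Mann-Whitney probability that a positive outscores
    a negative (ties count half); the variance comes from the structural
    components V10 (per positive) and V01 (per negative).
    """
    pos = scores[labels]
    neg = scores[~labels]
    n1, n0 = len(pos), len(neg)
    # midrank placement values
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(cmp.mean())
    v10 = cmp.mean(axis=1)  # per positive
    v01 = cmp.mean(axis=0)  # per negative
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + (
        np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return auc, (lo, hi)


def cutpoint_metrics(tp: int, fp: int, tn: int, fn: int, cutoff: float = float("nan")) -> CutpointMetrics:
    """Confusion-table metrics from raw counts.

    ``se = tp/(tp+fn)``, ``sp = tn/(tn+fp)``, ``ppv = tp/(tp+fp)``,
    ``npv = tn/(tn+fn)``, ``plr = se/(1-sp)``, ``nlr = (1-se)/sp``,
    ``youden = se + sp - 1``.  Undefined ratios are ``nan``.
    """
    counts = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    bad = {k: v for k, v in counts.items() if v < 0}
    if bad:
        raise DomainError(f"counts must be >= 0, got {bad}")
    if tp + fn == 0 or tn + fp == 0:
        raise DomainError("need at least one positive and one negative case")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    return CutpointMetrics(
        cutoff=cutoff,
        se=se,
        sp=sp,
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        plr=ratio(se, 1.0 - sp),
        nlr=ratio(1.0 - se, sp),
        youden=se + sp - 1.0,
    )


def youden_cutpoint(roc: RocResult, scores, labels) -> CutpointMetrics:
    """Cutoff maximizing Youden J = Se + Sp - 1 over observed score values.

    Ties are broken toward the larger cutoff (higher specificity).  The
    confusion table at the winning cutoff uses the decision rule
    ``score >= cutoff`` -> positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    j = roc.tpr - roc.fpr
    best_j = j.max()
    # roc_curve returns cutoffs in descending order; the first index
    # attaining the max J is the largest qualifying cutoff
    best_idx = int(np.argmax(j >= best_j - 1e-12))
    cutoff = float(roc.cutoffs[best_idx])
    pred = scores >= cutoff
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    return cutpoint_metrics(tp, fp, tn, fn, cutoff=cutoff)


def threshold_sweep(
    deltas: list[DeltaPair],
    thresholds=(100.0, 150.0, 200.0, 250.0, 300.0),
    require_direction: bool = False,
) -> list[tuple[RocResult | None, CutpointMetrics | None]]:
    """ROC + Youden metrics for each true-change threshold.

    For threshold ``t`` the label is ``|delta_ct| > t`` (strict) and the
    score is ``|delta_wiwo|``.  With ``require_direction=True`` a score
    only counts toward detection when the two methods also agree in sign:
    sign-discordant pairs get score 0.  A threshold yielding a single
    class produces a ``(None, None)`` row (flagged degenerate) rather
    than an error.
    """
    if not deltas:
        raise DegenerateDataError("no delta pairs supplied")
    d_ct = np.array([p.d_ct for p in deltas], dtype=float)
    d_wiwo = np.array([p.d_wiwo for p in deltas], dtype=float)
    scores = np.abs(d_wiwo)
    if require_direction:
        scores = np.where(d_ct * d_wiwo > 0, scores, 0.0)
    out = []
    for t in thresholds:
        labels = np.abs(d_ct) > t
        if labels.all() or not labels.any():
            out.append((None, None))
            continue
        roc = roc_auc(scores, labels, threshold_true_change=float(t))
        out.append((roc, youden_cutpoint(roc, scores, labels)))
    return out


def sweep_to_records(sweep, thresholds) -> list[dict]:
    """Flatten a threshold sweep into one record per threshold."""
    records = []
    for t, (roc, cp) in zip(thresholds, sweep):
        if roc is None:
            records.append({"threshold_mL": t, "degenerate": True})
            continue
        rec = {
            "threshold_mL": t,
            "degenerate": False,
            "auc": roc.auc,
            "auc_ci_lo": roc.auc_ci_95[0],
            "auc_ci_hi": roc.auc_ci_95[1],
            "n_positive": roc.n_positive,
            "n_negative": roc.n_negative,
        }
        rec.update(cp.to_dict())
        records.append(rec)
    return records
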