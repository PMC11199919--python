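"""Evaluation metrics for presence-only suitability predictions.

Ten quantities per evaluated model: discrimination (AUC of the ROC curve
by the Mann-Whitney statistic; area under the precision-recall-gain
curve), five confusion-matrix metrics at the TSS-maximizing threshold
(sensitivity, specificity, percent correctly classified, TSS, Cohen's
kappa), the continuous Boyce index computed against a landscape/background
sample, and two continuous scores (Pearson correlation of predictions
with the 0/1 labels and the mean absolute error). Because evaluation
"absences" are randomly sampled background points, all label-based
metrics are presence-only (PO) variants.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

__all__ = [
    "MetricReport",
    "confusion_metrics",
    "auc_roc",
    "auc_prg",
    "continuous_boyce_index",
    "continuous_scores",
    "max_tss_threshold",
    "compute_report",
]

METRIC_NAMES = (
    "auc_roc", "tss", "kappa", "sensitivity", "specificity",
    "pcc", "cbi", "auc_prg", "cor", "mae",
)


@dataclass
class MetricReport:
    """The ten evaluation metrics plus the confusion threshold used."""

    auc_roc: float
    tss: float
    kappa: float
    sensitivity: float
    specificity: float
    pcc: float
    cbi: float
    auc_prg: float
    cor: float
    mae: float
    threshold: float = np.nan

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})


def _check_two_class(obs: np.ndarray) -> None:
    if obs.min() == obs.max():
        raise ValueError("observations must contain both classes")


def confusion_metrics(pred: np.ndarray, obs: np.ndarray, threshold: float):
    """Sensitivity, specificity, PCC, TSS, and kappa at one threshold.

    Predictions at or above the threshold classify as presence.
    """
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, int)
    _check_two_class(obs)
    hat = pred >= threshold
    tp = int(np.sum(hat & (obs == 1)))
    fn = int(np.sum(~hat & (obs == 1)))
    tn = int(np.sum(~hat & (obs == 0)))
    fp = int(np.sum(hat & (obs == 0)))
    n = tp + fn + tn + fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    pcc = (tp + tn) / n
    tss = sens + spec - 1.0
    po = pcc
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = 0.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return {"sensitivity": sens, "specificity": spec, "pcc": pcc, "tss": tss, "kappa": kappa}


def auc_roc(pred_presence: np.ndarray, pred_absence: np.ndarray) -> float:
    """ROC AUC by the Mann-Whitney statistic: P(s_p > s_a) + P(tie)/2."""
    sp = np.asarray(pred_presence, float)
    sa = np.asarray(pred_absence, float)
    if len(sp) == 0 or len(sa) == 0:
        raise ValueError("both prediction sets must be nonempty")
    ranks = rankdata(np.concatenate([sp, sa]))
    u = ranks[: len(sp)].sum() - len(sp) * (len(sp) + 1) / 2.0
    return float(u / (len(sp) * len(sa)))


def _prg_points(pred_presence: np.ndarray, pred_absence: np.ndarray):
    """Confusion counts at every distinct threshold, scores descending."""
    scores = np.concatenate([pred_presence, pred_absence])
    labels = np.concatenate([np.ones(len(pred_presence)), np.zeros(len(pred_absence))])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    tp = np.cumsum(labels)
    fp = np.cumsum(1 - labels)
    distinct = np.nonzero(np.diff(scores))[0]
    idx = np.r_[distinct, len(scores) - 1]
    return tp[idx], fp[idx]


def auc_prg(pred_presence: np.ndarray, pred_absence: np.ndarray) -> float:
    """Area under the precision-recall-gain curve.

    Precision and recall are transformed to gains g(v) = (v - pi) /
    ((1 - pi) v) with pi the positive prevalence; the area is the
    piecewise-linear integral of precision gain over recall gain on
    [0, 1], entering the curve at the recall-gain = 0 crossing. Always
    <= 1; can be negative for worse-than-baseline rankings.
    """
    sp = np.asarray(pred_presence, float)
    sa = np.asarray(pred_absence, float)
    if len(sp) == 0 or len(sa) == 0:
        raise ValueError("both prediction sets must be nonempty")
    P, N = len(sp), len(sa)
    pi = P / (P + N)
    tp, fp = _prg_points(sp, sa)
    fn = P - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        rg = 1.0 - (pi / (1.0 - pi)) * (fn / tp)
        pg = 1.0 - (pi / (1.0 - pi)) * (fp / tp)
    valid = tp > 0
    rg, pg = rg[valid], pg[valid]
    if len(rg) == 0:
        return 0.0

    area = 0.0
    prev_rg, prev_pg = None, None
    for i in range(len(rg)):
        cur_rg, cur_pg = rg[i], pg[i]
        if prev_rg is not None and cur_rg > prev_rg:
            lo_rg, lo_pg, hi_rg, hi_pg = prev_rg, prev_pg, cur_rg, cur_pg
            if hi_rg > 0:
                if lo_rg < 0:  # interpolate the crossing at recall gain 0
                    w = (0.0 - lo_rg) / (hi_rg - lo_rg)
                    lo_pg = lo_pg + w * (hi_pg - lo_pg)
                    lo_rg = 0.0
                area += (hi_rg - lo_rg) * 0.5 * (lo_pg + hi_pg)
        prev_rg, prev_pg = cur_rg, cur_pg
    return float(area)


def continuous_boyce_index(
    pred_presence: np.ndarray,
    pred_landscape: np.ndarray,
    n_windows: int = 101,
    window_frac: float = 0.1,
) -> float:
    """Continuous Boyce index.

    Moving windows of width ``window_frac`` x the landscape prediction
    range, with ``n_windows`` evenly spaced centers, each yield a
    predicted-to-expected ratio P/E = (fraction of presences in window) /
    (fraction of landscape in window); the index is the Spearman rank
    correlation between window center and P/E over windows with E > 0.
    A well-calibrated model yields monotonically increasing P/E, hence an
    index near +1.
    """
    sp = np.asarray(pred_presence, float)
    sl = np.asarray(pred_landscape, float)
    if n_windows < 3:
        raise ValueError("n_windows must be >= 3")
    if len(sl) < len(sp):
        raise ValueError("landscape sample must be at least as large as presences")
    lo, hi = sl.min(), sl.max()
    width = window_frac * (hi - lo)
    if width <= 0:
        raise ValueError("landscape predictions have zero range")
    centers = np.linspace(lo + width / 2, hi - width / 2, n_windows)
    pe, used = [], []
    for c in centers:
        a, b = c - width / 2, c + width / 2
        e = np.mean((sl >= a) & (sl <= b))
        if e == 0:
            continue
        p = np.mean((sp >= a) & (sp <= b))
        pe.append(p / e)
        used.append(c)
    if len(used) < 3:
        raise ValueError("too few windows with landscape support")
    rho = spearmanr(used, pe).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def continuous_scores(pred: np.ndarray, obs: np.ndarray):
    """Mean absolute error and Pearson correlation of pred vs 0/1 labels."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if len(pred) == 0:
        raise ValueError("empty input")
    mae = float(np.mean(np.abs(pred - obs)))
    _check_two_class(obs.astype(int))
    if pred.std() == 0:
        raise ValueError("constant predictions: correlation undefined")
    cor = float(np.corrcoef(pred, obs)[0, 1])
    return {"cor": cor, "mae": mae}


def max_tss_threshold(pred: np.ndarray, obs: np.ndarray) -> float:
    """Threshold (among distinct predicted values) maximizing the TSS.

    Ties resolve to the smallest such threshold.
    """
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, int)
    _check_two_class(obs)
    cand = np.unique(pred)  # ascending
    P = (obs == 1).sum()
    N = (obs == 0).sum()
    # at threshold t: positives are pred >= t
    tp = np.array([(pred[obs == 1] >= t).sum() for t in cand])
    fp = np.array([(pred[obs == 0] >= t).sum() for t in cand])
    tss = tp / P + (N - fp) / N - 1.0
    return float(cand[int(np.argmax(tss))])


def compute_report(
    pred_presence: np.ndarray,
    pred_absence: np.ndarray,
    pred_landscape: np.ndarray | None = None,
    threshold: float | None = None,
    *,
    n_windows: int = 101,
    window_frac: float = 0.1,
) -> MetricReport:
    """Assemble the full ten-metric report for one evaluated model.

    ``pred_absence`` holds the sampled background (pseudo-absence)
    predictions; ``pred_landscape`` the background sample used by the
    Boyce index (defaults to ``pred_absence``). The confusion threshold
    defaults to the TSS-maximizing threshold on these points.
    """
    pred_presence = np.asarray(pred_presence, float)
    pred_absence = np.asarray(pred_absence, float)
    pred = np.concatenate([pred_presence, pred_absence])
    obs = np.concatenate([np.ones(len(pred_presence), int), np.zeros(len(pred_absence), int)])
    if threshold is None:
        threshold = max_tss_threshold(pred, obs)
    conf = confusion_metrics(pred, obs, threshold)
    cont = continuous_scores(pred, obs)
    if pred_landscape is None:
        pred_landscape = pred_absence
    landscape = np.asarray(pred_landscape, float)
    if len(landscape) < len(pred_presence):
        landscape = np.concatenate([landscape, pred_absence])
    try:
        cbi = continuous_boyce_index(pred_presence, landscape, n_windows, window_frac)
    except ValueError:
        cbi = np.nan
    return MetricReport(
        auc_roc=auc_roc(pred_presence, pred_absence),
        tss=conf["tss"],
        kappa=conf["kappa"],
        sensitivity=conf["sensitivity"],
        specificity=conf["specificity"],
        pcc=conf["pcc"],
        cbi=cbi,
        auc_prg=auc_prg(pred_presence, pred_absence),
        cor=cont["cor"],
        mae=cont["mae"],
        threshold=float(threshold),
    )
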