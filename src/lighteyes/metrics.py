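"""Pixel-wise segmentation evaluation.

Counts are tallied pixel-by-pixel, optionally restricted to a field-of-view
(FOV) mask — the circular region of a fundus photograph that images the
retina; vessel benchmarks conventionally exclude everything outside it.
Point metrics (Se/Sp/Pr/Re/F1/JI/Acc) are computed from a single
binarization of the probability map at the *equilibrium point*: the
threshold at which precision and recall are closest on the PR curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "scalar_metrics",
    "ji_from_pr_re",
    "pr_curve",
    "equilibrium_threshold",
    "roc_auc",
    "evaluate_maps",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    se: float  # sensitivity = recall
    sp: float
    pr: float
    f1: float
    ji: float
    acc: float
    auc: float | None = None
    threshold: float | None = None

    @property
    def re(self) -> float:
        return self.se

    def to_dict(self) -> dict:
        return {
            "Se": self.se, "Sp": self.sp, "Pr": self.pr, "Re": self.re,
            "F1": self.f1, "JI": self.ji, "Acc": self.acc, "AUC": self.auc,
            "threshold": self.threshold,
        }

    def to_text(self) -> str:
        parts = [f"{k:<10}{'' if v is None else format(v, '.4f')}"
                 for k, v in self.to_dict().items()]
        return "\n".join(parts)


def _flatten(pred, gt, fov=None):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if fov is not None:
        fov = np.asarray(fov).astype(bool)
        if fov.shape != gt.shape:
            raise ValueError(f"shape mismatch: fov {fov.shape} vs gt {gt.shape}")
        return pred[fov], gt[fov]
    return pred.ravel(), gt.ravel()


def confusion(binary_pred, gt, fov=None) -> ConfusionCounts:
    """Pixel confusion counts; pixels outside ``fov`` are excluded entirely."""
    pred, gt = _flatten(binary_pred, gt, fov)
    pred = pred.astype(bool)
    gt = gt.astype(bool)
    tp = int(np.sum(pred & gt))
    fp = int(np.sum(pred & ~gt))
    fn = int(np.sum(~pred & gt))
    tn = int(np.sum(~pred & ~gt))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def scalar_metrics(counts: ConfusionCounts) -> MetricReport:
    """Se/Sp/Pr/F1/JI/Acc from confusion counts (exact ratios)."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    se = _ratio(tp, tp + fn, "Se")
    sp = _ratio(tn, tn + fp, "Sp")
    pr = _ratio(tp, tp + fp, "Pr")
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "F1")
    ji = _ratio(tp, tp + fp + fn, "JI")
    acc = _ratio(tp + tn, counts.total, "Acc")
    return MetricReport(se=se, sp=sp, pr=pr, f1=f1, ji=ji, acc=acc)


def ji_from_pr_re(pr: float, re: float) -> float:
    """Jaccard index implied by precision and recall alone.

    From JI = TP/(TP+FP+FN): 1/JI = 1/Pr + 1/Re - 1, independent of the
    underlying counts.
    """
    if not (0.0 < pr <= 1.0 and 0.0 < re <= 1.0):
        raise ValueError("Pr and Re must lie in (0, 1]")
    return 1.0 / (1.0 / pr + 1.0 / re - 1.0)


def _threshold_grid(probs: np.ndarray, n_grid: int = 256, max_exact: int = 10_000):
    grid = np.linspace(0.0, 1.0, n_grid)
    if probs.size <= max_exact:
        grid = np.union1d(grid, np.unique(probs))
    return grid


def pr_curve(prob_map, gt, fov=None, grid=None):
    """Precision and recall at each threshold (pred = p >= t).

    Returns ``(thresholds, precision, recall)``; precision is NaN where no
    pixel is predicted foreground.
    """
    p, y = _flatten(prob_map, gt, fov)
    y = y.astype(bool)
    if grid is None:
        grid = _threshold_grid(p)
    grid = np.asarray(grid, dtype=np.float64)
    order = np.argsort(p)  # ascending
    ps, ys = p[order], y[order]
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("ground truth has no foreground; recall undefined")
    # pixels with p >= t: suffix counts
    cum_pos = np.concatenate([[0], np.cumsum(ys)])  # fg among the first i
    idx = np.searchsorted(ps, grid, side="left")
    n_pred = p.size - idx
    tp = n_pos - cum_pos[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(n_pred > 0, tp / np.maximum(n_pred, 1), np.nan)
    recall = tp / n_pos
    return grid, precision, recall


def equilibrium_threshold(prob_map, gt, fov=None, grid=None):
    """Threshold minimising |Pr - Re| over the grid, plus the binarized map.

    The sweep covers 256 evenly spaced thresholds, augmented with every
    distinct probability when the map is small (<= 10^4 pixels).  Ties are
    broken toward the lower threshold (higher recall).  Thresholds at which
    precision is undefined (no predicted foreground) are skipped.
    """
    p = np.asarray(prob_map, dtype=np.float64)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    thr, pr, re = pr_curve(p, gt, fov, grid)
    gap = np.abs(pr - re)
    valid = ~np.isnan(gap)
    if not valid.any():
        raise ValueError("precision undefined at every threshold")
    gmin = np.nanmin(gap)
    best = float(thr[valid & (gap <= gmin)][0])  # lowest threshold wins ties
    return best, (p >= best).astype(np.uint8)


def roc_auc(prob_map, gt, fov=None) -> float:
    """Area under the ROC curve (equals the Mann-Whitney statistic)."""
    p, y = _flatten(prob_map, gt, fov)
    y = y.astype(int)
    if y.min() == y.max():
        raise ValueError("ROC-AUC undefined: ground truth has a single class")
    return float(roc_auc_score(y, p))


def evaluate_maps(prob_maps, gts, fovs=None, grid=None) -> MetricReport:
    """Dataset-level evaluation of probability maps.

    Pixels of all images are concatenated (inside each FOV when given), a
    single global equilibrium threshold is selected, and all metrics are
    computed from the pooled confusion counts.
    """
    if fovs is None:
        fovs = [None] * len(prob_maps)
    ps, ys = [], []
    for pm, gt, fov in zip(prob_maps, gts, fovs):
        p, y = _flatten(pm, gt, fov)
        ps.append(p)
        ys.append(y)
    p = np.concatenate(ps)
    y = np.concatenate(ys).astype(np.uint8)
    thr, pred = equilibrium_threshold(p, y, grid=grid)
    counts = confusion(pred, y)
    report = scalar_metrics(counts)
    report.auc = roc_auc(p, y)
    report.threshold = thr
    return report
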