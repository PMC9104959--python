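"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the library's own computational paths:
the receptive-field oracle uses forward perturbations only (never the
hand-written backward pass), AUC uses the O(n^2) pairwise Mann-Whitney
definition, confusion counts use an explicit per-pixel Python loop, and the
equilibrium threshold is found by exhaustively evaluating every cut.
"""

from __future__ import annotations

import numpy as np

from lighteyes._nn import Conv2d
from lighteyes.model import LightEyesModel


def make_positive_model(config) -> LightEyesModel:
    """Build a model with constant positive weights and zero biases.

    On a non-negative input every activation is then non-negative (ReLUs
    pass everything through) and, crucially, a unit's value is *strictly
    positive* exactly when some positive input pixel lies inside its
    receptive field, and *exactly zero* otherwise — convolutions of exact
    zeros stay exact zeros in floating point, so support detection needs no
    tolerance at all.
    """
    model = LightEyesModel(config)
    for _name, layer, _ in model.nodes:
        if isinstance(layer, Conv2d):
            fan_in = layer.kernel**2 * layer.in_channels
            layer.W = np.full_like(layer.W, 1.0 / fan_in)
            layer.b = np.zeros_like(layer.b)
    return model


def _tap_center(model: LightEyesModel, image: np.ndarray, tap: str) -> float:
    maps_unused = model.forward(image, keep_cache=True)
    act = model.activation(tap)
    _, h, w = act.shape
    return float(act[0, h // 2, w // 2])


def receptive_field_bruteforce(
    model: LightEyesModel, tap: str, size: int = 80, axis: int = 0
) -> int:
    """Support size, along one axis, of the input region influencing the
    tap's centre unit, measured by forward passes only (requires a
    ``make_positive_model`` network).

    Feeds an image that is zero everywhere except one full input row (or
    column) and checks whether the tap centre is nonzero.  On the
    positive-weight zero-bias network this is exact: reachable taps are
    strictly positive, unreachable ones identically zero.  The support is a
    contiguous interval around the centre, so its two ends are located by
    bisection.
    """

    def affects(i: int) -> bool:
        img = np.zeros((size, size, 3))
        if axis == 0:
            img[i, :, :] = 1.0
        else:
            img[:, i, :] = 1.0
        return _tap_center(model, img, tap) > 0.0

    mid = size // 2
    assert affects(mid), "tap centre must depend on the central input row"
    # lowest affecting index in [0, mid]
    lo_lo, lo_hi = 0, mid
    while lo_lo < lo_hi:
        m = (lo_lo + lo_hi) // 2
        if affects(m):
            lo_hi = m
        else:
            lo_lo = m + 1
    # highest affecting index in [mid, size-1]
    hi_lo, hi_hi = mid, size - 1
    while hi_lo < hi_hi:
        m = (hi_lo + hi_hi + 1) // 2
        if affects(m):
            hi_lo = m
        else:
            hi_hi = m - 1
    return hi_lo - lo_lo + 1


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """O(n^2) pairwise AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def confusion_loop(pred, gt, fov=None):
    """Per-pixel Python-loop confusion tally -> (tp, fp, fn, tn)."""
    pred = np.asarray(pred).ravel()
    gt = np.asarray(gt).ravel()
    fov = None if fov is None else np.asarray(fov).ravel()
    tp = fp = fn = tn = 0
    for i in range(pred.size):
        if fov is not None and not fov[i]:
            continue
        p, g = bool(pred[i]), bool(gt[i])
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and g:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def equilibrium_exhaustive(probs, gt):
    """Evaluate |Pr - Re| at every distinct cut (including one below the
    minimum); returns (best_threshold, best_gap) with low-threshold ties."""
    probs = np.asarray(probs, dtype=float).ravel()
    gt = np.asarray(gt).ravel().astype(bool)
    cuts = sorted(set(probs.tolist()) | {0.0})
    best_t, best_gap = None, np.inf
    for t in cuts:
        pred = probs >= t
        tp = int((pred & gt).sum())
        n_pred = int(pred.sum())
        if n_pred == 0:
            continue
        pr = tp / n_pred
        re = tp / int(gt.sum())
        gap = abs(pr - re)
        if gap < best_gap - 1e-15:
            best_t, best_gap = t, gap
    return best_t, best_gap
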