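"""Random-drop loss for class-imbalanced pixel classification.

Foreground structures (vessels, and especially microaneurysms at ~0.1% of
pixels) are vastly outnumbered by background.  The class-balanced
cross-entropy reweights the two sums by beta = Nn/(Nn+Np); the random-drop
variant additionally discards each *background* pixel stochastically with
probability pdrop(p_j) — by default the linear function 1 - p_j — so easy,
confidently-background pixels stop contributing gradient while hard
negatives (high activation) are almost always retained:

    L(p, y) = -beta * sum_{y_j=1} log p_j
              - (1-beta) * sum_{y_j=0} keep_j * log(1 - p_j)

with beta recomputed per draw from the retained background count Nn and the
foreground count Np.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .config import DropLossConfig

__all__ = [
    "LossBreakdown",
    "linear_drop",
    "no_drop",
    "random_drop_indicator",
    "compute_beta",
    "random_drop_loss",
    "class_balanced_ce",
]

EPS = 1e-7  # probability clamp keeping both logs finite


def linear_drop(p: np.ndarray) -> np.ndarray:
    """Linear drop function pdrop(p) = 1 - p (keep probability = p)."""
    return 1.0 - p


def no_drop(p: np.ndarray) -> np.ndarray:
    """Drop function of the class-balanced baseline: keep everything."""
    return np.zeros_like(p)


@dataclass
class LossBreakdown:
    """Value and bookkeeping of one loss evaluation (one head, one draw)."""

    loss: float
    beta: float
    n_pos: int
    n_neg_kept: int
    keep_mask: np.ndarray  # True where a background pixel was retained
    grad_p: np.ndarray  # dL/dp, same shape as the probability map


def _validate_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return p


def random_drop_indicator(
    p_background: np.ndarray,
    rng: np.random.Generator,
    drop_function: Callable[[np.ndarray], np.ndarray] = linear_drop,
    r: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean keep mask over background pixels.

    Pixel j is kept iff r_j >= pdrop(p_j) with r_j ~ Uniform(0,1) drawn
    independently per pixel (``r`` may be supplied explicitly for
    deterministic checks).  Under the linear drop function the keep
    probability equals p_j exactly.
    """
    p = _validate_probs(p_background)
    pdrop = drop_function(p)
    if r is None:
        r = rng.random(p.shape)
    return np.asarray(r) >= pdrop


def compute_beta(n_neg_kept: int, n_pos: int) -> float:
    """Weight factor beta = Nn / (Nn + Np) from retained-background and
    foreground pixel counts."""
    if n_neg_kept < 0 or n_pos < 0:
        raise ValueError("pixel counts must be non-negative")
    if n_neg_kept + n_pos == 0:
        raise ValueError("empty supervision: no foreground and no retained background")
    return n_neg_kept / (n_neg_kept + n_pos)


def _validate_pair(p: np.ndarray, y: np.ndarray):
    p = _validate_probs(p)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("ground truth must be binary (0/1)")
    return p, y.astype(bool)


def random_drop_loss(
    p: np.ndarray,
    y: np.ndarray,
    config: DropLossConfig | None = None,
    rng: np.random.Generator | int | None = None,
    drop_function: Callable[[np.ndarray], np.ndarray] | None = None,
    r: np.ndarray | None = None,
) -> LossBreakdown:
    """Evaluate the random-drop loss on one probability map.

    Parameters
    ----------
    p, y : arrays of equal shape
        Predicted foreground probabilities and binary ground truth.
    config : DropLossConfig, optional
        ``kind='class_balanced'`` switches the drop function off;
        ``reduction='mean'`` divides by the supervised pixel count.
    rng : numpy Generator or seed
        Source of the per-pixel uniform draws.
    drop_function, r : overrides for the drop rule and the uniform draws
        (``r`` must then cover the background pixels, in row-major order).
    """
    config = config or DropLossConfig()
    if drop_function is None:
        drop_function = no_drop if config.kind == "class_balanced" else linear_drop
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    p, fg = _validate_pair(p, y)
    bg = ~fg
    pc = np.clip(p, EPS, 1.0 - EPS)

    if r is None:
        r_bg = None
    else:
        r_arr = np.asarray(r, dtype=np.float64)
        # full-map r: pick the background entries; else r lists bg pixels
        r_bg = r_arr[bg] if r_arr.shape == p.shape else r_arr.ravel()
        if r_bg.size != int(bg.sum()):
            raise ValueError("r must cover every background pixel")
    keep_bg = random_drop_indicator(p[bg], rng, drop_function, r=r_bg)
    keep_mask = np.zeros(p.shape, dtype=bool)
    keep_mask[bg] = keep_bg

    n_pos = int(fg.sum())
    n_neg = int(keep_bg.sum())
    beta = compute_beta(n_neg, n_pos)

    fg_term = -np.log(pc[fg]).sum()
    bg_term = -np.log(1.0 - pc[keep_mask]).sum()
    loss = beta * fg_term + (1.0 - beta) * bg_term

    grad = np.zeros_like(pc)
    grad[fg] = -beta / pc[fg]
    grad[keep_mask] = (1.0 - beta) / (1.0 - pc[keep_mask])

    if config.reduction == "mean":
        n_sup = max(n_pos + n_neg, 1)
        loss /= n_sup
        grad /= n_sup

    return LossBreakdown(
        loss=float(loss),
        beta=beta,
        n_pos=n_pos,
        n_neg_kept=n_neg,
        keep_mask=keep_mask,
        grad_p=grad,
    )


def class_balanced_ce(
    p: np.ndarray,
    y: np.ndarray,
    config: DropLossConfig | None = None,
) -> LossBreakdown:
    """Class-balanced cross-entropy: the same weighting with every
    background pixel retained (drop function identically zero)."""
    base = config or DropLossConfig()
    cfg = DropLossConfig(
        kind="class_balanced",
        reduction=base.reduction,
        heads=base.heads,
        head_weights=base.head_weights,
    )
    return random_drop_loss(p, y, cfg, rng=0)
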