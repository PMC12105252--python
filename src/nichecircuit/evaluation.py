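"""Presence-only and presence/absence model evaluation metrics.

The continuous Boyce index is the primary presence-only metric: the
Spearman rank correlation between habitat-suitability class (moving
windows over the prediction range) and the predicted-to-expected (P/E)
presence frequency ratio.  It ranges from -1 (counter prediction)
through 0 (no better than chance) to +1 (optimal prediction).

The True Skill Statistic (TSS) is sensitivity + specificity - 1
maximized over all classification thresholds.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["boyce_index", "tss"]


def boyce_index(
    presence_pred: np.ndarray,
    background_pred: np.ndarray,
    n_classes: int = 101,
    window_frac: float = 0.1,
) -> float:
    """Continuous Boyce index.

    Parameters
    ----------
    presence_pred : array
        Predicted suitability at (test) presence localities.
    background_pred : array
        Predicted suitability over the study area (all valid cells).
    n_classes : int
        Number of overlapping moving windows.
    window_frac : float
        Window width as a fraction of the prediction range.

    Returns
    -------
    float
        Spearman correlation between window midpoint and P/E ratio,
        in [-1, 1].
    """
    pres = np.asarray(presence_pred, dtype=float)
    bg = np.asarray(background_pred, dtype=float)
    pres = pres[np.isfinite(pres)]
    bg = bg[np.isfinite(bg)]
    if pres.size == 0 or bg.size == 0:
        raise ValueError("empty presence or background predictions")
    lo, hi = bg.min(), bg.max()
    if hi <= lo:
        raise ValueError("constant background predictions: Boyce undefined")
    width = window_frac * (hi - lo)
    starts = np.linspace(lo, hi - width, n_classes)
    mids = starts + width / 2.0
    P = np.empty(n_classes)
    E = np.empty(n_classes)
    for k, s in enumerate(starts):
        in_w_p = (pres >= s) & (pres <= s + width)
        in_w_b = (bg >= s) & (bg <= s + width)
        P[k] = in_w_p.mean()
        E[k] = in_w_b.mean()
    keep = E > 0
    if keep.sum() < 2:
        raise ValueError("fewer than two suitability classes with background support")
    ratio = P[keep] / E[keep]
    if np.all(ratio == ratio[0]):
        return 0.0
    rho, _ = stats.spearmanr(mids[keep], ratio)
    return float(rho)


def tss(predictions: np.ndarray, labels: np.ndarray) -> float:
    """True Skill Statistic: max over thresholds of sens + spec - 1."""
    from sklearn.metrics import roc_curve

    y = np.asarray(labels)
    p = np.asarray(predictions, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("TSS needs both classes present")
    fpr, tpr, _ = roc_curve(y, p)
    return float(np.max(tpr - fpr))
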