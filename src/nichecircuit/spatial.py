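"""Spatial autocorrelation diagnostics and spatially blocked validation.

Model residuals in species distribution modelling are typically
spatially autocorrelated; evaluating on randomly split data then
overstates performance.  The workflow here follows standard practice:

1. fit preliminary models and compute residuals at the training points;
2. build a Moran's I correlogram of those residuals over distance bins;
3. read off the spatial autocorrelation range (SAR) — the distance at
   which Moran's I stably approaches zero;
4. assign checkerboard cross-validation folds with a block size larger
   than the SAR, so train and test points are spatially independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "Correlogram",
    "morans_correlogram",
    "residual_correlogram",
    "estimate_sar",
    "checkerboard_folds",
]


@dataclass(frozen=True)
class Correlogram:
    """Moran's I per distance bin.

    ``distance_bins`` holds strictly increasing bin midpoints (map
    units); ``morans_i`` is NaN where a bin has no point pairs.
    """

    distance_bins: np.ndarray
    morans_i: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.distance_bins) > 0):
            raise ValueError("distance bins must be strictly increasing")


def morans_correlogram(
    xy: np.ndarray,
    values: np.ndarray,
    bin_width: float,
    max_dist: float,
) -> Correlogram:
    """Moran's I of ``values`` at point locations, per distance bin.

    Binary weights: w_ij = 1 iff the pair distance falls in the bin.
    I = (n / sum w) * sum_ij w_ij z_i z_j / sum_i z_i^2 with
    z = values - mean(values).
    """
    xy = np.asarray(xy, dtype=float)
    z = np.asarray(values, dtype=float)
    n = len(z)
    if n < 3:
        warnings.warn("fewer than 3 points: Moran's I is degenerate", stacklevel=2)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero residual variance: Moran's I undefined")
    dm_u = pdist(xy)  # condensed order matches triu_indices(n, 1)
    iu, ju = np.triu_indices(n, k=1)
    cr_u = z[iu] * z[ju]
    edges = np.arange(0.0, max_dist + bin_width, bin_width)
    if len(edges) < 2:
        raise ValueError("max_dist must exceed bin_width")
    mids = (edges[:-1] + edges[1:]) / 2.0
    morans = np.full(len(mids), np.nan)
    n_pairs = np.zeros(len(mids), dtype=np.int64)
    for k in range(len(mids)):
        in_bin = (dm_u >= edges[k]) & (dm_u < edges[k + 1])
        cnt = int(in_bin.sum())
        n_pairs[k] = cnt
        if cnt > 0:
            # symmetric weights count both (i,j) and (j,i); the factors
            # of two in numerator and sum-of-weights cancel
            morans[k] = n * float(cr_u[in_bin].sum()) / (cnt * denom)
    return Correlogram(distance_bins=mids, morans_i=morans, n_pairs=n_pairs)


def residual_correlogram(model, ds, bin_width: float, max_dist: float) -> Correlogram:
    """Correlogram of a fitted model's residuals on its training points.

    ``model`` must expose ``predict_df(X) -> probabilities``; ``ds`` is a
    presence/pseudo-absence dataset whose ``points`` DataFrame carries
    x, y, label and the predictor columns used by the model.
    """
    pts = ds.points if hasattr(ds, "points") else ds
    pred = model.predict_df(pts)
    resid = pts["label"].to_numpy(dtype=float) - np.asarray(pred, dtype=float)
    xy = pts[["x", "y"]].to_numpy(dtype=float)
    return morans_correlogram(xy, resid, bin_width, max_dist)


def estimate_sar(correlograms, tol: float = 0.05, min_pairs: int = 30) -> float:
    """Spatial autocorrelation range from one or more correlograms.

    The smallest bin midpoint d* such that I < tol at d* and every
    larger bin, across all supplied correlograms.  The criterion is
    one-sided: block size must exceed the range of *positive* residual
    autocorrelation, and Moran's I of positively autocorrelated data is
    biased negative at long lags (the per-bin values are tied to the
    global mean, so short-lag excess must be compensated), which would
    otherwise mask the stabilization.  Bins with fewer than
    ``min_pairs`` point pairs carry too much sampling noise to be
    informative (the usual correlogram rule of thumb is ~30 pairs per
    lag) and are skipped, as are empty bins.  If no correlogram
    stabilizes, returns the largest bin midpoint with a warning.
    """
    if isinstance(correlograms, Correlogram):
        correlograms = [correlograms]
    correlograms = list(correlograms)
    if not correlograms:
        raise ValueError("need at least one correlogram")
    sar = 0.0
    for cg in correlograms:
        ok = cg.morans_i < tol
        ok[~np.isfinite(cg.morans_i)] = True  # empty bins don't block
        ok[cg.n_pairs < min_pairs] = True  # under-supported bins don't block
        # first index from which all remaining bins are stable
        stable_from = len(ok)
        for k in range(len(ok) - 1, -1, -1):
            if ok[k]:
                stable_from = k
            else:
                break
        if stable_from >= len(ok):
            warnings.warn(
                "Moran's I never stabilizes below tolerance; returning max distance",
                stacklevel=2,
            )
            d_star = float(cg.distance_bins[-1])
        else:
            d_star = float(cg.distance_bins[stable_from])
        sar = max(sar, d_star)
    return sar


def checkerboard_folds(
    pts: pd.DataFrame,
    block_size: float,
    origin: tuple[float, float] | None = None,
) -> np.ndarray:
    """Two-fold checkerboard assignment of points to spatial blocks.

    Square blocks of side ``block_size`` are anchored at ``origin``
    (default: the minimum x/y of the points); fold =
    (block_row + block_col) mod 2.
    """
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    x = pts["x"].to_numpy(dtype=float)
    y = pts["y"].to_numpy(dtype=float)
    if origin is None:
        origin = (float(x.min()), float(y.min()))
    bx = np.floor((x - origin[0]) / block_size).astype(int)
    by = np.floor((y - origin[1]) / block_size).astype(int)
    folds = (bx + by) % 2
    if len(np.unique(folds)) < 2:
        raise ValueError(
            "all points fall in one checkerboard fold; use a smaller block size"
        )
    return folds
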