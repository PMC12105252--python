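"""Multi-scenario projection with extrapolation diagnostics.

Future projections combine several general circulation models (GCMs),
emission pathways (SSPs) and horizon years.  Where projection climates
leave the calibration range the model extrapolates; the Multivariate
Environmental Similarity Surface (MESS) quantifies that per cell, and a
dissimilarity-weighted average (MEDI) combines per-GCM projections so
that GCMs projecting conditions more similar to the calibration data
weigh more.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import Raster, RasterStack

__all__ = [
    "Scenario",
    "MESSRaster",
    "enumerate_scenarios",
    "mess",
    "medi_combine",
]


@dataclass(frozen=True)
class Scenario:
    """One (year, SSP, GCM) projection combination."""

    year: int
    ssp: str
    gcm: str

    @property
    def id(self) -> str:
        return f"{self.year}_ssp{self.ssp}_{self.gcm}"


def enumerate_scenarios(
    years: Sequence[int],
    ssps: Sequence[str],
    gcms: Sequence[str],
) -> list[Scenario]:
    """Cartesian product of years x SSPs x GCMs, ordered (year, ssp, gcm)."""
    if not years or not ssps or not gcms:
        raise ValueError("years, ssps and gcms must all be non-empty")
    return [
        Scenario(year=y, ssp=str(s), gcm=str(g))
        for y, s, g in itertools.product(years, ssps, gcms)
    ]


@dataclass
class MESSRaster:
    """MESS similarity raster with the per-cell most dissimilar variable.

    Negative values mark novel conditions: at least one variable outside
    its calibration range.
    """

    similarity: Raster
    most_dissimilar_var: np.ndarray  # per-cell variable name (object array)


def _mess_variable(cal: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Similarity of projection values ``p`` to calibration sample ``cal``
    for one variable (percent scale; negative = outside range)."""
    cal = np.sort(np.asarray(cal, dtype=float))
    vmin, vmax = cal[0], cal[-1]
    if vmax == vmin:
        raise ValueError("constant calibration variable: MESS undefined")
    n = cal.size
    f = 100.0 * np.searchsorted(cal, p, side="left") / n  # % of cal < p
    span = vmax - vmin
    sim = np.empty(p.shape, dtype=float)
    m0 = f == 0
    m100 = f == 100
    mlow = (f > 0) & (f <= 50)
    mhigh = (f > 50) & (f < 100)
    sim[m0] = (p[m0] - vmin) / span * 100.0
    sim[mlow] = 2.0 * f[mlow]
    sim[mhigh] = 2.0 * (100.0 - f[mhigh])
    sim[m100] = (vmax - p[m100]) / span * 100.0
    return sim


def mess(
    calibration: Mapping[str, np.ndarray] | pd.DataFrame,
    projection: RasterStack,
) -> MESSRaster:
    """Multivariate environmental similarity of a projection stack to a
    calibration sample.

    Per variable with projection value p and calibration percentile
    f = %(calibration < p): similarity is ``(p-min)/(max-min)*100`` at
    f = 0, ``2f`` for f <= 50, ``2(100-f)`` for f < 100 and
    ``(max-p)/(max-min)*100`` at f = 100 — negative below the minimum or
    above the maximum.  The MESS is the minimum over variables; the
    most dissimilar variable is the argmin.
    """
    if isinstance(calibration, pd.DataFrame):
        calibration = {c: calibration[c].dropna().to_numpy() for c in calibration}
    names = [n for n in projection.names if n in calibration]
    if not names:
        raise ValueError("no projection layer matches a calibration variable")
    grid = projection.grid
    sims = []
    for n in names:
        cal = np.asarray(calibration[n], dtype=float)
        cal = cal[np.isfinite(cal)]
        if cal.size == 0:
            raise ValueError(f"empty calibration sample for {n!r}")
        sims.append(_mess_variable(cal, projection[n].masked()))
    sims = np.stack(sims)
    idx = np.nanargmin(np.where(np.isnan(sims), np.inf, sims), axis=0)
    out = np.take_along_axis(sims, idx[None], axis=0)[0]
    out[np.isnan(sims).any(axis=0)] = np.nan
    var_names = np.asarray(names, dtype=object)[idx]
    return MESSRaster(
        similarity=grid.with_values(out, nodata=None),
        most_dissimilar_var=var_names,
    )


def medi_combine(
    projections: Mapping[str, Raster],
    mess_per_gcm: Mapping[str, Raster],
    eps: float = 1e-6,
) -> Raster:
    """Dissimilarity-weighted average of per-GCM projections.

    Per cell, each GCM's MESS value is rescaled to [0, 1] by the global
    (all-GCM) MESS range, shifted by ``eps``, and normalized into convex
    weights; the output is the weighted mean of the projections — a
    convex combination bounded by the member projections.  A zero global
    MESS range yields equal weights.
    """
    gcms = list(projections)
    if len(gcms) < 2:
        raise ValueError("need at least two GCMs to combine")
    grid = projections[gcms[0]]
    for g in gcms:
        if not grid.same_grid(projections[g]) or not grid.same_grid(mess_per_gcm[g]):
            raise ValueError("projection and MESS rasters must share the grid")
    mess_vals = np.stack([mess_per_gcm[g].masked() for g in gcms])
    proj_vals = np.stack([projections[g].masked() for g in gcms])
    gmin = np.nanmin(mess_vals)
    gmax = np.nanmax(mess_vals)
    if gmax > gmin:
        s = (mess_vals - gmin) / (gmax - gmin) + eps
    else:
        s = np.ones_like(mess_vals)
    w = s / s.sum(axis=0, keepdims=True)
    out = (w * proj_vals).sum(axis=0)
    return grid.with_values(out, nodata=None)
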