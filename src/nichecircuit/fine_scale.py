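"""Fine-scale weighted-overlay suitability modelling.

Each fine-scale predictor (habitat class, distance to streams, distance
to water bodies, slope, aspect) is reclassified to a common [0, 1]
suitability scale from the ratio of its frequency distribution at
occurrence localities to its background distribution — a categorical
score table, or a fitted curve (exponential decay for distances,
Gaussian for slope; circular Gaussian for aspect).  The reclassified
layers and the climatic ensemble suitability are then fused by a
weighted arithmetic overlay.  Future projections swap only the climatic
layer, keeping transforms and weights fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit

from .evaluation import boyce_index
from .raster import Raster, RasterStack, extract_at_points

__all__ = [
    "SuitabilityTransform",
    "frequency_transform",
    "weighted_overlay",
    "project_fine_future",
    "validate_boyce",
    "FineScaleModel",
    "DEFAULT_WEIGHTS",
]

#: Default layer weights (ensemble-dominant, habitat-heavy); always
#: overridable in :class:`FineScaleModel` and :func:`weighted_overlay`.
DEFAULT_WEIGHTS: dict[str, float] = {
    "enm": 0.40,
    "habitat": 0.20,
    "dist_stream": 0.15,
    "dist_water": 0.15,
    "slope": 0.05,
    "aspect": 0.05,
}


def _exp_decay(d, a, scale):
    return a * np.exp(-d / scale)


def _gaussian(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


def _circular_gaussian(x, a, mu, sigma):
    delta = np.abs(x - mu) % 360.0
    delta = np.minimum(delta, 360.0 - delta)
    return a * np.exp(-(delta**2) / (2 * sigma**2))


_CURVES = {
    "exp_decay": _exp_decay,
    "gaussian": _gaussian,
    "circular_gaussian": _circular_gaussian,
}


@dataclass
class SuitabilityTransform:
    """Reclassification of one predictor to the common [0, 1] scale.

    ``kind`` is ``"categorical-frequency"`` (``mapping``: class ->
    score) or ``"continuous-curve"`` (``curve``: family name,
    ``params``: fitted coefficients, ``peak``: value used to rescale the
    curve maximum to 1).
    """

    predictor: str
    kind: str
    mapping: dict = field(default_factory=dict)
    curve: str | None = None
    params: tuple | None = None

    def transform(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.kind == "categorical-frequency":
            out = np.full(v.shape, np.nan)
            ok = np.isfinite(v)
            out[ok] = np.vectorize(lambda c: self.mapping.get(int(c), 0.0))(v[ok])
            return out
        fn = _CURVES[self.curve]
        out = fn(v, *self.params)
        return np.clip(out, 0.0, 1.0)

    def transform_raster(self, r: Raster) -> Raster:
        return r.with_values(self.transform(r.masked()), nodata=None)

    # -- YAML round-trip -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "kind": self.kind,
            "mapping": {int(k): float(s) for k, s in self.mapping.items()},
            "curve": self.curve,
            "params": list(map(float, self.params)) if self.params else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SuitabilityTransform":
        return cls(
            predictor=d["predictor"],
            kind=d["kind"],
            mapping={int(k): v for k, v in (d.get("mapping") or {}).items()},
            curve=d.get("curve"),
            params=tuple(d["params"]) if d.get("params") else None,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "SuitabilityTransform":
        return cls.from_dict(yaml.safe_load(text))


def frequency_transform(
    occ_values: np.ndarray,
    bg_values: np.ndarray,
    kind: str,
    predictor: str = "predictor",
    curve: str = "exp_decay",
    n_bins: int = 12,
) -> SuitabilityTransform:
    """Fit a suitability transform from occurrence vs background
    frequency distributions of one predictor.

    Categorical: score(class) = occurrence frequency / background
    frequency, rescaled so the best class scores 1; classes absent from
    the background score 0 (with a warning).  Continuous: the binned
    frequency ratio is fitted by least squares with the requested curve
    family and rescaled so the curve maximum over the background range
    is 1.
    """
    occ = np.asarray(occ_values, dtype=float)
    occ = occ[np.isfinite(occ)]
    bg = np.asarray(bg_values, dtype=float)
    bg = bg[np.isfinite(bg)]
    if occ.size < 30:
        raise ValueError("need at least 30 occurrence values")
    if kind == "categorical-frequency":
        occ_i = occ.astype(int)
        bg_i = bg.astype(int)
        bg_freq = pd.Series(bg_i).value_counts(normalize=True)
        occ_freq = pd.Series(occ_i).value_counts(normalize=True)
        scores = {}
        for cls, f_occ in occ_freq.items():
            if cls not in bg_freq:
                warnings.warn(
                    f"class {cls} absent from background; score set to 0",
                    stacklevel=2,
                )
                scores[int(cls)] = 0.0
            else:
                scores[int(cls)] = float(f_occ / bg_freq[cls])
        for cls in bg_freq.index:
            scores.setdefault(int(cls), 0.0)
        peak = max(scores.values())
        if peak > 0:
            scores = {c: s / peak for c, s in scores.items()}
        return SuitabilityTransform(
            predictor=predictor, kind=kind, mapping=scores
        )
    if kind != "continuous-curve":
        raise ValueError(f"unknown transform kind: {kind!r}")
    lo, hi = bg.min(), bg.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    bg_counts, _ = np.histogram(bg, bins=edges)
    occ_counts, _ = np.histogram(occ, bins=edges)
    keep = bg_counts > 0
    ratio = (occ_counts[keep] / occ.size) / (bg_counts[keep] / bg.size)
    x = mids[keep]
    fn = _CURVES[curve]
    p0 = _initial_guess(curve, x, ratio)
    try:
        params, _ = curve_fit(fn, x, ratio, p0=p0, maxfev=20_000)
    except RuntimeError:
        warnings.warn("curve fit failed to converge; using initial guess", stacklevel=2)
        params = np.asarray(p0)
    # rescale so the curve maximum over the background range is 1
    dense = np.linspace(lo, hi, 512)
    peak = float(np.max(fn(dense, *params)))
    params = tuple(params)
    if peak > 0:
        params = (params[0] / peak, *params[1:])
    return SuitabilityTransform(
        predictor=predictor, kind=kind, curve=curve, params=params
    )


def _initial_guess(curve: str, x: np.ndarray, ratio: np.ndarray):
    if curve == "exp_decay":
        return (max(ratio.max(), 1e-6), max((x.max() - x.min()) / 3.0, 1e-6))
    mu0 = float(x[np.argmax(ratio)])
    sigma0 = max((x.max() - x.min()) / 4.0, 1e-6)
    return (max(ratio.max(), 1e-6), mu0, sigma0)


def weighted_overlay(
    layers: Mapping[str, Raster],
    weights: Mapping[str, float],
) -> Raster:
    """Per-cell weighted arithmetic mean of [0, 1] layers.

    Weights must sum to 1 (tolerance 1e-9); nodata in any layer
    propagates to the output.
    """
    names = list(layers)
    w = np.array([weights[n] for n in names], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {w.sum()!r}, expected 1")
    grid = layers[names[0]]
    for n in names[1:]:
        if not grid.same_grid(layers[n]):
            raise ValueError(f"layer {n!r} is not co-registered")
    vals = np.stack([layers[n].masked() for n in names])
    out = np.tensordot(w, vals, axes=1)
    return grid.with_values(out, nodata=None)


def project_fine_future(
    transformed_fixed: Mapping[str, Raster],
    enm_future: Raster,
    weights: Mapping[str, float],
    enm_key: str = "enm",
) -> Raster:
    """Future fine-scale suitability: same transforms and weights, with
    only the climatic ensemble layer replaced."""
    layers = dict(transformed_fixed)
    layers[enm_key] = enm_future
    return weighted_overlay(layers, weights)


def validate_boyce(final_sdm: Raster, occurrences: pd.DataFrame, **kw) -> float:
    """Continuous Boyce index of a final suitability raster against
    held-out occurrence localities (raster cells as background)."""
    stack = RasterStack({"sdm": final_sdm})
    pred = extract_at_points(stack, occurrences)["sdm"].to_numpy()
    bg = final_sdm.masked()
    return boyce_index(pred[np.isfinite(pred)], bg[np.isfinite(bg)], **kw)


class FineScaleModel:
    """Fits per-predictor transforms and fuses them with the climatic
    ensemble layer by weighted overlay (fit / transform shaped).

    ``curve_families`` fixes the curve family per continuous predictor
    (reproducibility: no automatic family selection).
    """

    DEFAULT_KINDS = {
        "habitat": ("categorical-frequency", None),
        "dist_stream": ("continuous-curve", "exp_decay"),
        "dist_water": ("continuous-curve", "exp_decay"),
        "slope": ("continuous-curve", "gaussian"),
        "aspect": ("continuous-curve", "circular_gaussian"),
    }

    def __init__(
        self,
        weights: Mapping[str, float] | None = None,
        kinds: Mapping[str, tuple] | None = None,
        n_bins: int = 12,
    ):
        self.weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
        self.kinds = dict(self.DEFAULT_KINDS if kinds is None else kinds)
        self.n_bins = n_bins

    def fit(self, occurrences: pd.DataFrame, predictors: RasterStack):
        """Learn one transform per configured predictor present in the
        stack, from occurrence vs background frequency distributions."""
        names = [n for n in self.kinds if n in predictors.names]
        vals = extract_at_points(predictors.subset(names), occurrences)
        self.transforms_ = {}
        for n in names:
            kind, curve = self.kinds[n]
            bg = predictors[n].masked()
            self.transforms_[n] = frequency_transform(
                vals[n].to_numpy(),
                bg[np.isfinite(bg)],
                kind=kind,
                predictor=n,
                curve=curve or "exp_decay",
                n_bins=self.n_bins,
            )
        self.fixed_layers_ = {
            n: self.transforms_[n].transform_raster(predictors[n]) for n in names
        }
        return self

    def overlay(self, enm_suitability: Raster) -> Raster:
        """Final weighted suitability for a given climatic ensemble layer."""
        if not hasattr(self, "fixed_layers_"):
            raise ValueError("model is not fitted")
        active = {"enm", *self.fixed_layers_}
        w = {k: v for k, v in self.weights.items() if k in active}
        total = sum(w.values())
        w = {k: v / total for k, v in w.items()}  # renormalize to present layers
        layers = dict(self.fixed_layers_)
        layers["enm"] = enm_suitability
        return weighted_overlay(layers, w)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "weights": self.weights,
                "transforms": {n: t.to_dict() for n, t in self.transforms_.items()},
            }
        )
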