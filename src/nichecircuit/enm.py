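"""Ensemble climatic-niche modelling.

The workflow mirrors standard ensemble SDM practice for presence-only
data:

* a rectilinear surface range envelope (SRE) around the presences'
  climate values (quantiles ``q`` and ``1 - q`` per variable) defines
  "climatically unsuitable" space;
* pseudo-absences are drawn uniformly, without duplicate cells, from the
  region outside that envelope — several independent replicate sets;
* three learner families are fitted per replicate with case weights
  that equalize the total weight of presences and pseudo-absences:
  a quadratic logistic regression, stochastic gradient-boosted trees
  (5000 trees, depth 3, shrinkage 0.001, bag fraction 0.5, minimum 10
  observations per leaf) and a random forest (500 trees, 2 candidate
  predictors per split, minimum node size 5);
* spatially blocked 2-fold checkerboard cross-validation — block size
  above the spatial autocorrelation range estimated from residual
  correlograms of preliminary fits — yields Boyce and TSS per model;
* models with Boyce index > 0.7 and TSS > 0.5 enter a weighted-mean
  ensemble with weights proportional to their Boyce index.

:class:`EnsembleNicheModel` is a scikit-learn-style estimator that runs
the whole chain (``fit(occurrences, stack)`` / ``predict(stack)``);
the module-level functions expose the individual steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .evaluation import boyce_index, tss
from .raster import Raster, RasterStack, extract_at_points, thin_occurrences
from .spatial import checkerboard_folds, estimate_sar, morans_correlogram

__all__ = [
    "SREEnvelope",
    "PresencePseudoAbsenceDataset",
    "FittedModel",
    "EnsembleModel",
    "QuadraticLogisticSDM",
    "build_sre_envelope",
    "draw_pseudoabsences",
    "make_learner",
    "fit_learner",
    "build_ensemble",
    "variable_importance",
    "EnsembleNicheModel",
    "LEARNER_FAMILIES",
]

LEARNER_FAMILIES = ("quadratic-logistic", "boosted-trees", "random-forest")


# ------------------------------------------------------------ envelope

@dataclass(frozen=True)
class SREEnvelope:
    """Per-variable quantile box around presence climate values."""

    lower: dict[str, float]
    upper: dict[str, float]
    q: float

    def inside(self, df: pd.DataFrame) -> np.ndarray:
        """True where a row is within bounds for ALL variables."""
        ok = np.ones(len(df), dtype=bool)
        for v in self.lower:
            x = df[v].to_numpy(dtype=float)
            ok &= (x >= self.lower[v]) & (x <= self.upper[v])
        return ok


def build_sre_envelope(
    presence_values: pd.DataFrame,
    variables: Sequence[str] | None = None,
    q: float = 0.025,
) -> SREEnvelope:
    """Surface range envelope: quantiles q and 1-q (linear interpolation)
    of the presence-cell values of each climate variable."""
    if not 0 <= q < 0.5:
        raise ValueError("q must lie in [0, 0.5)")
    if variables is None:
        variables = [c for c in presence_values.columns if c not in ("x", "y", "missing")]
    if len(presence_values) < 20:
        raise ValueError("need at least 20 presences to estimate the envelope")
    lower, upper = {}, {}
    for v in variables:
        vals = presence_values[v].dropna().to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(f"too few presence values for variable {v!r}")
        lower[v] = float(np.quantile(vals, q))
        upper[v] = float(np.quantile(vals, 1 - q))
    return SREEnvelope(lower=lower, upper=upper, q=q)


# ------------------------------------------------------ pseudo-absences

@dataclass
class PresencePseudoAbsenceDataset:
    """Labelled points for one pseudo-absence replicate.

    ``points`` has columns x, y, label (1/0), weight, plus the predictor
    columns once attached; presence rows are identical across
    replicates; the summed weight of presences equals that of
    pseudo-absences.  ``fold`` is added by checkerboard assignment.
    """

    points: pd.DataFrame
    replicate_id: int

    @property
    def n_presences(self) -> int:
        return int((self.points["label"] == 1).sum())

    @property
    def n_pseudoabsences(self) -> int:
        return int((self.points["label"] == 0).sum())


def draw_pseudoabsences(
    env: SREEnvelope,
    stack: RasterStack,
    presences: pd.DataFrame,
    n: int = 1000,
    n_sets: int = 10,
    seed: int = 42,
) -> list[PresencePseudoAbsenceDataset]:
    """Replicate pseudo-absence sets drawn outside the SRE envelope.

    Each set holds ``n`` points at distinct cell centres, uniform over
    the cells outside the envelope (in at least one variable), appended
    to the presence rows (label 1).  Pseudo-absence case weight is
    ``n_presences / n`` so the classes carry equal total weight.
    """
    grid = stack.grid
    table = stack.table()
    valid = ~table[list(env.lower)].isna().any(axis=1).to_numpy()
    inside = env.inside(table)
    outside_idx = np.flatnonzero(valid & ~inside)
    if outside_idx.size < n:
        raise ValueError(
            f"only {outside_idx.size} cells outside the envelope; need {n}"
        )
    n_pres = len(presences)
    pres_rows = pd.DataFrame(
        {
            "x": presences["x"].to_numpy(dtype=float),
            "y": presences["y"].to_numpy(dtype=float),
            "label": 1,
            "weight": 1.0,
        }
    )
    ncols = grid.shape[1]
    rng = np.random.default_rng(seed)
    datasets = []
    for rep in range(1, n_sets + 1):
        cells = rng.choice(outside_idx, size=n, replace=False)
        x, y = grid.xy(cells // ncols, cells % ncols)
        pa_rows = pd.DataFrame(
            {"x": x, "y": y, "label": 0, "weight": n_pres / n}
        )
        pts = pd.concat([pres_rows, pa_rows], ignore_index=True)
        datasets.append(PresencePseudoAbsenceDataset(points=pts, replicate_id=rep))
    return datasets


# ------------------------------------------------------------ learners

class QuadraticLogisticSDM(BaseEstimator):
    """Additive quadratic logistic regression (GLM with linear + squared
    terms per predictor, binomial error, logit link).

    Features are standardized internally; a mild ridge penalty keeps the
    fit defined under complete separation.
    """

    def __init__(self, C: float = 100.0, max_iter: int = 2000):
        self.C = C
        self.max_iter = max_iter

    def _design(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean_) / self.scale_
        return np.hstack([Z, Z**2])

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        self.lr_ = LogisticRegression(C=self.C, max_iter=self.max_iter)
        self.lr_.fit(self._design(X), y, sample_weight=sample_weight)
        return self

    def predict_proba(self, X):
        return self.lr_.predict_proba(self._design(np.asarray(X, dtype=float)))

    def predict(self, X):
        return self.lr_.predict(self._design(np.asarray(X, dtype=float)))


def make_learner(family: str, seed: int = 42, **overrides):
    """Instantiate a learner of the given family with its default
    hyperparameters (overridable by keyword)."""
    if family == "quadratic-logistic":
        return QuadraticLogisticSDM(**overrides)
    if family == "boosted-trees":
        params = dict(
            n_estimators=5000,
            learning_rate=0.001,
            max_depth=3,  # three-way interactions
            min_samples_leaf=10,
            subsample=0.5,  # bag fraction
            random_state=seed,
        )
        params.update(overrides)
        return GradientBoostingClassifier(**params)
    if family == "random-forest":
        params = dict(
            n_estimators=500,
            max_features=2,
            min_samples_leaf=5,
            random_state=seed,
        )
        params.update(overrides)
        return RandomForestClassifier(**params)
    raise ValueError(f"unknown learner family: {family!r}")


@dataclass
class FittedModel:
    """One fitted learner with its spatial-CV evaluation."""

    family: str
    replicate_id: int
    train_fold: int
    estimator: object
    feature_names: list[str]
    boyce: float = np.nan
    tss: float = np.nan

    def predict_df(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.feature_names].to_numpy(dtype=float)
        return self.estimator.predict_proba(X)[:, 1]

    def predict_raster(self, stack: RasterStack) -> Raster:
        table = stack.table()[self.feature_names]
        ok = ~table.isna().any(axis=1).to_numpy()
        out = np.full(len(table), np.nan)
        if ok.any():
            out[ok] = self.estimator.predict_proba(
                table.to_numpy(dtype=float)[ok]
            )[:, 1]
        return stack.grid.with_values(out.reshape(stack.grid.shape), nodata=None)


def fit_learner(
    ds: PresencePseudoAbsenceDataset,
    family: str,
    feature_names: Sequence[str],
    seed: int = 42,
    train_mask: np.ndarray | None = None,
    **overrides,
) -> FittedModel:
    """Fit one learner on (a subset of) a presence/pseudo-absence dataset.

    Constant predictors are dropped with a warning; a single-class
    training subset raises.
    """
    pts = ds.points if train_mask is None else ds.points.loc[train_mask]
    y = pts["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    feats = list(feature_names)
    X = pts[feats].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [f for f, k in zip(feats, keep) if not k]
        warnings.warn(f"dropping constant predictors: {dropped}", stacklevel=2)
        feats = [f for f, k in zip(feats, keep) if k]
        X = X[:, keep]
    w = pts["weight"].to_numpy(dtype=float)
    est = make_learner(family, seed=seed, **overrides)
    est.fit(X, y, sample_weight=w)
    fold = -1
    if train_mask is not None and "fold" in ds.points:
        folds = ds.points.loc[train_mask, "fold"].unique()
        fold = int(folds[0]) if len(folds) == 1 else -1
    return FittedModel(
        family=family,
        replicate_id=ds.replicate_id,
        train_fold=fold,
        estimator=est,
        feature_names=feats,
    )


# ------------------------------------------------------------- ensemble

@dataclass
class EnsembleModel:
    """Boyce-weighted ensemble of selected fitted models."""

    members: list[FittedModel]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "weights", w)

    def predict_df(self, df: pd.DataFrame) -> np.ndarray:
        preds = np.stack([m.predict_df(df) for m in self.members])
        return self.weights @ preds

    def predict_raster(self, stack: RasterStack) -> Raster:
        preds = np.stack(
            [m.predict_raster(stack).values for m in self.members]
        )
        out = np.tensordot(self.weights, preds, axes=1)
        return stack.grid.with_values(out, nodata=None)


def build_ensemble(
    models: Sequence[FittedModel],
    boyce_min: float = 0.7,
    tss_min: float = 0.5,
) -> EnsembleModel:
    """Select models with Boyce > boyce_min and TSS > tss_min (strict)
    and weight them proportionally to their Boyce index."""
    passing = [m for m in models if m.boyce > boyce_min and m.tss > tss_min]
    if not passing:
        scores = [(m.family, m.replicate_id, m.boyce, m.tss) for m in models]
        raise ValueError(
            f"no model passes Boyce > {boyce_min} and TSS > {tss_min}; "
            f"scores (family, replicate, boyce, tss): {scores}"
        )
    b = np.array([m.boyce for m in passing], dtype=float)
    return EnsembleModel(members=passing, weights=b / b.sum())


def variable_importance(
    ens: EnsembleModel,
    stack: RasterStack,
    n_perm: int = 3,
    seed: int = 42,
) -> pd.Series:
    """Permutation importance of each predictor, as percentages.

    For each variable, its values are shuffled across valid cells and
    the drop in correlation with the original ensemble prediction,
    ``1 - cor(pred, pred_shuffled)``, is averaged over permutations;
    the raw importances are normalized to sum to 100.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    feats = sorted({f for m in ens.members for f in m.feature_names})
    table = stack.table()
    ok = ~table[feats].isna().any(axis=1).to_numpy()
    base = ens.predict_df(table.loc[ok])
    raw = {}
    for v in feats:
        drops = []
        for _ in range(n_perm):
            shuffled = table.loc[ok].copy()
            shuffled[v] = rng.permutation(shuffled[v].to_numpy())
            pred = ens.predict_df(shuffled)
            if np.std(base) == 0 or np.std(pred) == 0:
                drops.append(0.0)
            else:
                drops.append(1.0 - float(np.corrcoef(base, pred)[0, 1]))
        raw[v] = float(np.mean(drops))
    s = pd.Series(raw)
    total = s.sum()
    if total > 0:
        s = 100.0 * s / total
    return s


# ------------------------------------------------------- full pipeline

class EnsembleNicheModel(BaseEstimator):
    """End-to-end ensemble niche model as a scikit-learn-style estimator.

    ``fit`` takes an occurrence table (columns x, y[, species]) and a
    climate :class:`RasterStack`; ``predict`` returns the ensemble
    suitability raster for any co-registered stack (e.g. a future
    scenario).

    Parameters
    ----------
    families : tuple of str
        Learner families to fit per pseudo-absence replicate.
    n_pseudoabsences, n_sets : int
        Pseudo-absence points per replicate and number of replicates.
    sre_q : float
        SRE envelope quantile (bounds at q and 1-q).
    boyce_min, tss_min : float
        Strict selection thresholds for ensemble membership.
    block_size : float or None
        Checkerboard block side; None estimates the spatial
        autocorrelation range from preliminary-fit residuals and uses
        twice that value.
    sar_families : tuple of str
        Families used for the preliminary SAR fits.
    vif_threshold : float or None
        Apply iterative VIF screening to the climate stack first;
        None disables it.
    seed : int
        Seed for every stochastic step.
    """

    def __init__(
        self,
        families: tuple = LEARNER_FAMILIES,
        n_pseudoabsences: int = 1000,
        n_sets: int = 10,
        sre_q: float = 0.025,
        boyce_min: float = 0.7,
        tss_min: float = 0.5,
        block_size: float | None = None,
        sar_families: tuple = ("quadratic-logistic",),
        sar_tol: float = 0.05,
        vif_threshold: float | None = 10.0,
        learner_overrides: dict | None = None,
        seed: int = 42,
    ):
        self.families = families
        self.n_pseudoabsences = n_pseudoabsences
        self.n_sets = n_sets
        self.sre_q = sre_q
        self.boyce_min = boyce_min
        self.tss_min = tss_min
        self.block_size = block_size
        self.sar_families = sar_families
        self.sar_tol = sar_tol
        self.vif_threshold = vif_threshold
        self.learner_overrides = learner_overrides
        self.seed = seed

    # -- helpers ----------------------------------------------------
    def _overrides(self, family: str) -> dict:
        if not self.learner_overrides:
            return {}
        return dict(self.learner_overrides.get(family, {}))

    def _attach_predictors(self, ds: PresencePseudoAbsenceDataset, stack: RasterStack):
        vals = extract_at_points(stack, ds.points)
        for v in self.retained_vars_:
            ds.points[v] = vals[v]
        ds.points.dropna(subset=self.retained_vars_, inplace=True)
        ds.points.reset_index(drop=True, inplace=True)

    # -- estimator API ----------------------------------------------
    def fit(self, occurrences: pd.DataFrame, stack: RasterStack):
        from .raster import vif_screen

        grid = stack.grid
        pres = thin_occurrences(occurrences, grid)
        self.presences_ = pres

        if self.vif_threshold is not None and len(stack) >= 2:
            self.retained_vars_, self.vif_dropped_ = vif_screen(
                stack, threshold=self.vif_threshold, seed=self.seed
            )
        else:
            self.retained_vars_, self.vif_dropped_ = list(stack.names), []
        work = stack.subset(self.retained_vars_)

        pres_vals = extract_at_points(work, pres)
        self.envelope_ = build_sre_envelope(
            pres_vals, variables=self.retained_vars_, q=self.sre_q
        )
        self.datasets_ = draw_pseudoabsences(
            self.envelope_, work, pres,
            n=self.n_pseudoabsences, n_sets=self.n_sets, seed=self.seed,
        )
        for ds in self.datasets_:
            self._attach_predictors(ds, work)

        # ---- SAR from preliminary fits on the full datasets
        if self.block_size is None:
            xmin, ymin, xmax, ymax = grid.bounds
            diag = float(np.hypot(xmax - xmin, ymax - ymin))
            bin_width = diag / 40.0  # 20 bins to half the diagonal
            correlograms = []
            for ds in self.datasets_:
                for fam in self.sar_families:
                    m = fit_learner(
                        ds, fam, self.retained_vars_, seed=self.seed,
                        **self._overrides(fam),
                    )
                    pred = m.predict_df(ds.points)
                    resid = ds.points["label"].to_numpy(dtype=float) - pred
                    correlograms.append(
                        morans_correlogram(
                            ds.points[["x", "y"]].to_numpy(dtype=float),
                            resid, bin_width, diag / 2.0,
                        )
                    )
            self.sar_ = estimate_sar(correlograms, tol=self.sar_tol)
            self.block_size_ = 2.0 * self.sar_
        else:
            self.sar_ = None
            self.block_size_ = float(self.block_size)

        # ---- checkerboard folds, per-fold fitting and evaluation
        models: list[FittedModel] = []
        records = []
        for ds in self.datasets_:
            ds.points["fold"] = checkerboard_folds(ds.points, self.block_size_)
            for fam in self.families:
                for fold in (0, 1):
                    train = ds.points["fold"].to_numpy() == fold
                    test = ~train
                    m = fit_learner(
                        ds, fam, self.retained_vars_, seed=self.seed,
                        train_mask=train, **self._overrides(fam),
                    )
                    test_pts = ds.points.loc[test]
                    pred_test = m.predict_df(test_pts)
                    bg = m.predict_raster(work)
                    try:
                        m.boyce = boyce_index(
                            pred_test[test_pts["label"].to_numpy() == 1],
                            bg.masked()[np.isfinite(bg.masked())],
                        )
                    except ValueError:
                        m.boyce = np.nan
                    try:
                        m.tss = tss(pred_test, test_pts["label"].to_numpy())
                    except ValueError:
                        m.tss = np.nan
                    models.append(m)
                    records.append(
                        dict(
                            family=fam,
                            replicate=ds.replicate_id,
                            train_fold=fold,
                            boyce=m.boyce,
                            tss=m.tss,
                        )
                    )
        self.models_ = models
        self.evaluations_ = pd.DataFrame(records)
        self.ensemble_ = build_ensemble(
            models, boyce_min=self.boyce_min, tss_min=self.tss_min
        )
        self.stack_names_ = list(work.names)
        return self

    def predict(self, stack: RasterStack) -> Raster:
        """Ensemble suitability raster over a co-registered stack."""
        if not hasattr(self, "ensemble_"):
            raise ValueError("model is not fitted")
        work = stack.subset([n for n in self.stack_names_ if n in stack.names])
        return self.ensemble_.predict_raster(work)

    def variable_importance(self, stack: RasterStack, n_perm: int = 3) -> pd.Series:
        return variable_importance(
            self.ensemble_, stack.subset(self.stack_names_),
            n_perm=n_perm, seed=self.seed,
        )
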