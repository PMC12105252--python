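"""SRE envelope, pseudo-absence draws, learners, ensemble assembly and
variable importance."""

import numpy as np
import pandas as pd
import pytest

from nichecircuit import (
    RasterStack,
    build_ensemble,
    build_sre_envelope,
    draw_pseudoabsences,
    fit_learner,
    make_learner,
    variable_importance,
)
from nichecircuit.enm import FittedModel, PresencePseudoAbsenceDataset

from conftest import make_raster


class TestSREEnvelope:
    def _pres(self, values):
        return pd.DataFrame({"clim": values})

    def test_q_zero_is_min_max(self):
        vals = np.r_[3.0, 9.0, 1.0, 7.0] .repeat(6)
        env = build_sre_envelope(self._pres(vals), ["clim"], q=0.0)
        assert env.lower["clim"] == 1.0 and env.upper["clim"] == 9.0

    def test_degenerate_constant_values(self):
        env = build_sre_envelope(self._pres(np.full(25, 4.2)), ["clim"], q=0.025)
        assert env.lower["clim"] == env.upper["clim"] == 4.2

    def test_linear_interpolation_quantiles(self):
        env = build_sre_envelope(
            self._pres(np.arange(1.0, 101.0)), ["clim"], q=0.025
        )
        assert env.lower["clim"] == pytest.approx(3.475)
        assert env.upper["clim"] == pytest.approx(97.525)

    def test_too_few_presences(self):
        with pytest.raises(ValueError, match="20"):
            build_sre_envelope(self._pres(np.arange(5.0)), ["clim"])


class TestPseudoAbsences:
    def _setup(self, n_grid=60):
        rng = np.random.default_rng(0)
        grid_vals = rng.standard_normal((n_grid, n_grid))
        stack = RasterStack({"clim": make_raster(grid_vals)})
        # presences concentrated in the middle of the value range
        pres_vals = pd.DataFrame({"clim": rng.uniform(-0.5, 0.5, size=300)})
        env = build_sre_envelope(pres_vals, ["clim"], q=0.0)
        pres = pd.DataFrame(
            {"x": rng.uniform(0, 100, 300), "y": rng.uniform(0, 100, 300)}
        )
        return env, stack, pres

    def test_paper_defaults_ten_sets_of_1000(self):
        env, stack, pres = self._setup(100)
        sets = draw_pseudoabsences(env, stack, pres, n=1000, n_sets=10, seed=1)
        assert len(sets) == 10
        assert all(ds.n_pseudoabsences == 1000 for ds in sets)
        assert all(ds.n_presences == 300 for ds in sets)

    def test_weights_equalize_classes(self):
        env, stack, pres = self._setup()
        ds = draw_pseudoabsences(env, stack, pres, n=1000, n_sets=1, seed=1)[0]
        pts = ds.points
        w_pres = pts.loc[pts.label == 1, "weight"].sum()
        w_abs = pts.loc[pts.label == 0, "weight"].sum()
        assert w_abs == pytest.approx(w_pres)
        assert pts.loc[pts.label == 0, "weight"].iloc[0] == pytest.approx(0.3)

    def test_all_draws_outside_envelope(self):
        env, stack, pres = self._setup()
        ds = draw_pseudoabsences(env, stack, pres, n=500, n_sets=2, seed=2)[0]
        from nichecircuit import extract_at_points

        pa = ds.points[ds.points.label == 0]
        vals = extract_at_points(stack, pa)
        assert not env.inside(vals).any()

    def test_no_duplicate_cells_within_set(self):
        env, stack, pres = self._setup()
        ds = draw_pseudoabsences(env, stack, pres, n=800, n_sets=1, seed=3)[0]
        pa = ds.points[ds.points.label == 0]
        assert not pa.duplicated(["x", "y"]).any()

    def test_region_too_small_raises(self):
        env, stack, pres = self._setup(10)
        with pytest.raises(ValueError, match="outside the envelope"):
            draw_pseudoabsences(env, stack, pres, n=10_000, n_sets=1, seed=0)


def _toy_dataset(n=120, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    if informative:
        label = (x1 > 0).astype(int)
    else:
        label = rng.integers(0, 2, size=n)
    pts = pd.DataFrame(
        {
            "x": rng.uniform(0, 1000, n),
            "y": rng.uniform(0, 1000, n),
            "label": label,
            "weight": 1.0,
            "v1": x1,
            "v2": rng.standard_normal(n),
        }
    )
    return PresencePseudoAbsenceDataset(points=pts, replicate_id=1)


class TestLearners:
    def test_separable_logistic_confident(self):
        # two well-separated 1-D clusters: the regularized fit should be
        # near-certain at every presence
        rng = np.random.default_rng(4)
        n = 120
        label = rng.integers(0, 2, size=n)
        pts = pd.DataFrame(
            {
                "x": rng.uniform(0, 1000, n),
                "y": rng.uniform(0, 1000, n),
                "label": label,
                "weight": 1.0,
                "v1": label * 6.0 - 3.0 + 0.3 * rng.standard_normal(n),
            }
        )
        ds = PresencePseudoAbsenceDataset(points=pts, replicate_id=1)
        m = fit_learner(ds, "quadratic-logistic", ["v1"])
        pres = ds.points[ds.points.label == 1]
        assert np.all(m.predict_df(pres) >= 0.99)

    def test_duplicate_point_identical_prediction(self):
        ds = _toy_dataset()
        for fam in ("quadratic-logistic", "boosted-trees", "random-forest"):
            over = {"n_estimators": 50} if fam != "quadratic-logistic" else {}
            m = fit_learner(ds, fam, ["v1", "v2"], **over)
            row = ds.points.iloc[[0]]
            dup = pd.concat([row, row], ignore_index=True)
            p = m.predict_df(dup)
            assert p[0] == p[1]

    def test_single_class_raises(self):
        ds = _toy_dataset()
        ds.points["label"] = 1
        with pytest.raises(ValueError, match="single class"):
            fit_learner(ds, "quadratic-logistic", ["v1"])

    def test_constant_predictor_dropped_with_warning(self):
        ds = _toy_dataset()
        ds.points["v3"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            m = fit_learner(ds, "quadratic-logistic", ["v1", "v3"])
        assert m.feature_names == ["v1"]

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            make_learner("maxent")

    def test_uninformative_labels_boyce_near_zero(self):
        """Models fitted to labels independent of predictors should show
        no presence/suitability association (|B| small on average)."""
        from nichecircuit import boyce_index

        vals = []
        rng = np.random.default_rng(9)
        for seed in range(20):
            ds = _toy_dataset(n=300, seed=seed, informative=False)
            m = fit_learner(ds, "quadratic-logistic", ["v1", "v2"])
            bg = m.predict_df(ds.points)
            pres = ds.points[ds.points.label == 1]
            test = pres.sample(60, random_state=seed)
            try:
                vals.append(boyce_index(m.predict_df(test), bg))
            except ValueError:
                pass
        assert abs(np.mean(vals)) < 0.3


def _scored(family, rep, boyce, tss_):
    return FittedModel(
        family=family, replicate_id=rep, train_fold=0,
        estimator=None, feature_names=["v"], boyce=boyce, tss=tss_,
    )


class TestBuildEnsemble:
    def test_equal_boyce_equal_weights(self):
        ens = build_ensemble([_scored("a", 1, 0.8, 0.6), _scored("b", 1, 0.8, 0.6)])
        assert np.allclose(ens.weights, [0.5, 0.5])

    def test_single_member_weight_one(self):
        ens = build_ensemble([_scored("a", 1, 0.9, 0.6), _scored("b", 1, 0.2, 0.6)])
        assert len(ens.members) == 1 and ens.weights[0] == 1.0

    def test_boyce_proportional_weights(self):
        ens = build_ensemble([_scored("a", 1, 0.8, 0.6), _scored("b", 1, 0.9, 0.6)])
        assert np.allclose(ens.weights, [0.8 / 1.7, 0.9 / 1.7])
        assert ens.weights[0] == pytest.approx(0.4706, abs=1e-4)
        assert ens.weights[1] == pytest.approx(0.5294, abs=1e-4)

    def test_thresholds_are_strict(self):
        with pytest.raises(ValueError, match="no model passes"):
            build_ensemble([_scored("a", 1, 0.7, 0.6), _scored("b", 1, 0.9, 0.5)])

    def test_ensemble_prediction_bounded_by_members(self):
        rng = np.random.default_rng(1)
        ds = _toy_dataset(n=200, seed=1)
        models = []
        for fam, over in [
            ("quadratic-logistic", {}),
            ("random-forest", {"n_estimators": 50}),
        ]:
            m = fit_learner(ds, fam, ["v1", "v2"], **over)
            m.boyce, m.tss = 0.8, 0.6
            models.append(m)
        ens = build_ensemble(models)
        df = pd.DataFrame(
            {"v1": rng.standard_normal(100), "v2": rng.standard_normal(100)}
        )
        preds = np.stack([m.predict_df(df) for m in models])
        e = ens.predict_df(df)
        assert np.all(e >= preds.min(axis=0) - 1e-12)
        assert np.all(e <= preds.max(axis=0) + 1e-12)
        assert np.all((e >= 0) & (e <= 1))


class TestVariableImportance:
    def test_single_variable_model_gets_everything(self):
        ds = _toy_dataset(n=200, seed=2)
        m = fit_learner(ds, "quadratic-logistic", ["v1"])
        m.boyce, m.tss = 0.9, 0.7
        ens = build_ensemble([m])
        stack = RasterStack(
            {
                "v1": make_raster(np.random.default_rng(0).standard_normal((20, 20))),
                "v2": make_raster(np.random.default_rng(1).standard_normal((20, 20))),
            }
        )
        imp = variable_importance(ens, stack, n_perm=2, seed=0)
        assert imp["v1"] == pytest.approx(100.0)

    def test_uninformative_variable_near_zero(self):
        rng = np.random.default_rng(3)
        n = 400
        pts = pd.DataFrame(
            {
                "x": rng.uniform(0, 1000, n),
                "y": rng.uniform(0, 1000, n),
                "weight": 1.0,
                "v1": rng.standard_normal(n),
                "v2": rng.standard_normal(n),
            }
        )
        pts["label"] = (pts["v1"] > 0).astype(int)
        ds = PresencePseudoAbsenceDataset(points=pts, replicate_id=1)
        m = fit_learner(ds, "quadratic-logistic", ["v1", "v2"])
        m.boyce, m.tss = 0.9, 0.7
        ens = build_ensemble([m])
        stack = RasterStack(
            {
                "v1": make_raster(rng.standard_normal((30, 30))),
                "v2": make_raster(rng.standard_normal((30, 30))),
            }
        )
        imp = variable_importance(ens, stack, n_perm=3, seed=1)
        assert imp["v2"] < 2.0
        assert imp.sum() == pytest.approx(100.0)

    def test_nperm_validation(self):
        with pytest.raises(ValueError, match="n_perm"):
            variable_importance(None, None, n_perm=0)
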