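import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from mltiplet.classifier import (
    MultipletClassifier,
    TRIM_VARIABLES,
    build_training_set,
    estimate_doublet_proportion,
    fit_glm,
    predict_doublets,
    trim_2sd,
)


def _flags(index, flagged):
    return pd.Series([b in flagged for b in index], index=index)


class TestTrainingSet:
    INDEX = pd.Index(["b1", "b2", "b3", "b4"])

    def test_union_of_sources(self):
        calls = pd.DataFrame(
            {"vdj": _flags(self.INDEX, {"b1", "b2"}), "cite": _flags(self.INDEX, {"b2", "b3"})}
        )
        ts = build_training_set(calls)
        assert set(ts.positives) == {"b1", "b2", "b3"}
        assert set(ts.negatives) == {"b4"}
        assert ts.sources["b2"] == ["vdj", "cite"]

    def test_single_source(self):
        ts = build_training_set(pd.DataFrame({"vdj": _flags(self.INDEX, {"b4"})}))
        assert set(ts.positives) == {"b4"}

    def test_no_positives_errors(self):
        with pytest.raises(ValueError, match="no identified doublets"):
            build_training_set(pd.DataFrame({"vdj": _flags(self.INDEX, set())}))

    def test_all_flagged_errors(self):
        with pytest.raises(ValueError, match="no negatives"):
            build_training_set(pd.DataFrame({"vdj": _flags(self.INDEX, set(self.INDEX))}))


class TestTrimming:
    def test_mean_kept_and_3sd_removed(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {v: rng.normal(0, 1, 100) for v in TRIM_VARIABLES},
            index=[f"b{i}" for i in range(100)],
        )
        df.loc["b0"] = df.mean()  # at the group mean on every variable
        df.loc["b1", "clr_n_umi"] = df["clr_n_umi"].mean() + 3.5 * df["clr_n_umi"].std()
        kept = trim_2sd(df, df.index)
        assert "b0" in kept and "b1" not in kept

    def test_normal_retention_fraction(self):
        rng = np.random.default_rng(1)
        n = 100_000
        df = pd.DataFrame({v: rng.normal(0, 1, n) for v in TRIM_VARIABLES})
        kept = trim_2sd(df, df.index)
        # independent variables: P(all four within 2 SD) = 0.9545^4
        assert len(kept) / n == pytest.approx(0.9545**4, abs=0.01)

    def test_trimming_everything_errors(self):
        df = pd.DataFrame({v: [0.0, 100.0] for v in TRIM_VARIABLES})
        with pytest.raises(ValueError):
            trim_2sd(df, df.index, n_sd=0.0)


def _logistic_sim(n=10_000, seed=0, beta=(-2.0, 1.5, 0.0)):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {"z1": rng.normal(size=n), "z2": rng.normal(size=n)},
        index=[f"b{i}" for i in range(n)],
    )
    eta = beta[0] + beta[1] * X["z1"] + beta[2] * X["z2"]
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    return X, pd.Series(y, index=X.index)


class TestGlmFit:
    def test_parameter_recovery(self):
        X, y = _logistic_sim()
        model = MultipletClassifier(feature_names=["z1", "z2"]).fit(X, y)
        assert model.intercept_ == pytest.approx(-2.0, abs=0.15)
        assert model.coef_["z1"] == pytest.approx(1.5, abs=0.15)
        lo, hi = model.conf_int_.loc["z2"]
        assert lo < 0 < hi  # null covariate's CI covers 0

    def test_null_model_all_cis_cover_zero(self):
        X, y = _logistic_sim(n=5000, seed=3, beta=(-1.0, 0.0, 0.0))
        model = MultipletClassifier(feature_names=["z1", "z2"]).fit(X, y)
        for v in ("z1", "z2"):
            lo, hi = model.conf_int_.loc[v]
            assert lo < 0 < hi

    def test_duplicated_rows_leave_coefficients_unchanged(self):
        X, y = _logistic_sim(n=2000, seed=4)
        m1 = MultipletClassifier(feature_names=["z1", "z2"]).fit(X, y)
        X2 = pd.concat([X, X.set_axis(X.index + "_dup")])
        y2 = pd.concat([y, y.set_axis(y.index + "_dup")])
        m2 = MultipletClassifier(feature_names=["z1", "z2"]).fit(X2, y2)
        np.testing.assert_allclose(m1.coef_, m2.coef_, atol=1e-6)

    def test_perfect_separation_falls_back_to_ridge(self):
        X = pd.DataFrame({"z1": np.concatenate([np.full(50, -1.0), np.full(50, 1.0)])
                          + np.linspace(0, 0.01, 100)},
                         index=[f"b{i}" for i in range(100)])
        y = pd.Series([False] * 50 + [True] * 50, index=X.index)
        with pytest.warns(UserWarning, match="ridge"):
            model = MultipletClassifier(feature_names=["z1"]).fit(X, y)
        assert np.isfinite(model.coef_["z1"])
        assert (model.predict(X) == y).mean() > 0.95

    def test_collinear_column_dropped(self):
        X, y = _logistic_sim(n=2000, seed=5)
        X["z3"] = 2 * X["z1"]
        with pytest.warns(UserWarning, match="collinear"):
            model = MultipletClassifier(feature_names=["z1", "z2", "z3"]).fit(X, y)
        assert "z3" not in model.feature_names_


class TestPrediction:
    def _unit_model(self, coef, intercept=0.0, cutoff=0.5):
        m = MultipletClassifier(cutoff=cutoff)
        m.feature_names_ = list(coef)
        m.coef_ = pd.Series(coef)
        m.intercept_ = intercept
        return m

    def test_zero_linear_predictor_is_half_and_not_called(self):
        m = self._unit_model({"z1": 1.0})
        X = pd.DataFrame({"z1": [0.0]}, index=["b0"])
        assert m.predict_proba(X).iloc[0] == pytest.approx(0.5)
        assert not m.predict(X).iloc[0]  # strict '>' at the cutoff

    def test_zero_coefficients_constant_probability(self):
        m = self._unit_model({"z1": 0.0}, intercept=-1.0)
        X = pd.DataFrame({"z1": [0.0, 5.0, -3.0]})
        p = m.predict_proba(X)
        np.testing.assert_allclose(p, 1 / (1 + np.e), rtol=1e-12)

    def test_missing_feature_column_errors(self):
        m = self._unit_model({"z1": 1.0})
        with pytest.raises(KeyError, match="missing"):
            m.predict_proba(pd.DataFrame({"other": [1.0]}))

    def test_auroc_on_recovery_simulation(self):
        # strong, well-specified signal: the fitted probabilities must rank
        # the labels almost perfectly
        X, y = _logistic_sim(n=10_000, seed=6, beta=(-2.0, 3.0, 0.0))
        model = MultipletClassifier(feature_names=["z1", "z2"]).fit(X, y)
        assert roc_auc_score(y, model.predict_proba(X)) > 0.9

    def test_training_positives_always_called(self):
        X, y = _logistic_sim(n=500, seed=7)
        ts = build_training_set(pd.DataFrame({"src": y}))
        feats = X.copy()
        model = MultipletClassifier(feature_names=["z1", "z2"]).fit(X, y)
        pred = predict_doublets(model, feats, training=ts)
        assert pred.loc[ts.positives, "call"].all()

    def test_json_round_trip(self, tmp_path):
        X, y = _logistic_sim(n=2000, seed=8)
        model = MultipletClassifier(feature_names=["z1", "z2"], cutoff=0.4).fit(X, y)
        model.to_json(tmp_path / "m.json")
        back = MultipletClassifier.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(
            model.predict_proba(X), back.predict_proba(X), rtol=1e-12
        )
        assert back.cutoff == 0.4


class TestProportion:
    def test_counting(self):
        calls = np.zeros(1000, dtype=bool)
        calls[:50] = True
        assert estimate_doublet_proportion(calls) == 0.05
        assert estimate_doublet_proportion(np.zeros(10, dtype=bool)) == 0.0

    def test_monotone_in_cutoff(self):
        X, y = _logistic_sim(n=2000, seed=9)
        model = MultipletClassifier(feature_names=["z1", "z2"]).fit(X, y)
        props = [
            estimate_doublet_proportion(predict_doublets(model, X, cutoff=c)["call"])
            for c in (0.2, 0.5, 0.8)
        ]
        assert props[0] >= props[1] >= props[2]
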