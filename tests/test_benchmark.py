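import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyClassifier
from sklearn.linear_model import LogisticRegression

from phenoclass.benchmark import (ALGORITHM_NAMES, calibrate,
                                  default_algorithms, derive_seed,
                                  make_splits, run_benchmark, tune)
from phenoclass.labelling import ACTIVE, INACTIVE, LabelledDataset
from phenoclass.simulate import GeneratorConfig, gen_labelled_feature_data

from conftest import entries_from_pactivities


def balanced_dataset(n=400):
    entries = entries_from_pactivities(np.linspace(4, 8, n))
    labels = [INACTIVE] * (n // 2) + [ACTIVE] * (n - n // 2)
    return LabelledDataset(entries=entries, labels=labels, method="FIX",
                           parameter_pct=50.0)


class TestRegistry:
    def test_exactly_ten_algorithms(self):
        reg = default_algorithms()
        assert tuple(reg) == ALGORITHM_NAMES
        assert len(reg) == 10

    def test_grid_override(self):
        reg = default_algorithms({"KNN": {"n_neighbors": [3]}})
        assert reg["KNN"].grid == {"n_neighbors": [3]}
        with pytest.raises(KeyError):
            default_algorithms({"XGB": {}})

    def test_scaled_algorithms_wrap_in_pipeline(self):
        reg = default_algorithms()
        assert reg["SVM"].needs_scaling and reg["KNN"].needs_scaling
        assert not reg["RF"].needs_scaling
        assert "model__C" in reg["SVM"].grid_for_build()


class TestMakeSplits:
    def test_stratified_fold_sizes(self):
        plans = make_splits(balanced_dataset(400), seed=0)
        label_of = dict(zip(
            [e.compound_id for e in balanced_dataset(400).entries],
            balanced_dataset(400).labels))
        folds = plans[0].fold_assignment
        for f in range(1, 5):
            ids = [c for c, k in folds.items() if k == f]
            n_act = sum(1 for c in ids if label_of[c] == ACTIVE)
            assert len(ids) == 100
            assert abs(n_act - 50) <= 1

    def test_deterministic_given_seed(self):
        a = make_splits(balanced_dataset(), seed=7)
        b = make_splits(balanced_dataset(), seed=7)
        assert a[0].fold_assignment == b[0].fold_assignment
        assert [(p.validation_fold, p.test_fold) for p in a] == \
            [(p.validation_fold, p.test_fold) for p in b]

    def test_twelve_distinct_ordered_pairs(self):
        plans = make_splits(balanced_dataset(), seed=3)
        pairs = {(p.validation_fold, p.test_fold) for p in plans}
        assert len(plans) == 12 and len(pairs) == 12
        assert all(v != t for v, t in pairs)

    def test_roles_partition_dataset(self):
        plans = make_splits(balanced_dataset(120), seed=1)
        for p in plans:
            ids = p.train_ids + p.validation_ids + p.test_ids
            assert len(ids) == 120 and len(set(ids)) == 120
            # 50:25:25 within fold granularity
            assert len(p.train_ids) == 60

    def test_too_small_class_rejected(self):
        entries = entries_from_pactivities(np.linspace(4, 8, 10))
        ds = LabelledDataset(entries=entries,
                             labels=[ACTIVE] * 3 + [INACTIVE] * 7,
                             method="FIX", parameter_pct=30.0)
        with pytest.raises(ValueError):
            make_splits(ds, seed=0)


class TestTune:
    def _blobs(self, rng, n=120, sep=6.0):
        X = rng.normal(size=(n, 4))
        y = (rng.random(n) < 0.5).astype(int)
        X[:, 0] += sep * y
        return X, y

    def test_single_point_grid_equals_plain_fit(self, rng):
        X, y = self._blobs(rng)
        spec = default_algorithms({"RF": {"n_estimators": [30]}})["RF"]
        model, params = tune(spec, X, y, seed=0)
        assert params == {"n_estimators": 30}
        plain = spec.build(seed=0).set_params(n_estimators=30).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), plain.predict(X))

    def test_knn_separable_blobs_high_training_f1(self, rng):
        X, y = self._blobs(rng)
        spec = default_algorithms({"KNN": {"n_neighbors": [3, 5]}})["KNN"]
        model, _ = tune(spec, X, y, seed=0)
        from sklearn.metrics import f1_score
        assert f1_score(y, model.predict(X)) > 0.97

    def test_degenerate_grid_point_rejected_by_search(self, rng):
        # k = n-1 neighbours ~ majority vote (degenerate); k = 3 can separate
        X, y = self._blobs(rng, n=80)
        spec = default_algorithms(
            {"KNN": {"n_neighbors": [3, 63]}})["KNN"]
        _, params = tune(spec, X, y, seed=0)
        assert params["model__n_neighbors"] == 3


class TestCalibrate:
    def test_constant_score_model_gives_base_rate(self, rng):
        X = rng.normal(size=(200, 3))
        y = (rng.random(200) < 0.3).astype(int)
        model = DummyClassifier(strategy="prior").fit(X, y)
        X_val = rng.normal(size=(400, 3))
        y_val = (rng.random(400) < 0.7).astype(int)
        cal = calibrate(model, X_val, y_val)
        prob = cal.predict_proba(X_val)
        assert np.allclose(prob, prob[0])
        assert prob[0] == pytest.approx(y_val.mean(), abs=0.05)

    def test_monotone_map_preserves_ranking_and_auc(self, rng):
        from phenoclass.metrics import roc_auc
        X = rng.normal(size=(300, 2))
        y = ((X[:, 0] + rng.normal(scale=1.2, size=300)) > 0).astype(int)
        model = LogisticRegression().fit(X[:150], y[:150])
        cal = calibrate(model, X[150:], y[150:])
        raw = model.predict_proba(X[:150])[:, 1]
        mapped = cal.predict_proba(X[:150])
        labels = [ACTIVE if v else INACTIVE for v in y[:150]]
        assert roc_auc(mapped, labels) == pytest.approx(
            roc_auc(raw, labels), abs=1e-9)

    def test_already_calibrated_scores_near_identity(self, rng):
        # labels drawn Bernoulli(p) from the model's own probabilities:
        # the fitted sigmoid should be close to the identity on [0.2, 0.8]
        n = 4000
        X = rng.uniform(-3, 3, size=(n, 1))
        model = LogisticRegression().fit(X, (X[:, 0] > 0).astype(int))
        p = model.predict_proba(X)[:, 1]
        y = (rng.random(n) < p).astype(int)
        cal = calibrate(model, X, y)
        mapped = cal.predict_proba(X)
        sel = (p > 0.2) & (p < 0.8)
        assert np.abs(mapped[sel] - p[sel]).mean() < 0.05

    def test_single_class_validation_skips_calibration(self, rng):
        X = rng.normal(size=(50, 2))
        y = (X[:, 0] > 0).astype(int)
        model = LogisticRegression().fit(X, y)
        cal = calibrate(model, X[:5], np.ones(5, dtype=int))
        assert not cal.calibrated
        np.testing.assert_allclose(cal.predict_proba(X),
                                   model.predict_proba(X)[:, 1])


@pytest.fixture(scope="module")
def small_problem():
    cfg = GeneratorConfig(n_compounds=120, n_features=10,
                          signal_strength=3.0, seed=11)
    return gen_labelled_feature_data(cfg)


class TestRunBenchmark:
    def _algos(self):
        reg = default_algorithms({"NB": {}, "CART": {"max_depth": [4]}})
        return {"NB": reg["NB"], "CART": reg["CART"]}

    def test_row_accounting(self, small_problem):
        ds, fm = small_problem
        results, summary = run_benchmark({"d": ds}, {"f": fm},
                                         algorithms=self._algos(), seed=0)
        assert len(results) == 24          # 2 algorithms x 12 iterations
        assert len(summary) == 2
        assert set(results["iteration"]) == set(range(1, 13))

    def test_bit_reproducible_given_seed(self, small_problem):
        ds, fm = small_problem
        r1, _ = run_benchmark({"d": ds}, {"f": fm},
                              algorithms=self._algos(), seed=5)
        r2, _ = run_benchmark({"d": ds}, {"f": fm},
                              algorithms=self._algos(), seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_summary_matches_hand_aggregation(self, small_problem):
        ds, fm = small_problem
        results, summary = run_benchmark({"d": ds}, {"f": fm},
                                         algorithms=self._algos(), seed=0)
        grp = results[results["algorithm"] == "NB"]["test_mcc"].astype(float)
        row = summary[summary["algorithm"] == "NB"].iloc[0]
        assert row["test_mcc_mean"] == pytest.approx(grp.mean())
        assert row["test_mcc_sd"] == pytest.approx(grp.std(ddof=0))

    def test_signal_recovered(self, small_problem):
        ds, fm = small_problem
        _, summary = run_benchmark({"d": ds}, {"f": fm},
                                   algorithms=self._algos(), seed=0)
        assert (summary["test_mcc_mean"] > 0.7).all()


def test_derive_seed_stable_and_bounded():
    s1 = derive_seed(42, "fit", "a", 1)
    assert s1 == derive_seed(42, "fit", "a", 1)
    assert s1 != derive_seed(42, "fit", "a", 2)
    assert 0 <= s1 < 2**31
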