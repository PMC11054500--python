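import math

import numpy as np
import pandas as pd
import pytest

from walk6mwt.models import (
    USER_BASED_BINDINGS,
    load_reference_model,
    odds_ratios,
    rfe_select,
    screen_features,
    train_evaluate,
    vif_reduce,
)


class TestScreening:
    def test_feature_identical_to_label(self, rng):
        y = rng.integers(0, 2, 100)
        X = pd.DataFrame({"copy": y.astype(float), "noise": rng.normal(size=100)})
        res = screen_features(X, y)
        assert res.loc["copy", "r"] == pytest.approx(1.0)
        assert res.loc["copy", "ks"] == pytest.approx(1.0)

    def test_null_mostly_nonsignificant(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(200, 100)))
        X.columns = [f"f{i}" for i in range(100)]
        y = rng.integers(0, 2, 200)
        res = screen_features(X, y)
        assert (res["r_pvalue"] < 0.05).mean() < 0.15

    def test_shifted_class_detected(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 100)
        x = rng.normal(size=200) + 2.0 * y  # +2 sd shift
        res = screen_features(pd.DataFrame({"shifted": x}), y)
        assert res.loc["shifted", "r_pvalue"] < 0.05
        assert res.loc["shifted", "ks_pvalue"] < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            screen_features(pd.DataFrame({"a": [1.0, 2.0]}), [1, 1])


@pytest.fixture(scope="module")
def informative_problem():
    rng = np.random.default_rng(7)
    n = 200
    y = rng.integers(0, 2, n)
    X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"g{i}" for i in range(10)])
    X["g0"] = X["g0"] + 2.0 * y
    pids = [f"p{i % 20}" for i in range(n)]
    return X, y, pids


class TestRfeSelect:
    def test_informative_feature_recovered(self, informative_problem):
        X, y, pids = informative_problem
        sel = rfe_select(X, y, pids, seed=7)
        assert "g0" in sel.consensus

    def test_consensus_requires_three_of_five(self, informative_problem):
        X, y, pids = informative_problem
        sel = rfe_select(X, y, pids, seed=7)
        counts = {c: sum(c in s for s in sel.repetition_sets) for c in X.columns}
        for c in X.columns:
            assert (c in sel.consensus) == (counts[c] >= 3)

    def test_deterministic_per_seed(self, informative_problem):
        X, y, pids = informative_problem
        a = rfe_select(X, y, pids, seed=3)
        b = rfe_select(X, y, pids, seed=3)
        assert a.consensus == b.consensus
        assert a.repetition_sets == b.repetition_sets

    def test_too_few_participants_rejected(self, informative_problem):
        X, y, _ = informative_problem
        with pytest.raises(ValueError, match="participants"):
            rfe_select(X, y, ["p0", "p1"] * 100, seed=0)


class TestVifReduce:
    def test_orthogonal_features_untouched(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        reduced, res = vif_reduce(X)
        assert list(reduced.columns) == list("abcd")
        assert res.combinations == {}
        assert all(v <= 2.5 for v in res.final_vif.values())

    def test_duplicated_column_merged_once(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        X["d"] = X["a"]
        reduced, res = vif_reduce(X)
        assert len(res.combinations) == 1
        (name, members), = res.combinations.items()
        assert set(members) == {"a", "d"}
        assert all(v <= 2.5 for v in res.final_vif.values())

    def test_three_way_collinearity_resolved(self, rng):
        base = rng.normal(size=200)
        X = pd.DataFrame(
            {
                "x": base + 0.2 * rng.normal(size=200),
                "y": base + 0.2 * rng.normal(size=200),
                "z": base + 0.2 * rng.normal(size=200),
                "w": rng.normal(size=200),
            }
        )
        reduced, res = vif_reduce(X)
        assert len(res.combinations) <= 2
        if len(reduced.columns) >= 2:
            assert all(v <= 2.5 for v in res.final_vif.values())

    def test_constant_feature_named_in_error(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50), "flat": np.ones(50)})
        with pytest.raises(ValueError, match="flat"):
            vif_reduce(X)


class TestTrainEvaluate:
    def test_separable_data_perfect_metrics(self, rng):
        y = np.repeat([0, 1], 60)
        X = pd.DataFrame({"x": y * 10.0 + rng.normal(0, 0.1, 120)})
        rep = train_evaluate(X, y, seed=0)
        for m in rep.metrics.values():
            assert m.sensitivity == m.specificity == m.f1 == m.accuracy == 1.0
            assert m.auc == 1.0

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(300, 5)))
        X.columns = [f"f{i}" for i in range(5)]
        y = rng.integers(0, 2, 300)
        rep = train_evaluate(X, y, seed=2)
        assert abs(rep.metrics["LR"].auc - 0.5) < 0.1

    def test_reproducible_per_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        y = (X["a"] + rng.normal(0, 1, 80) > 0).astype(int)
        r1 = train_evaluate(X, y, seed=5)
        r2 = train_evaluate(X, y, seed=5)
        assert r1.metrics["RF"].auc == r2.metrics["RF"].auc
        assert r1.lr_coefficients == r2.lr_coefficients

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError):
            train_evaluate(X, np.ones(10, dtype=int), seed=0)


class TestOddsRatios:
    def test_zero_coefficient(self):
        assert odds_ratios({"a": 0.0}) == {"a": 1.0}

    def test_published_user_based_coefficients(self):
        ors = odds_ratios({"dh": 1.54, "curve": -2.65})
        assert ors["dh"] == pytest.approx(4.665, abs=0.001)
        assert ors["curve"] == pytest.approx(0.0707, abs=0.0001)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            odds_ratios({"a": float("nan")})


class TestReferenceModels:
    def test_user_based_probability_at_standardized_zero(self):
        model = load_reference_model("user_based")
        p = model.predict_from_inputs({"X1": 0, "X2": 0, "X3": 0, "X4": 0})
        assert p == pytest.approx(1 / (1 + math.exp(-0.90)), abs=1e-9)
        assert p == pytest.approx(0.7109, abs=1e-4)

    def test_error_based_probability_at_standardized_zero(self):
        model = load_reference_model("error_based")
        p = model.predict_from_inputs({f"X{i}": 0 for i in range(1, 6)})
        assert p == pytest.approx(1 / (1 + math.exp(0.22)), abs=1e-9)
        assert p == pytest.approx(0.4452, abs=1e-4)

    @pytest.mark.parametrize("which,coefs", [
        ("user_based", {"X1": 1.03, "X2": 0.81, "X3": -2.65, "X4": 1.54}),
        ("error_based", {"X1": 0.26, "X2": 0.52, "X3": 0.51, "X4": -0.18, "X5": 0.26}),
    ])
    def test_monotone_in_each_input_with_coefficient_sign(self, which, coefs):
        model = load_reference_model(which)
        zero = {x: 0.0 for x in coefs}
        p0 = model.predict_from_inputs(zero)
        for x, beta in coefs.items():
            bumped = dict(zero, **{x: 1.0})
            p1 = model.predict_from_inputs(bumped)
            assert (p1 > p0) == (beta > 0)

    def test_predict_standardizes_raw_features(self):
        model = load_reference_model("user_based")
        # at the packaged cohort means, every input standardizes to zero
        feats = {f: mu for f, (mu, _) in model.standardization.items()}
        assert model.predict(feats) == pytest.approx(0.7109, abs=1e-4)

    def test_missing_feature_named(self):
        model = load_reference_model("user_based")
        with pytest.raises(KeyError, match="quality_sampen"):
            model.predict({"heading_std": 1.0})

    def test_bindings_cover_published_features(self):
        assert USER_BASED_BINDINGS["X4"] == ["deltaheading_mean", "deltaheading_iqr"]
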