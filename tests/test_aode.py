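import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from appia import aode
from appia.aode import (
    MISSING,
    discretize,
    fit_aode,
    fit_discretizer,
    fit_nb,
    nb_predict,
    predict,
    predict_proba,
)

from aode_oracle import aode_oracle, nb_oracle


def _random_dataset(rng, n_rows=30, n_attrs=3, n_vals=3, missing_rate=0.25):
    X = rng.integers(0, n_vals, size=(n_rows, n_attrs))
    X[rng.random(X.shape) < missing_rate] = MISSING
    y = np.where(rng.random(n_rows) < 0.5, "positive", "negative").tolist()
    if len(set(y)) < 2:  # force both classes
        y[0], y[1] = "positive", "negative"
    return X, y


def _rows_as_dicts(X, attrs):
    return [
        {a: (None if v == MISSING else int(v)) for a, v in zip(attrs, row)}
        for row in X
    ]


def _instance_as_dict(x, attrs):
    return {a: (None if v == MISSING else int(v)) for a, v in zip(attrs, x)}


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

class TestFitDiscretizer:
    def test_500_values_ten_bands(self, rng):
        df = pd.DataFrame({"a": rng.random(500)})
        model = fit_discretizer(df)
        assert model.n_bands("a") == 10

    def test_120_values_two_bands(self, rng):
        df = pd.DataFrame({"a": rng.random(120)})
        assert fit_discretizer(df).n_bands("a") == 2

    def test_30_values_single_band(self, rng):
        df = pd.DataFrame({"a": rng.random(30)})
        assert fit_discretizer(df).n_bands("a") == 1

    def test_cut_points_strictly_increasing(self, rng):
        df = pd.DataFrame({"a": rng.integers(0, 4, size=400).astype(float)})
        cuts = fit_discretizer(df).cuts["a"]
        assert (np.diff(cuts) > 0).all()

    def test_band_floor_under_heavy_ties(self, rng):
        values = np.concatenate([np.full(100, 5.0), rng.random(20)])
        df = pd.DataFrame({"a": values})
        model = fit_discretizer(df)
        codes = discretize(df, model)
        counts = np.bincount(codes[:, 0], minlength=model.n_bands("a"))
        assert (counts >= 50).all()

    def test_entirely_missing_attribute(self, rng, caplog):
        df = pd.DataFrame({"a": rng.random(200), "b": [np.nan] * 200})
        with caplog.at_level("WARNING"):
            model = fit_discretizer(df)
        assert "b" in model.always_missing
        codes = discretize(df, model)
        assert (codes[:, 1] == MISSING).all()


class TestDiscretize:
    def _model(self):
        return aode.DiscretizationModel(cuts={"a": np.array([1.0, 2.0])})

    def test_below_all_cuts(self):
        assert discretize({"a": 0.5}, self._model())[0] == 0

    def test_value_on_cut_goes_right(self):
        assert discretize({"a": 1.0}, self._model())[0] == 1

    def test_missing_stays_missing(self):
        assert discretize({"a": None}, self._model())[0] == MISSING

    def test_out_of_range_clamps(self):
        assert discretize({"a": 99.0}, self._model())[0] == 2


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class TestFitAode:
    def test_complete_instances_populate_pair_tables(self, rng):
        X = rng.integers(0, 2, size=(82, 4))
        y = ["positive" if v else "negative" for v in rng.integers(0, 2, 82)]
        model = fit_aode(X, y, attributes=list("abcd"))
        assert model.pair.sum() == 82 * 4 * 3  # every ordered attr pair counted

    def test_single_class_rejected(self, rng):
        X = rng.integers(0, 2, size=(10, 2))
        with pytest.raises(ValueError):
            fit_aode(X, ["positive"] * 10, attributes=["a", "b"])

    def test_duplicates_double_counts(self, rng):
        X, y = _random_dataset(rng, n_rows=20)
        model_once = fit_aode(X, y, attributes=list("abc"), n_values=[3, 3, 3])
        model_twice = fit_aode(
            np.vstack([X, X]), y + y, attributes=list("abc"), n_values=[3, 3, 3]
        )
        np.testing.assert_array_equal(model_twice.joint, 2 * model_once.joint)
        np.testing.assert_array_equal(model_twice.pair, 2 * model_once.pair)

    def test_all_missing_instance_counts_only_class_prior(self):
        X = np.array([[0, 1], [MISSING, MISSING]])
        model = fit_aode(X, ["positive", "negative"], attributes=["a", "b"])
        assert model.class_counts.tolist() == [1, 1]
        assert model.joint.sum() == 2  # only the complete row's attributes
        assert model.n_known.tolist() == [1, 1]

    def test_row_order_irrelevant(self, rng):
        X, y = _random_dataset(rng, n_rows=40)
        order = rng.permutation(40)
        a = fit_aode(X, y, attributes=list("abc"), n_values=[3, 3, 3])
        b = fit_aode(
            X[order], [y[i] for i in order], attributes=list("abc"), n_values=[3, 3, 3]
        )
        np.testing.assert_array_equal(a.joint, b.joint)
        np.testing.assert_array_equal(a.pair, b.pair)


# ---------------------------------------------------------------------------
# prediction vs the brute-force oracle
# ---------------------------------------------------------------------------

class TestPredictProba:
    def test_tiny_dataset_matches_oracle(self, rng):
        X = np.array(
            [[0, 0], [0, 1], [1, 0], [1, 1], [0, 0], [1, 1], [0, 1], [1, 1]]
        )
        y = ["negative", "negative", "negative", "positive",
             "positive", "positive", "negative", "positive"]
        model = fit_aode(X, y, attributes=["a", "b"], n_values=[2, 2])
        attrs = ["a", "b"]
        rows = _rows_as_dicts(X, attrs)
        n_values = {"a": 2, "b": 2}
        for instance in ([0, 0], [0, 1], [1, 0], [1, 1], [MISSING, 1]):
            expected = aode_oracle(rows, y, n_values, _instance_as_dict(instance, attrs))
            got = predict_proba(model, np.array(instance))
            for k, cls in enumerate(model.classes):
                assert got[k] == pytest.approx(expected[cls], abs=1e-12)

    def test_single_known_attribute_equals_nb(self, rng):
        X, y = _random_dataset(rng, n_rows=40, n_attrs=3)
        model = fit_aode(X, y, attributes=list("abc"), n_values=[3, 3, 3])
        nb = fit_nb(X, y, attributes=list("abc"), n_values=[3, 3, 3])
        instance = np.array([1, MISSING, MISSING])
        np.testing.assert_allclose(
            predict_proba(model, instance), nb_predict(nb, instance), atol=1e-12
        )

    def test_probabilities_sum_to_one(self, rng):
        X, y = _random_dataset(rng, n_rows=50, n_attrs=4)
        model = fit_aode(X, y, attributes=list("abcd"), n_values=[3, 3, 3, 3])
        Xt, _ = _random_dataset(rng, n_rows=30, n_attrs=4)
        probs = predict_proba(model, Xt)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_never_errors_on_missing(self, rng):
        X, y = _random_dataset(rng, n_rows=40, n_attrs=4)
        model = fit_aode(X, y, attributes=list("abcd"), n_values=[3, 3, 3, 3])
        all_missing = np.full(4, MISSING)
        probs = predict_proba(model, all_missing)
        prior = (model.class_counts + 1) / (model.n_rows + 2)
        np.testing.assert_allclose(probs, prior / prior.sum(), atol=1e-12)

    def test_attribute_order_irrelevant(self, rng):
        X, y = _random_dataset(rng, n_rows=40, n_attrs=4)
        model = fit_aode(X, y, attributes=list("abcd"), n_values=[3, 3, 3, 3])
        order = [2, 0, 3, 1]
        permuted = fit_aode(
            X[:, order],
            y,
            attributes=[list("abcd")[i] for i in order],
            n_values=[3, 3, 3, 3],
        )
        Xt, _ = _random_dataset(rng, n_rows=20, n_attrs=4)
        np.testing.assert_allclose(
            predict_proba(model, Xt), predict_proba(permuted, Xt[:, order]), atol=1e-12
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=30)
    def test_oracle_equivalence_random_cases(self, seed):
        rng = np.random.default_rng(seed)
        n_attrs = int(rng.integers(1, 5))
        n_vals = int(rng.integers(2, 4))
        n_rows = int(rng.integers(4, 51))
        X, y = _random_dataset(rng, n_rows=n_rows, n_attrs=n_attrs, n_vals=n_vals)
        attrs = [f"a{i}" for i in range(n_attrs)]
        model = fit_aode(X, y, attributes=attrs, n_values=[n_vals] * n_attrs)
        rows = _rows_as_dicts(X, attrs)
        n_values = {a: n_vals for a in attrs}
        instance = X[int(rng.integers(n_rows))]
        expected = aode_oracle(rows, y, n_values, _instance_as_dict(instance, attrs))
        got = predict_proba(model, instance)
        for k, cls in enumerate(model.classes):
            assert got[k] == pytest.approx(expected[cls], abs=1e-12)


class TestNaiveBayes:
    def test_empty_known_returns_prior(self, rng):
        X, y = _random_dataset(rng, n_rows=30)
        nb = fit_nb(X, y, attributes=list("abc"), n_values=[3, 3, 3])
        probs = nb_predict(nb, np.full(3, MISSING))
        prior = (nb.class_counts + 1) / (nb.n_rows + 2)
        np.testing.assert_allclose(probs, prior / prior.sum(), atol=1e-12)

    def test_matches_oracle(self, rng):
        X, y = _random_dataset(rng, n_rows=40)
        attrs = list("abc")
        nb = fit_nb(X, y, attributes=attrs, n_values=[3, 3, 3])
        rows = _rows_as_dicts(X, attrs)
        instance = X[0]
        expected = nb_oracle(rows, y, {a: 3 for a in attrs}, _instance_as_dict(instance, attrs))
        got = nb_predict(nb, instance)
        for k, cls in enumerate(nb.classes):
            assert got[k] == pytest.approx(expected[cls], abs=1e-12)

    def test_agrees_with_aode_on_conditionally_independent_data(self):
        rng = np.random.default_rng(42)
        n = 4000
        y = np.where(rng.random(n) < 0.5, "positive", "negative")
        # attributes independent given the class
        p = {"positive": [0.8, 0.3, 0.6], "negative": [0.2, 0.7, 0.4]}
        X = np.column_stack(
            [
                (rng.random(n) < np.where(y == "positive", p["positive"][j], p["negative"][j]))
                .astype(np.int64)
                for j in range(3)
            ]
        )
        attrs = list("abc")
        model = fit_aode(X, list(y), attributes=attrs, n_values=[2, 2, 2])
        nb = fit_nb(X, list(y), attributes=attrs, n_values=[2, 2, 2])
        Xt = np.array([[i, j, k] for i in range(2) for j in range(2) for k in range(2)])
        diff = np.abs(predict_proba(model, Xt) - nb_predict(nb, Xt))
        assert diff.mean() < 0.02


class TestPredict:
    def _model(self, rng):
        X, y = _random_dataset(rng, n_rows=60, n_attrs=3)
        return fit_aode(X, y, attributes=list("abc"), n_values=[3, 3, 3])

    def test_threshold_semantics(self, rng):
        model = self._model(rng)
        Xt, _ = _random_dataset(rng, n_rows=40, n_attrs=3)
        labels, probs = predict(model, Xt, threshold=0.5)
        for label, p in zip(labels, probs):
            if p > 0.5:
                assert label == "positive"
            elif p < 0.5:
                assert label == "negative"

    def test_threshold_one_requires_certainty(self, rng):
        model = self._model(rng)
        Xt, _ = _random_dataset(rng, n_rows=40, n_attrs=3)
        labels, probs = predict(model, Xt, threshold=1.0)
        assert all(
            (label == "positive") == (p >= 1.0) for label, p in zip(labels, probs)
        )

    def test_exact_tie_is_negative(self, rng):
        model = self._model(rng)
        # engineer a tie via the prior on an all-missing instance of a
        # perfectly balanced training set
        X = np.array([[0], [1], [0], [1]])
        balanced = fit_aode(X, ["positive", "negative"] * 2, attributes=["a"], n_values=[2])
        label, p = predict(balanced, np.array([MISSING]), threshold=0.5)
        assert p == 0.5
        assert label == "negative"

    def test_labels_monotone_in_threshold(self, rng):
        model = self._model(rng)
        Xt, _ = _random_dataset(rng, n_rows=30, n_attrs=3)
        positives_at = []
        for threshold in (0.1, 0.3, 0.5, 0.7, 0.9):
            labels, _ = predict(model, Xt, threshold=threshold)
            positives_at.append(set(np.flatnonzero(labels == "positive")))
        for smaller, larger in zip(positives_at[1:], positives_at):
            assert smaller <= larger


class TestClassificationPower:
    def test_mcc_positive_on_planted_signal(self):
        from appia import evaluation

        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            n = 600
            y = np.where(rng.random(n) < 0.3, "positive", "negative")
            signal = np.where(y == "positive", 1.2, 0.0)
            raw = pd.DataFrame(
                {
                    "a": rng.normal(signal, 1.0),
                    "b": rng.normal(-signal, 1.0),
                    "c": rng.normal(0, 1.0, size=n),
                }
            )
            raw[rng.random((n, 3)) < 0.2] = np.nan
            disc = fit_discretizer(raw.iloc[:400], min_per_band=20)
            codes = discretize(raw, disc)
            model = fit_aode(
                codes[:400], list(y[:400]), attributes=list("abc"),
                n_values=[disc.n_bands(a) for a in "abc"],
            )
            labels, _ = predict(model, codes[400:])
            counts = evaluation.confusion_counts(
                labels == "positive", y[400:] == "positive"
            )
            assert evaluation.mcc(counts) > 0, f"seed {seed}"
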