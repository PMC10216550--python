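"""Importance measures, SHAP summaries, the bias statistic, embeddings."""

import numpy as np
import pytest

from conftest import make_informative_table
from ppsw.explain import (
    ShapSummary,
    embed,
    impurity_importance,
    permutation_importance,
    shap_bias,
    shap_summarize,
    silhouette,
)
from ppsw.ml import SplitSpec, feature_matrix, split, train_evaluate


@pytest.fixture(scope="module")
def forest_result():
    table = make_informative_table(n=300, n_features=8, seed=0)
    train, test = split(table, SplitSpec(seed=0))
    res = train_evaluate(train, test, "random_forest", "density", seed=0, n_estimators=100)
    return res, test


class TestImportances:
    def test_impurity_scores_normalized_and_signal_ranked(self, forest_result):
        res, _ = forest_result
        imp = impurity_importance(res)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        # only f0/f1 carry signal in the fixture
        assert set(imp.nlargest(2).index) == {"f0", "f1"}

    def test_noise_features_score_near_uniform(self):
        import pandas as pd

        r = np.random.default_rng(1)
        table = pd.DataFrame(r.random((500, 6)), columns=[f"f{i}" for i in range(6)])
        table["density_label"] = r.integers(0, 3, 500).astype(str)
        train, test = split(table, SplitSpec(seed=0))
        res = train_evaluate(train, test, "random_forest", "density", seed=0, n_estimators=100)
        imp = impurity_importance(res)
        assert imp.max() < 5 * (1.0 / 6)

    def test_permutation_drop_of_constant_column_is_zero(self, forest_result):
        res, test = forest_result
        test = test.copy()
        test["f7"] = 0.5  # constant on the evaluation set
        drops = permutation_importance(res, test, n_repeats=3, seed=0)
        assert drops["f7"] == 0.0

    def test_informative_feature_has_largest_drop(self, forest_result):
        res, test = forest_result
        drops = permutation_importance(res, test, n_repeats=5, seed=0)
        assert drops.idxmax() in ("f0", "f1")
        assert drops.max() > 0

    def test_permutation_deterministic_given_seed(self, forest_result):
        res, test = forest_result
        a = permutation_importance(res, test, n_repeats=3, seed=9)
        b = permutation_importance(res, test, n_repeats=3, seed=9)
        assert (a == b).all()

    def test_invalid_repeats_rejected(self, forest_result):
        res, test = forest_result
        with pytest.raises(ValueError):
            permutation_importance(res, test, n_repeats=0)


class TestShapSummary:
    def test_local_accuracy_on_every_sample_and_class(self, forest_result):
        res, test = forest_result
        summary = shap_summarize(res, test)
        x, _ = feature_matrix(test)
        proba = res.fitted_model.predict_proba(x)
        recon = summary.base_values[None, :] + summary.values.sum(axis=1)
        assert np.abs(recon - proba).max() <= 1e-6

    def test_uninformative_feature_attribution_small(self, forest_result):
        res, test = forest_result
        summary = shap_summarize(res, test)
        totals = summary.mean_abs.sum(axis=1)
        by_name = dict(zip(summary.feature_names, totals))
        top = max(totals)
        assert by_name["f5"] < 0.10 * top

    def test_sample_vector_reductions(self, forest_result):
        res, test = forest_result
        summary = shap_summarize(res, test)
        n, f, c = summary.values.shape
        assert summary.sample_vectors("concat").shape == (n, f * c)
        assert summary.sample_vectors("mean").shape == (n, f)
        with pytest.raises(ValueError):
            summary.sample_vectors("max")


class TestBias:
    @staticmethod
    def _summary(values, classes=("a", "b")):
        n, f, c = values.shape
        return ShapSummary(values=values, base_values=np.zeros(c),
                           feature_names=[f"f{i}" for i in range(f)],
                           class_names=list(classes))

    def test_self_bias_is_exactly_zero(self, rng):
        s = self._summary(rng.normal(size=(10, 4, 2)))
        bias = shap_bias(s, s)
        assert all(v == 0.0 for v in bias.per_class_bias.values())

    def test_antisymmetry(self, rng):
        a = self._summary(rng.normal(size=(10, 4, 2)))
        b = self._summary(rng.normal(size=(10, 6, 2)))  # feature sets may differ
        ab = shap_bias(a, b)
        ba = shap_bias(b, a)
        for c in ab.per_class_bias:
            assert ab.per_class_bias[c] == -ba.per_class_bias[c]

    def test_doubling_linearity(self, rng):
        vals = rng.normal(size=(12, 5, 3))
        base = self._summary(vals, classes=("x", "y", "z"))
        doubled = self._summary(2 * vals, classes=("x", "y", "z"))
        bias = shap_bias(doubled, base)
        expected = np.abs(vals).mean(axis=1).mean(axis=0)
        for k, c in enumerate(("x", "y", "z")):
            assert bias.per_class_bias[c] == pytest.approx(expected[k])

    def test_sample_mismatch_rejected(self, rng):
        a = self._summary(rng.normal(size=(10, 4, 2)))
        b = self._summary(rng.normal(size=(9, 4, 2)))
        with pytest.raises(ValueError, match="sample-count"):
            shap_bias(a, b)


class TestEmbedding:
    def test_shape_and_determinism(self, rng):
        x = rng.random((40, 6))
        labels = np.repeat(["a", "b"], 20)
        e1 = embed(x, labels, "raw_features", seed=3)
        e2 = embed(x, labels, "raw_features", seed=3)
        assert e1.coords.shape == (40, 2)
        np.testing.assert_array_equal(e1.coords, e2.coords)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            embed(rng.random((5, 3)), ["a"] * 5)

    def test_well_separated_classes_get_positive_silhouette(self, rng):
        x = np.vstack([rng.normal(0, 0.1, (20, 4)), rng.normal(5, 0.1, (20, 4))])
        labels = np.repeat(["a", "b"], 20)
        e = embed(x, labels, "raw_features", seed=0, n_neighbors=10)
        assert silhouette(e) > 0.5
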