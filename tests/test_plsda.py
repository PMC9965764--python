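import numpy as np
import pandas as pd
import pytest

from chemophen import plsda, preprocess as prep
from chemophen.simulate import SynthConfig, generate


def _toy_two_class(n_per=6, p=4, sep=20.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, p)) * 0.2
    X[:n_per, 0] += sep
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return pd.DataFrame(X, columns=[f"v{j}" for j in range(p)]), y


class TestFit:
    def test_separable_toy_one_component_perfect_training(self):
        # classes differ on a single coordinate; the rest are constant and
        # must receive zero weight without being dropped
        X = pd.DataFrame(
            {"v0": [0.0, 0.2, -0.1, 10.0, 10.2, 9.9],
             "v1": np.full(6, 3.0), "v2": np.zeros(6)}
        )
        y = np.array(["a"] * 3 + ["b"] * 3)
        model = plsda.fit_plsda(X, y, max_components=3, seed=0)
        assert model.n_components == 1
        assert (model.predict(X) == y).all()
        assert np.allclose(model.x_weights[1:], 0.0)

    def test_duplicated_columns_get_equal_importance(self):
        X, y = _toy_two_class()
        X["v0_copy"] = X["v0"]
        model = plsda.fit_plsda(X, y, seed=0)
        imp = plsda.variable_importance(model)
        assert np.allclose(imp.loc["v0"], imp.loc["v0_copy"], atol=1e-10)

    def test_deterministic_given_seed(self):
        X, y = _toy_two_class(seed=3)
        m1 = plsda.fit_plsda(X, y, seed=11)
        m2 = plsda.fit_plsda(X, y, seed=11)
        assert m1.n_components == m2.n_components
        assert np.array_equal(m1.x_weights, m2.x_weights)
        assert np.array_equal(m1.decision_scores(X), m2.decision_scores(X))

    def test_score_vectors_orthogonal(self, rng):
        X = pd.DataFrame(rng.normal(size=(16, 10)))
        y = np.array(["a", "b", "c", "d"] * 4)
        model = plsda.fit_plsda(X, y, max_components=4, seed=0)
        T = model.x_scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(G)).max()

    def test_singleton_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="single sample"):
            plsda.fit_plsda(X, y)


class TestVip:
    def test_single_component_closed_form(self):
        # two variables, only the first informative -> weights (1, 0),
        # VIP = (sqrt(2), 0)
        rng = np.random.default_rng(0)
        v0 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        X = pd.DataFrame({"v0": v0, "v1": np.ones(6)})
        y = np.array(["a"] * 3 + ["b"] * 3)
        X["v0"] = [0, 0.1, -0.1, 5, 5.1, 4.9]
        model = plsda.fit_plsda(X, y, max_components=1, seed=0)
        imp = plsda.variable_importance(model)
        assert np.allclose(imp.loc["v0"], np.sqrt(2), atol=1e-8)
        assert np.allclose(imp.loc["v1"], 0.0, atol=1e-8)

    def test_vip_normalization_identity(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 30)))
        y = np.array(["a", "b", "c"] * 4)
        model = plsda.fit_plsda(X, y, max_components=4, seed=2)
        imp = plsda.variable_importance(model)
        p = X.shape[1]
        for cls in imp.columns:
            assert (imp[cls] ** 2).sum() == pytest.approx(p, abs=1e-8 * p)


class TestSelectMarkers:
    def test_exactly_five_of_thousand_distinct(self, rng):
        imp = pd.DataFrame(
            {"a": rng.permutation(1000).astype(float),
             "b": rng.permutation(1000).astype(float)},
            index=[f"v{j}" for j in range(1000)],
        )
        sel = plsda.select_markers(imp, 0.995)
        for cls in ("a", "b"):
            assert len(sel.per_class[cls]) == 5

    def test_all_equal_importances_select_nothing(self):
        imp = pd.DataFrame({"a": np.ones(50)}, index=[f"v{j}" for j in range(50)])
        sel = plsda.select_markers(imp, 0.995)
        assert sel.selected == set()

    def test_selection_invariant_to_positive_scaling(self):
        X, y = _toy_two_class(seed=5)
        m1 = plsda.fit_plsda(X, y, seed=0)
        sel1 = plsda.select_markers(plsda.variable_importance(m1), 0.5)
        X2 = X.copy()
        X2["v1"] = X2["v1"] * 37.5
        m2 = plsda.fit_plsda(X2, y, seed=0)
        sel2 = plsda.select_markers(plsda.variable_importance(m2), 0.5)
        assert sel1.selected == sel2.selected


class TestEvaluate:
    def test_separable_data_perfect_metrics(self):
        X, y = _toy_two_class(n_per=6)
        model = plsda.fit_plsda(X, y, seed=0)
        ev = plsda.evaluate(model, X, y, k_folds=10, seed=0)
        assert ev.accuracy == 1.0
        assert ev.macro_auc == 1.0
        assert ev.macro_auc_pr == 1.0

    def test_permuted_labels_accuracy_near_chance(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(40, 12)))
        y = np.array(["a", "b"] * 20)
        y_perm = rng.permutation(y)
        model = plsda.fit_plsda(X, y_perm, max_components=2, seed=0)
        ev = plsda.evaluate(model, X, y_perm, k_folds=5, seed=0)
        se = np.sqrt(0.5 * 0.5 / 40)
        assert abs(ev.accuracy - 0.5) <= 3 * se + 1e-12

    def test_auc_equals_hand_mann_whitney(self):
        # single variable, hand-orderable scores
        X = pd.DataFrame({"v": [0.1, 0.4, 0.35, 0.8, 0.7, 0.9]})
        y = np.array(["neg", "neg", "pos", "pos", "neg", "pos"])
        model = plsda.fit_plsda(X, y, max_components=1, seed=0)
        ev = plsda.evaluate(model, X, y, k_folds=3, seed=0)
        # AUC from full-model scores instead of CV pooling for the rank check:
        from sklearn.metrics import roc_auc_score

        scores = model.decision_scores(X)[:, list(model.classes).index("pos")]
        pos = scores[y == "pos"]
        neg = scores[y == "neg"]
        hand = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert roc_auc_score((y == "pos").astype(int), scores) == pytest.approx(hand, abs=1e-12)
        assert 0.0 <= ev.macro_auc <= 1.0

    def test_r2_in_range_and_k_clamped(self):
        X, y = _toy_two_class(n_per=3)
        model = plsda.fit_plsda(X, y, seed=0)
        ev = plsda.evaluate(model, X, y, k_folds=10, seed=0)
        assert ev.k_folds == 6  # min(10, 3 * 2, 6)
        assert ev.r2 <= 1.0


class TestHeatmap:
    def test_columns_z_scored(self, rng):
        X = pd.DataFrame(rng.normal(2, 3, size=(9, 5)),
                         columns=[f"v{j}" for j in range(5)])
        y = np.array(["a", "b", "c"] * 3)
        hm = plsda.heatmap_matrix(X, ["v0", "v3"], y)
        assert np.allclose(hm.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(hm.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_constant_variable_excluded(self, rng):
        X = pd.DataFrame({"v0": rng.normal(size=6), "v1": np.full(6, 2.0)})
        y = np.array(["a", "b"] * 3)
        hm = plsda.heatmap_matrix(X, ["v0", "v1"], y)
        assert list(hm.columns) == ["v0"]

    def test_empty_selection_rejected_with_advice(self):
        X = pd.DataFrame(np.ones((4, 2)))
        with pytest.raises(ValueError, match="threshold"):
            plsda.heatmap_matrix(X, [], np.array(["a", "a", "b", "b"]))

    def test_planted_marker_overrepresented_in_its_taxon(self):
        bundle = generate(SynthConfig(seed=4, n_features=60, n_markers_per_taxon=3,
                                      brownian_sd=0.0, replicate_sd=0.2))
        table = prep.log_transform(bundle.feature_table)
        y = table.sample_meta["taxon"].to_numpy()
        taxon = "taxon_01"
        markers = sorted(bundle.planted_markers[taxon])
        hm = plsda.heatmap_matrix(table.abundance, markers, y)
        rows = [i for i, t in enumerate(sorted(y)) if t == taxon]
        assert hm.iloc[rows].mean().mean() > 0
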