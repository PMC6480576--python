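import numpy as np
import pandas as pd
import pytest

from _oracles import concordant_pair_auc
from datquant import (
    VARIABLE_GROUPS,
    StageClassifier,
    auc_score,
    cohen_kappa,
    confusion_matrix,
    evaluate,
    fit_logistic,
    fit_svm_rbf,
    run_model_grid,
    split_half,
)


def make_table(rng, n_per_stage=(20, 20, 20), separation=2.0):
    rows = []
    for k, stage in enumerate(("healthy", "mild", "severe")):
        for i in range(n_per_stage[k]):
            rows.append(
                {
                    "subject_id": f"{stage}-{i}",
                    "stage": stage,
                    "SK": rng.normal(separation * (2 - k), 1.0),
                    "KUR": rng.normal(separation * (2 - k), 1.0),
                    "DTAV": rng.normal(20 - separation * 3 * k, 2.0),
                }
            )
    return pd.DataFrame(rows)


class TestSplitHalf:
    def test_parity_sizes(self, rng):
        table = make_table(rng, (2, 2, 1))
        with pytest.warns(UserWarning, match="fewer than 2"):
            train, test = split_half(table, seed=0)
        assert (len(train), len(test)) == (3, 2)

    def test_even_split_and_determinism(self, rng):
        table = make_table(rng, (10, 10, 10))
        tr1, te1 = split_half(table, seed=5)
        tr2, te2 = split_half(table, seed=5)
        assert (len(tr1), len(te1)) == (15, 15)
        assert list(tr1.subject_id) == list(tr2.subject_id)
        assert set(tr1.subject_id).isdisjoint(te1.subject_id)

    def test_stratification_preserves_proportions(self, rng):
        table = make_table(rng, (6, 30, 24))
        train, _ = split_half(table, seed=1, stratified=True)
        counts = train.stage.value_counts()
        assert counts["healthy"] == 3 and counts["mild"] == 15 and counts["severe"] == 12


class TestCohenKappa:
    def test_closed_forms(self):
        assert cohen_kappa(np.diag([5, 7, 9])) == 1.0
        assert cohen_kappa(np.array([[25, 25], [25, 25]])) == 0.0
        # p_o = 0.7, p_e = 0.5
        assert cohen_kappa(np.array([[40, 10], [20, 30]])) == pytest.approx(0.4)

    def test_degenerate_single_cell(self):
        with pytest.warns(UserWarning, match="kappa"):
            assert cohen_kappa(np.array([[10, 0], [0, 0]])) == 0.0

    def test_permuted_labels_average_to_zero(self, rng):
        """Chance-level agreement: kappa averages ~0 over 1,000 label
        permutations of a fixed prediction vector."""
        y_pred = np.array(["healthy"] * 30 + ["mild"] * 40 + ["severe"] * 30)
        y_true = y_pred.copy()
        kappas = []
        for _ in range(1000):
            perm = rng.permutation(y_true)
            kappas.append(cohen_kappa(confusion_matrix(perm, y_pred)))
        assert abs(np.mean(kappas)) < 0.05
        assert max(kappas) <= 1.0


class TestAuc:
    def test_four_point_example(self):
        scores = np.array([[0.9, 0.1], [0.4, 0.6], [0.5, 0.5], [0.1, 0.9]])
        labels = np.array(["pos", "pos", "neg", "neg"])
        macro, per = auc_score(scores, labels, classes=["pos", "neg"])
        assert per["pos"] == pytest.approx(0.75)  # 3 of 4 concordant pairs

    def test_perfect_and_null_ranking(self, rng):
        labels = np.array(["a"] * 10 + ["b"] * 10)
        perfect = np.column_stack([np.r_[np.ones(10), np.zeros(10)], np.r_[np.zeros(10), np.ones(10)]])
        macro, _ = auc_score(perfect, labels, classes=["a", "b"])
        assert macro == 1.0
        noise = rng.random((2000, 2))
        labels = rng.choice(["a", "b"], 2000)
        macro, _ = auc_score(noise, labels, classes=["a", "b"])
        assert macro == pytest.approx(0.5, abs=0.05)

    def test_matches_concordant_pair_enumeration(self, rng):
        """Rank formulation equals brute-force pair counting, n <= 20."""
        for _ in range(50):
            n = int(rng.integers(4, 21))
            labels = np.array(["p"] * (n // 2) + ["n"] * (n - n // 2))
            scores = rng.integers(0, 5, size=(n, 2)).astype(float)
            _, per = auc_score(scores, labels, classes=["p", "n"])
            expected = concordant_pair_auc(
                scores[labels == "p", 0], scores[labels == "n", 0]
            )
            assert per["p"] == pytest.approx(expected, rel=1e-12)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            auc_score(np.ones((3, 2)), ["a", "a", "a"], classes=["a", "b"])


class _FixedModel:
    """Stub classifier returning precomputed predictions (metric tests)."""

    def __init__(self, y_pred, classes):
        self.y_pred = np.asarray(y_pred)
        self.classes_ = np.asarray(classes)

    def predict(self, X):
        return self.y_pred

    def predict_scores(self, X):
        return (self.y_pred[:, None] == self.classes_[None, :]).astype(float)


class TestEvaluate:
    def _table(self, y_true):
        n = len(y_true)
        return pd.DataFrame({"stage": y_true, "SK": np.zeros(n), "KUR": np.zeros(n), "DTAV": np.zeros(n)})

    def test_hand_computed_confusion_panel(self):
        # rows truth h/m/s: [[4,1,0],[2,6,2],[0,1,4]]
        y_true = ["healthy"] * 5 + ["mild"] * 10 + ["severe"] * 5
        y_pred = (
            ["healthy"] * 4 + ["mild"]
            + ["healthy"] * 2 + ["mild"] * 6 + ["severe"] * 2
            + ["mild"] + ["severe"] * 4
        )
        model = _FixedModel(y_pred, ["healthy", "mild", "severe"])
        rep = evaluate(model, self._table(y_true), ["SK", "KUR", "DTAV"])
        assert rep.confusion == [[4, 1, 0], [2, 6, 2], [0, 1, 4]]
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.kappa == pytest.approx(0.35 / 0.65)
        assert rep.sensitivity == pytest.approx(0.25 * 0.8 + 0.5 * 0.6 + 0.25 * 0.8)
        assert rep.specificity == pytest.approx(0.25 * (13 / 15) + 0.5 * 0.8 + 0.25 * (13 / 15))
        assert rep.ppv == pytest.approx(0.25 * (4 / 6) + 0.5 * 0.75 + 0.25 * (4 / 6))
        assert rep.npv == pytest.approx(0.25 * (13 / 14) + 0.5 * (8 / 12) + 0.25 * (13 / 14))
        assert rep.per_class["healthy"]["sensitivity"] == pytest.approx(0.8)

    def test_perfect_predictions(self):
        y = ["healthy"] * 3 + ["mild"] * 3 + ["severe"] * 3
        rep = evaluate(_FixedModel(y, ["healthy", "mild", "severe"]), self._table(y), ["SK"])
        for m in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "auc"):
            assert getattr(rep, m) == pytest.approx(1.0)
        assert rep.kappa == pytest.approx(1.0)

    def test_all_one_class_predictions_give_zero_kappa(self):
        y_true = ["healthy"] * 4 + ["mild"] * 4 + ["severe"] * 4
        rep = evaluate(
            _FixedModel(["mild"] * 12, ["healthy", "mild", "severe"]),
            self._table(y_true),
            ["SK"],
        )
        assert rep.kappa == pytest.approx(0.0)


class TestModels:
    def test_logistic_sign_tracks_separation(self):
        train = pd.DataFrame(
            {
                "stage": ["mild"] * 20 + ["severe"] * 20,
                "SK": np.r_[np.random.default_rng(0).normal(2, 0.5, 20),
                            np.random.default_rng(1).normal(-2, 0.5, 20)],
            }
        )
        clf = fit_logistic(train, ["SK"])
        order = list(clf.classes_)
        coef = clf.model_.coef_[0][0]
        # higher SK pushes toward 'severe' iff severe is the positive class
        assert (coef < 0) == (order.index("severe") == 1)

    def test_logistic_on_label_independent_features(self, rng):
        table = make_table(rng, (67, 67, 66), separation=0.0)
        train, test = split_half(table, seed=3)
        clf = fit_logistic(train, ["SK", "KUR", "DTAV"])
        assert np.abs(clf.model_.coef_).max() < 0.6
        rep = evaluate(clf, test, ["SK", "KUR", "DTAV"])
        majority = test.stage.value_counts(normalize=True).max()
        assert abs(rep.accuracy - majority) < 0.15

    def test_svm_separable_toy_has_zero_training_error(self, rng):
        table = make_table(rng, (15, 15, 15), separation=5.0)
        clf = fit_svm_rbf(table, ["SK", "DTAV"], C=10.0)
        pred = clf.predict(table[["SK", "DTAV"]].to_numpy())
        assert (pred == table.stage.to_numpy()).all()

    def test_svm_determinism(self, rng):
        table = make_table(rng, (12, 12, 12))
        train, test = split_half(table, seed=2)
        p1 = fit_svm_rbf(train, ["SK", "KUR"]).predict(test[["SK", "KUR"]].to_numpy())
        p2 = fit_svm_rbf(train, ["SK", "KUR"]).predict(test[["SK", "KUR"]].to_numpy())
        assert (p1 == p2).all()

    def test_single_class_training_is_an_error(self, rng):
        table = make_table(rng, (10, 0, 0))
        with pytest.raises(ValueError):
            fit_svm_rbf(table, ["SK"])

    def test_constant_feature_is_an_error(self, rng):
        table = make_table(rng, (5, 5, 5))
        table["SK"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(table, ["SK"])


class TestModelGrid:
    def test_grid_has_ten_deterministic_cells(self, rng):
        table = make_table(rng, (10, 10, 10))
        grid = run_model_grid(table, seed=4)
        assert len(grid) == 10
        assert {m for m, _ in grid} == {"lr", "svm"}
        assert {g for _, g in grid} == set(VARIABLE_GROUPS)
        again = run_model_grid(table, seed=4)
        for key in grid:
            assert grid[key].confusion == again[key].confusion

    def test_fadv_at_least_as_accurate_as_single_features(self, cohort_features):
        """On the well-separated phantom cohort the combined FADV group is
        at least as accurate as each single-feature model, and the SVM
        stays within 0.05 of the LR accuracy."""
        grid = run_model_grid(cohort_features, seed=0)
        for method in ("lr", "svm"):
            fadv = grid[(method, "FADV")].accuracy
            for single in ("SK", "KUR", "FAV"):
                assert fadv >= grid[(method, single)].accuracy
        assert grid[("svm", "FADV")].accuracy >= grid[("lr", "FADV")].accuracy - 0.05
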