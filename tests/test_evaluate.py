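"""Nested-CV evaluation: separability, null behaviour, optimal point,
stratification, leakage safety and determinism."""
import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

import eegfractal.evaluate as ev
from eegfractal import (
    ClassifierSpec,
    EvaluationCurve,
    default_classifiers,
    default_problems,
    nested_cv_accuracy,
    problem_from_name,
    relieff_rank,
    sequential_curve,
)


def separable_matrix(n_per_class=30, n_features=3, gap=10.0, seed=0):
    """Two classes whose feature means sit `gap` SDs apart."""
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal((n_per_class, n_features))
    x1 = rng.standard_normal((n_per_class, n_features)) + gap
    df = pd.DataFrame(
        np.vstack([x0, x1]), columns=[f"f{i}" for i in range(n_features)]
    )
    labels = np.array(["A"] * n_per_class + ["E"] * n_per_class)
    return df, labels


SMALL_SPECS = {
    "mlp": ClassifierSpec("mlp", ({"hidden": 5}, {"hidden": 10})),
    "svm_linear": ClassifierSpec("svm_linear", ({"C": 1.0},)),
    "svm_rbf": ClassifierSpec("svm_rbf", ({"C": 1.0, "gamma": 0.1},)),
}

AE = problem_from_name("A/E")


class TestProblems:
    def test_default_suite_has_five_problems(self):
        problems = default_problems()
        assert len(problems) == 5
        assert [p.name for p in problems] == [
            "ABCD/E", "AB/CD/E", "A/D/E", "A/E", "D/E",
        ]

    def test_grouping_parsed(self):
        p = problem_from_name("ABCD/E")
        assert p.label_map == {"A": 0, "B": 0, "C": 0, "D": 0, "E": 1}

    def test_three_class_grouping(self):
        p = problem_from_name("AB/CD/E")
        assert sorted(set(p.label_map.values())) == [0, 1, 2]

    def test_malformed_names_rejected(self):
        for bad in ("ABE", "A//E", "A/A"):
            with pytest.raises(ValueError):
                problem_from_name(bad)


class TestNestedCV:
    @pytest.mark.parametrize("kind", ["mlp", "svm_linear", "svm_rbf"])
    def test_fully_separated_classes_give_100(self, kind):
        df, labels = separable_matrix()
        acc = nested_cv_accuracy(df, labels, AE, SMALL_SPECS[kind], seed=0)
        assert acc == 100.0

    def test_permuted_labels_give_chance(self):
        """With labels shuffled, accuracy collapses to the 50% null."""
        df, labels = separable_matrix(n_per_class=100)
        accs = []
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(labels)
            accs.append(
                nested_cv_accuracy(df, perm, AE, SMALL_SPECS["svm_linear"], seed=seed)
            )
        assert np.mean(accs) == pytest.approx(50.0, abs=7.0)

    def test_mlp_is_single_hidden_layer_tanh(self):
        clf = SMALL_SPECS["mlp"].build({"hidden": 5}, seed=0)
        assert clf.activation == "tanh"
        assert clf.hidden_layer_sizes == (5,)

    def test_small_class_rejected(self):
        df, labels = separable_matrix(n_per_class=5)
        with pytest.raises(ValueError, match="10-fold"):
            nested_cv_accuracy(df, labels, AE, SMALL_SPECS["svm_linear"])

    def test_unknown_feature_rejected(self):
        df, labels = separable_matrix()
        with pytest.raises(ValueError, match="unknown"):
            nested_cv_accuracy(
                df, labels, AE, SMALL_SPECS["svm_linear"], feature_subset=["nope"]
            )

    def test_deterministic_for_seed(self):
        df, labels = separable_matrix(gap=0.5)
        a = nested_cv_accuracy(df, labels, AE, SMALL_SPECS["svm_rbf"], seed=3)
        b = nested_cv_accuracy(df, labels, AE, SMALL_SPECS["svm_rbf"], seed=3)
        assert a == b

    def test_stratified_folds_balanced(self):
        """Every fold's class proportions stay within one instance of global."""
        y = np.array([0] * 40 + [1] * 20)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        for _, te in skf.split(np.zeros((60, 1)), y):
            counts = np.bincount(y[te], minlength=2)
            assert abs(counts[0] - 4) <= 1 and abs(counts[1] - 2) <= 1


class TestSequentialCurve:
    def test_optimal_point_smallest_n_at_max(self):
        curve = EvaluationCurve("p", "c", [90.0, 95.0, 95.0, 94.0])
        assert curve.optimal_point == (2, 95.0)

    def test_curve_length_matches_feature_count(self):
        df, labels = separable_matrix(n_features=4, gap=3.0)
        curve = sequential_curve(
            df, labels, AE, SMALL_SPECS["svm_linear"], seed=0
        )
        assert len(curve.accuracies) == 4
        n_star, acc_star = curve.optimal_point
        assert acc_star == max(curve.accuracies)
        assert np.isfinite(curve.all_features_accuracy)

    def test_informative_first_feature_beats_noise_feature(self):
        """Ranking puts the separating feature first; accuracy at n=1 beats
        a single pure-noise feature."""
        rng = np.random.default_rng(2)
        df, labels = separable_matrix(n_features=1, gap=8.0, seed=2)
        df["noise"] = rng.standard_normal(len(df))
        curve = sequential_curve(df, labels, AE, SMALL_SPECS["svm_linear"], seed=0)
        noise_only = nested_cv_accuracy(
            df, labels, AE, SMALL_SPECS["svm_linear"], feature_subset=["noise"], seed=0
        )
        assert curve.accuracies[0] >= noise_only

    def test_foldwise_ranking_sees_only_training_rows(self, monkeypatch):
        """Leakage canary: in foldwise mode every ReliefF call receives
        exactly the outer-training rows, never the held-out fold."""
        df, labels = separable_matrix(n_per_class=20, gap=4.0)
        sizes = []
        real = ev.relieff_rank

        def spy(matrix, y, **kwargs):
            sizes.append(len(matrix))
            return real(matrix, y, **kwargs)

        monkeypatch.setattr(ev, "relieff_rank", spy)
        sequential_curve(
            df, labels, AE, SMALL_SPECS["svm_linear"], ranking_mode="foldwise", seed=0
        )
        assert len(sizes) == 10
        assert all(s == 36 for s in sizes)  # 90% of 40 instances

    def test_global_ranking_must_cover_features(self):
        df, labels = separable_matrix()
        other = relieff_rank(df[["f0", "f1"]], labels, k_neighbors=3)
        with pytest.raises(ValueError, match="cover"):
            sequential_curve(df, labels, AE, SMALL_SPECS["svm_linear"], ranking=other)


class TestDefaultGrids:
    def test_grid_shapes(self):
        mlp, lin, rbf = default_classifiers()
        assert len(mlp.grid) == 5 and len(lin.grid) == 5 and len(rbf.grid) == 25

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("forest", ({"n": 1},))
        with pytest.raises(ValueError):
            ClassifierSpec("mlp", ())
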