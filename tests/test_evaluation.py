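"""Grouped CV, weighted F1 (confusion-matrix oracle), importances."""

import numpy as np
import pandas as pd
import pytest

from imurehab.classifiers import ModelSpec, fit
from imurehab.evaluation import (
    LeakageError,
    cross_validate,
    cv_grouped_permutation_importance,
    gini_importance,
    group_importance,
    grouped_folds,
    grouped_permutation_importance,
    permutation_importance,
    weighted_f1,
)
from imurehab.featurizer import FeatureMatrix


def oracle_weighted_f1(y_true, y_pred):
    """Independent oracle built from an explicit confusion matrix."""
    classes = sorted(set(y_true))
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes) + 1))
    for t, p in zip(y_true, y_pred):
        cm[index[t], index.get(p, len(classes))] += 1
    total = 0.0
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        total += (tp + fn) / len(y_true) * f1
    return total


class TestGroupedFolds:
    def test_19_groups_in_6_folds_differ_by_at_most_one(self):
        groups = [f"P{i}" for i in range(19)]
        assignment = grouped_folds(groups, 6, seed=0)
        assert sorted(assignment.fold_sizes(), reverse=True) == [4, 3, 3, 3, 3, 3]

    def test_every_group_in_exactly_one_fold(self):
        groups = [f"P{i}" for i in range(13)] * 3
        assignment = grouped_folds(groups, 5, seed=2)
        assert set(assignment.group_to_fold) == set(groups)
        assert all(0 <= f < 5 for f in assignment.group_to_fold.values())

    def test_seeded_determinism(self):
        groups = [f"P{i}" for i in range(10)]
        assert grouped_folds(groups, 3, seed=4) == grouped_folds(groups, 3, seed=4)

    def test_fewer_groups_than_folds_rejected(self):
        with pytest.raises(ValueError):
            grouped_folds(["P1", "P2"], 3)


class TestWeightedF1:
    def test_perfect_predictions(self):
        assert weighted_f1(["a", "b", "a"], ["a", "b", "a"]) == 1.0

    def test_hand_computed_example(self):
        # F1_A = 2/3, F1_B = 4/5, equal support -> 0.7333...
        score = weighted_f1(list("AABB"), list("ABBB"))
        assert score == pytest.approx(11 / 15, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_f1([], [])

    def test_matches_confusion_matrix_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        labels = np.array(["a", "b", "c", "d"])
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            y_true = labels[rng.integers(0, 4, n)]
            y_pred = labels[rng.integers(0, 4, n)]
            assert weighted_f1(y_true, y_pred) == pytest.approx(
                oracle_weighted_f1(y_true, y_pred), abs=1e-12
            )


def _grouped_features(n_groups=8, per_group=12, n_features=6, informative=True,
                      seed=0):
    rng = np.random.default_rng(seed)
    rows, labels, groups = [], [], []
    for g in range(n_groups):
        for i in range(per_group):
            y = "a" if i % 2 == 0 else "b"
            x = rng.normal(size=n_features)
            if informative and y == "a":
                x[0] += 8.0
            rows.append(x)
            labels.append(y)
            groups.append(f"P{g}")
    meta = pd.DataFrame({
        "location": ["lower_back"] * n_features,
        "channel": ["accelerometer"] * n_features,
        "axis": ["x"] * n_features,
        "feature_name": [f"f{i}" for i in range(n_features)],
    })
    return FeatureMatrix(np.array(rows), meta, np.array(labels), np.array(groups))


class TestCrossValidate:
    def test_separable_data_scores_one_with_zero_spread(self):
        feats = _grouped_features()
        cv = cross_validate(ModelSpec("random_forest", seed=0), feats, k=4, seed=0)
        assert cv.mean == 1.0
        assert cv.sd == 0.0

    def test_confusion_total_equals_segment_count(self):
        feats = _grouped_features()
        cv = cross_validate(ModelSpec("decision_tree", seed=0), feats, k=4, seed=0)
        assert cv.confusion.to_numpy().sum() == feats.n_segments

    def test_shuffled_labels_score_near_chance(self):
        feats = _grouped_features(informative=False, n_groups=10, per_group=20)
        cv = cross_validate(ModelSpec("decision_tree", seed=0), feats, k=5, seed=0)
        assert abs(cv.mean - 0.5) < 0.1  # two balanced classes

    def test_leaked_fold_assignment_is_rejected(self):
        # deliberately split one participant's rows across folds
        feats = _grouped_features(n_groups=4)
        leaked = np.arange(feats.n_segments) % 2
        with pytest.raises(LeakageError):
            cross_validate(ModelSpec("decision_tree"), feats, folds=leaked)

    def test_mean_sd_recomputable_from_folds(self):
        feats = _grouped_features(seed=3)
        cv = cross_validate(ModelSpec("gaussian_nb"), feats, k=4, seed=1)
        assert cv.mean == pytest.approx(np.mean(cv.fold_scores))
        assert cv.sd == pytest.approx(np.std(cv.fold_scores))


class TestGiniImportance:
    def test_sums_to_one_and_tags_metadata(self):
        feats = _grouped_features()
        model = fit(ModelSpec("random_forest", seed=0), feats, feats.labels)
        table = gini_importance(model, feats.feature_meta)
        assert table.table["importance"].sum() == pytest.approx(1.0)
        assert table.table["importance"].iloc[0] == table.table["importance"].max()

    def test_single_feature_gets_full_importance(self):
        feats = _grouped_features(n_features=1)
        model = fit(ModelSpec("decision_tree", seed=0), feats, feats.labels)
        table = gini_importance(model, feats.feature_meta)
        assert table.table["importance"].iloc[0] == pytest.approx(1.0)

    def test_non_tree_family_rejected(self):
        feats = _grouped_features()
        model = fit(ModelSpec("knn"), feats, feats.labels)
        with pytest.raises(ValueError, match="tree-family"):
            gini_importance(model, feats.feature_meta)


class TestPermutationImportance:
    def test_constant_column_has_exactly_zero_importance(self):
        feats = _grouped_features()
        matrix = feats.matrix.copy()
        matrix[:, 3] = 5.0
        feats = FeatureMatrix(matrix, feats.feature_meta, feats.labels, feats.groups)
        model = fit(ModelSpec("random_forest", seed=0), feats, feats.labels)
        table = permutation_importance(model, feats, feats.labels, n_repeats=3, seed=0)
        assert table.table["importance"].iloc[3] == 0.0

    def test_planted_column_is_most_important(self):
        train = _grouped_features(seed=1)
        val = _grouped_features(seed=2)
        model = fit(ModelSpec("random_forest", seed=0), train, train.labels)
        table = permutation_importance(model, val, val.labels, n_repeats=5, seed=0)
        assert table.table["importance"].idxmax() == 0

    def test_seeded_determinism(self):
        feats = _grouped_features()
        model = fit(ModelSpec("random_forest", seed=0), feats, feats.labels)
        a = permutation_importance(model, feats, feats.labels, n_repeats=4, seed=9)
        b = permutation_importance(model, feats, feats.labels, n_repeats=4, seed=9)
        assert a.table.equals(b.table)

    def test_noise_columns_center_on_zero(self):
        train = _grouped_features(seed=4, n_features=8)
        val = _grouped_features(seed=5, n_features=8)
        model = fit(ModelSpec("random_forest", seed=0), train, train.labels)
        table = permutation_importance(model, val, val.labels, n_repeats=10, seed=0)
        noise = table.table["importance"].iloc[1:]  # column 0 is the signal
        assert noise.abs().mean() < 0.02

    def test_repeat_count_validated(self):
        feats = _grouped_features()
        model = fit(ModelSpec("random_forest", seed=0), feats, feats.labels)
        with pytest.raises(ValueError):
            permutation_importance(model, feats, feats.labels, n_repeats=0)


def _planted_grid_features(seed=0):
    """Only the lower-back accelerometer columns carry class signal."""
    rng = np.random.default_rng(seed)
    cells = [("lower_back", "accelerometer"), ("lower_back", "gyroscope"),
             ("wrist", "accelerometer"), ("wrist", "pressure")]
    n = 160
    labels = np.array(["a", "b"] * (n // 2))
    groups = np.array([f"P{i % 8}" for i in range(n)])
    blocks, meta_rows = [], []
    for loc, ch in cells:
        block = rng.normal(size=(n, 3))
        if (loc, ch) == ("lower_back", "accelerometer"):
            block[labels == "a"] += 4.0
        blocks.append(block)
        meta_rows += [(loc, ch, ax, f"f{ax}") for ax in "xyz"]
    meta = pd.DataFrame(meta_rows, columns=["location", "channel", "axis",
                                            "feature_name"])
    return FeatureMatrix(np.hstack(blocks), meta, labels, groups)


class TestGroupImportance:
    def test_grid_sums_conserve_total(self):
        feats = _planted_grid_features()
        model = fit(ModelSpec("random_forest", seed=0), feats, feats.labels)
        table = gini_importance(model, feats.feature_meta)
        grid = group_importance(table)
        assert grid.to_numpy().sum() == pytest.approx(
            table.table["importance"].sum()
        )

    def test_single_location_table_fills_one_row(self):
        feats = _grouped_features()
        model = fit(ModelSpec("random_forest", seed=0), feats, feats.labels)
        grid = group_importance(gini_importance(model, feats.feature_meta))
        assert list(grid.index) == ["lower_back"]

    def test_planted_lower_back_accelerometer_cell_wins(self):
        feats = _planted_grid_features()
        table = cv_grouped_permutation_importance(
            ModelSpec("random_forest", seed=0), feats, k=4, seed=0, n_repeats=3
        )
        grid = group_importance(table)
        assert grid.stack().idxmax() == ("lower_back", "accelerometer")

    def test_missing_metadata_rejected(self):
        from imurehab.evaluation import ImportanceTable
        bare = ImportanceTable(
            table=pd.DataFrame({"location": ["", ""], "channel": ["", ""],
                                "importance": [0.1, 0.2]}),
            method="gini",
        )
        with pytest.raises(ValueError):
            group_importance(bare)


class TestStandardizationModes:
    def test_global_mode_is_available_for_fidelity_checks(self):
        feats = _grouped_features()
        per_fold = cross_validate(ModelSpec("decision_tree", seed=0), feats,
                                  k=4, seed=0)
        global_ = cross_validate(ModelSpec("decision_tree", seed=0), feats,
                                 k=4, seed=0, standardize="global")
        assert len(global_.fold_scores) == len(per_fold.fold_scores)
        with pytest.raises(ValueError):
            cross_validate(ModelSpec("decision_tree"), feats, standardize="robust")


class TestHeatmapExport:
    def test_writes_an_image(self, tmp_path):
        from imurehab.evaluation import export_heatmap

        feats = _planted_grid_features()
        model = fit(ModelSpec("random_forest", seed=0), feats, feats.labels)
        grid = group_importance(gini_importance(model, feats.feature_meta))
        out = tmp_path / "grid.png"
        export_heatmap(grid, out)
        assert out.stat().st_size > 0
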