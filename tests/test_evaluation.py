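"""Nested-CV protocol shape, metric arithmetic, and model behaviour on
constructed feature matrices."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_synthetic_matrix
from facetouch.errors import DesignError, UnsupportedFamilyError
from facetouch.evaluation import (BINARY, MULTICLASS, ModelSpec,
                                  binary_metrics, default_model_spec,
                                  forest_importances, grid_search_inner,
                                  make_nested_plan, multiclass_metrics,
                                  pooled_confusion, run_nested_cv,
                                  window_sweep)
from facetouch.features import FEATURE_NAMES
from facetouch.labels import FT, NFT

PIDS = [f"P{i:02d}" for i in range(1, 11)]


class TestNestedPlan:
    def test_shape_and_partition(self):
        plan = make_nested_plan(PIDS, seed=0)
        assert len(plan.outer_folds) == 10
        assert sorted(f.test_participant for f in plan.outer_folds) == PIDS
        for fold in plan.outer_folds:
            groups = fold.inner_groups
            assert len(groups) == 3 and all(len(g) == 3 for g in groups)
            flat = [p for g in groups for p in g]
            assert sorted(flat) == sorted(set(PIDS) - {fold.test_participant})
            assert fold.test_participant not in flat

    def test_inner_iteration_trains_on_six(self):
        plan = make_nested_plan(PIDS, seed=1)
        for fold in plan.outer_folds:
            for held_out in range(3):
                train = [p for g, grp in enumerate(fold.inner_groups)
                         for p in grp if g != held_out]
                assert len(train) == 6
                assert len(fold.inner_groups[held_out]) == 3

    def test_deterministic(self):
        assert make_nested_plan(PIDS, 5) == make_nested_plan(PIDS, 5)

    @pytest.mark.parametrize("n", [3, 4, 11])
    def test_bad_designs(self, n):
        with pytest.raises(DesignError):
            make_nested_plan([f"P{i}" for i in range(n)], 0)


class TestBinaryMetrics:
    def test_arithmetic(self):
        """TP=8 FP=2 FN=1 TN=9."""
        y_true = np.array([FT] * 9 + [NFT] * 11)
        y_pred = np.array([FT] * 8 + [NFT] + [FT] * 2 + [NFT] * 9)
        m = binary_metrics(y_true, y_pred)
        assert m["precision"] == pytest.approx(0.800)
        assert m["recall"] == pytest.approx(8 / 9)
        assert m["f1"] == pytest.approx(2 * 0.8 * (8 / 9) / (0.8 + 8 / 9))
        assert m["accuracy"] == pytest.approx(0.85)

    def test_perfect(self):
        y = np.array([FT, FT, NFT, NFT])
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        m = binary_metrics(y, y, scores)
        assert all(m[k] == 1.0 for k in
                   ("accuracy", "recall", "precision", "f1", "auc"))

    def test_no_positives_flagged(self):
        y = np.array([NFT, NFT])
        m = binary_metrics(y, y)
        assert m["recall"] is None and m["f1"] is None

    def test_single_class_auc_undefined(self):
        y = np.array([FT, FT])
        m = binary_metrics(y, y, np.array([0.5, 0.6]))
        assert m["auc"] is None


class TestMulticlassMetrics:
    def test_all_correct(self):
        y = np.array([f"A{i}" for i in range(10)] * 3)
        m = multiclass_metrics(y, y)
        assert all(v == 1.0 for v in m.values())

    def test_macro_recall_toy(self):
        """A: 3 correct, 1→B; B: 4 correct → macro recall (0.75+1)/2."""
        y_true = np.array(["A"] * 4 + ["B"] * 4)
        y_pred = np.array(["A"] * 3 + ["B"] + ["B"] * 4)
        m = multiclass_metrics(y_true, y_pred)
        assert m["recall"] == pytest.approx(0.875)

    def test_uniform_random_near_chance(self):
        rng = np.random.default_rng(0)
        classes = np.array([f"A{i}" for i in range(10)])
        y_true = np.repeat(classes, 500)
        y_pred = rng.choice(classes, size=len(y_true))
        m = multiclass_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(0.1, abs=0.02)


class TestPooledConfusion:
    def test_perfect_diagonal_and_row_sums(self, synthetic_matrix):
        class _F:
            def __init__(self, y):
                self.y_true = y
                self.y_pred = y
        y = synthetic_matrix["activity"].to_numpy()
        cm = pooled_confusion([_F(y)])
        np.testing.assert_allclose(np.diag(cm.to_numpy()), 100.0)
        np.testing.assert_allclose(cm.sum(axis=1), 100.0, atol=1e-6)


FAST_LR = ModelSpec("logistic_regression", ({"C": 1.0},))


class TestGridSearch:
    def test_single_point_grid(self, synthetic_matrix):
        plan = make_nested_plan(PIDS, 0)
        fold = plan.outer_folds[0]
        sub = synthetic_matrix[
            synthetic_matrix.participant_id != fold.test_participant]
        assert grid_search_inner(sub, fold, FAST_LR, BINARY) == {"C": 1.0}

    def test_separating_point_selected(self, synthetic_matrix):
        """An all-but-unregularized LR separates the constructed data; a
        C ≈ 0 one cannot — the separating grid point must win."""
        spec = ModelSpec("logistic_regression", ({"C": 1e-10}, {"C": 10.0}))
        plan = make_nested_plan(PIDS, 0)
        fold = plan.outer_folds[0]
        sub = synthetic_matrix[
            synthetic_matrix.participant_id != fold.test_participant]
        assert grid_search_inner(sub, fold, spec, BINARY) == {"C": 10.0}

    def test_tie_breaks_to_first(self, synthetic_matrix):
        spec = ModelSpec("logistic_regression", ({"C": 1.0}, {"C": 1.0 + 0}))
        plan = make_nested_plan(PIDS, 0)
        fold = plan.outer_folds[0]
        sub = synthetic_matrix[
            synthetic_matrix.participant_id != fold.test_participant]
        best = grid_search_inner(sub, fold, spec, BINARY)
        assert best is spec.grid[0]


class TestRunNestedCV:
    def test_separable_binary(self, synthetic_matrix):
        plan = make_nested_plan(PIDS, 0)
        rep = run_nested_cv(synthetic_matrix, BINARY, FAST_LR, plan, 5)
        assert rep.summary["f1"][0] >= 0.85
        assert len(rep.folds) == 10
        for fold in rep.folds:
            assert len(fold.y_pred) == len(fold.y_true) == 60
            assert all(0 <= v <= 1 for v in fold.metrics.values()
                       if v is not None)

    def test_permuted_labels_near_chance_auc(self):
        matrix = make_synthetic_matrix(seed=3)
        rng = np.random.default_rng(5)
        matrix["category"] = rng.permutation(matrix["category"].to_numpy())
        plan = make_nested_plan(PIDS, 0)
        rep = run_nested_cv(matrix, BINARY, FAST_LR, plan, 5)
        assert 0.35 <= rep.summary["auc"][0] <= 0.65

    def test_collapsed_binary_at_least_multiclass_accuracy(self):
        """Merging the 10 predicted activities into FT/NFT cannot create
        new errors, so collapsed accuracy ≥ multiclass accuracy per fold."""
        from facetouch.labels import category_of
        matrix = make_synthetic_matrix(
            seed=1, informative=("mangle", "sdangle", "mvm"), separation=2.0)
        plan = make_nested_plan(PIDS, 0)
        rep = run_nested_cv(matrix, MULTICLASS, FAST_LR, plan, 5)
        for fold in rep.folds:
            collapsed_true = np.array([category_of(a) for a in fold.y_true])
            collapsed_pred = np.array([category_of(a) for a in fold.y_pred])
            acc_collapsed = float(np.mean(collapsed_true == collapsed_pred))
            assert acc_collapsed >= fold.metrics["accuracy"] - 1e-12

    def test_scaler_fitted_on_training_fold_only(self, synthetic_matrix):
        plan = make_nested_plan(PIDS, 0)
        rep = run_nested_cv(synthetic_matrix, BINARY, FAST_LR, plan, 5)
        fold = rep.folds[0]
        train = synthetic_matrix[
            synthetic_matrix.participant_id != fold.test_participant]
        X = train[list(FEATURE_NAMES)].to_numpy()
        Z = fold.model.named_steps["scale"].transform(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-8
        assert np.abs(Z.std(axis=0) - 1).max() < 1e-6

    def test_mean_sd_aggregation(self, synthetic_matrix):
        plan = make_nested_plan(PIDS, 0)
        rep = run_nested_cv(synthetic_matrix, BINARY, FAST_LR, plan, 5)
        accs = [f.metrics["accuracy"] for f in rep.folds]
        assert rep.summary["accuracy"][0] == pytest.approx(np.mean(accs))
        assert rep.summary["accuracy"][1] == pytest.approx(
            np.std(accs, ddof=1))

    def test_report_serializable(self, synthetic_matrix):
        import json
        plan = make_nested_plan(PIDS, 0)
        rep = run_nested_cv(synthetic_matrix, BINARY, FAST_LR, plan, 5)
        d = json.loads(json.dumps(rep.to_dict()))
        assert d["family"] == "logistic_regression"
        assert len(d["folds"]) == 10
        assert d["roc"]  # at least one fold with both classes


class TestForestImportances:
    def test_informative_features_rank_top(self):
        matrix = make_synthetic_matrix(
            seed=2, informative=("mangle", "sdangle"), separation=5.0)
        plan = make_nested_plan(PIDS, 0)
        spec = ModelSpec("random_forest", ({"n_estimators": 50},))
        rep = run_nested_cv(matrix, BINARY, spec, plan, 5)
        imp = rep.importances
        assert imp.max() == pytest.approx(1.0)
        assert (imp >= 0).all() and (imp <= 1).all()
        assert {"mangle", "sdangle"} <= set(imp.index[:5])

    def test_non_forest_rejected(self, synthetic_matrix):
        plan = make_nested_plan(PIDS, 0)
        rep = run_nested_cv(synthetic_matrix, BINARY, FAST_LR, plan, 5)
        with pytest.raises(UnsupportedFamilyError):
            forest_importances(rep.folds)


def test_default_grids_documented_shape():
    assert len(default_model_spec("logistic_regression").grid) == 5
    assert len(default_model_spec("svm").grid) == 9
    assert len(default_model_spec("decision_tree").grid) == 12
    assert len(default_model_spec("random_forest").grid) == 6
    with pytest.raises(UnsupportedFamilyError):
        default_model_spec("cnn")


class TestWindowSweep:
    def test_sweep_table_shape_bounds_and_consistency(self):
        """Shape/bounds, determinism, and each cell equal to an independent
        single-length run with the same seed."""
        from facetouch.features import extract_features
        from facetouch.ingest import align_and_trim
        from facetouch.simulate import SimulationConfig, simulate_dataset
        cfg = SimulationConfig(n_participants=7, activity_duration=35.0,
                               idle_gap=2.0, seed=9)
        recs, logs = simulate_dataset(cfg)
        segs = []
        for r, l in zip(recs, logs):
            segs.extend(align_and_trim(r, l))
        specs = [FAST_LR]
        t1 = window_sweep(segs, [2, 5], BINARY, specs, 30.0, plan_seed=4)
        t2 = window_sweep(segs, [2, 5], BINARY, specs, 30.0, plan_seed=4)
        assert list(t1.index) == [2, 5]
        assert ((t1 >= 0) & (t1 <= 1)).all().all()
        pd.testing.assert_frame_equal(t1, t2)
        # consistency with an independent single-length run
        m5 = extract_features(segs, 5, 30.0)
        plan = make_nested_plan(sorted(m5.participant_id.unique()), 4)
        rep = run_nested_cv(m5, BINARY, FAST_LR, plan, 5)
        assert t1.loc[5, "logistic_regression"] == pytest.approx(
            rep.summary["accuracy"][0])
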