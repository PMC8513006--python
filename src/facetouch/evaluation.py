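"""Participant-grouped nested cross-validation and all reported metrics.

Protocol
--------
Ten outer folds, one per participant: the test set is every window from a
single held-out participant (leave-one-subject-out), the remaining nine
participants form the outer training set.  Those nine are partitioned into
three inner folds of three participants each; grid search trains each
hyperparameter combination on two inner folds (6 participants) and scores it
on the held-out one (3 participants).  The best combination refits on all
nine training participants and is evaluated once on the test participant.
Final metrics are the mean and standard deviation over the ten outer folds.

Features are z-scored using training-fold statistics only (inside an
sklearn Pipeline, so inner fits standardize on inner-training data); the
face-touching (FT) category is the positive class in the binary task.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support, roc_auc_score,
                             roc_curve)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import (DesignError, StratificationError, UnsupportedFamilyError)
from .features import FEATURE_NAMES, extract_features
from .labels import FT

logger = logging.getLogger(__name__)

FAMILIES = ("logistic_regression", "svm", "decision_tree", "random_forest")

BINARY = "binary"
MULTICLASS = "multiclass"


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family with its hyperparameter grid (searched in order)."""

    family: str
    grid: tuple[dict, ...]

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise UnsupportedFamilyError(f"unknown family {self.family!r}")
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")


def default_model_spec(family: str, n_features: int = len(FEATURE_NAMES)
                       ) -> ModelSpec:
    """Default grids: regularization strength for LR/SVM, pre-pruning depth
    and leaf size for the tree, size and depth for the forest."""
    if family == "logistic_regression":
        grid = tuple({"C": c} for c in (0.01, 0.1, 1.0, 10.0, 100.0))
    elif family == "svm":
        grid = tuple({"C": c, "gamma": f / n_features}
                     for c, f in itertools.product((0.1, 1.0, 10.0),
                                                   (0.5, 1.0, 2.0)))
    elif family == "decision_tree":
        grid = tuple({"max_depth": d, "min_samples_leaf": m}
                     for d, m in itertools.product((3, 5, 10, None),
                                                   (1, 5, 10)))
    elif family == "random_forest":
        grid = tuple({"n_estimators": n, "max_depth": d}
                     for n, d in itertools.product((100, 300),
                                                   (5, 10, None)))
    else:
        raise UnsupportedFamilyError(f"unknown family {family!r}")
    return ModelSpec(family, grid)


def make_estimator(family: str, params: dict, random_state: int) -> Pipeline:
    """A fold estimator: per-fold z-scoring followed by the classifier."""
    if family == "logistic_regression":
        clf = LogisticRegression(max_iter=5000, **params)
    elif family == "svm":
        clf = SVC(kernel="rbf", **params)
    elif family == "decision_tree":
        clf = DecisionTreeClassifier(random_state=random_state, **params)
    elif family == "random_forest":
        clf = RandomForestClassifier(random_state=random_state, **params)
    else:
        raise UnsupportedFamilyError(f"unknown family {family!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass(frozen=True)
class OuterFold:
    test_participant: str
    inner_groups: tuple[tuple[str, ...], ...]  # 3 disjoint triples

    @property
    def train_participants(self) -> tuple[str, ...]:
        return tuple(p for g in self.inner_groups for p in g)


@dataclass(frozen=True)
class NestedCVPlan:
    outer_folds: tuple[OuterFold, ...]
    seed: int


def make_nested_plan(participant_ids: list[str], seed: int) -> NestedCVPlan:
    """Build the outer LOSO folds and the inner participant triples.

    Each participant is the test subject in exactly one outer fold; the
    remaining participants are shuffled deterministically by the seed and cut
    into consecutive groups of three.
    """
    ids = sorted(set(participant_ids))
    if len(ids) < 4:
        raise DesignError("need at least 4 participants for nested CV")
    if (len(ids) - 1) % 3 != 0:
        raise DesignError(
            f"{len(ids)} participants: the {len(ids) - 1} training "
            "participants per fold do not divide into groups of 3")
    if (len(ids) - 1) // 3 < 2:
        raise DesignError(
            "need at least 7 participants so every fold has two or more "
            "inner groups (otherwise the inner training set is empty)")
    rng = np.random.default_rng(seed)
    folds = []
    for test in ids:
        rest = [p for p in ids if p != test]
        order = rng.permutation(len(rest))
        shuffled = [rest[i] for i in order]
        groups = tuple(tuple(shuffled[i:i + 3])
                       for i in range(0, len(shuffled), 3))
        folds.append(OuterFold(test, groups))
    return NestedCVPlan(tuple(folds), seed)


# ---------------------------------------------------------------------------
# metrics

def binary_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                   scores: np.ndarray | None = None) -> dict[str, float | None]:
    """Accuracy, recall, precision, F1 (FT positive) and trapezoidal AUC.

    Undefined metrics (no positive examples; single-class test set for AUC)
    are returned as None rather than silently zeroed.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out: dict[str, float | None] = {
        "accuracy": float(accuracy_score(y_true, y_pred))}
    if (y_true == FT).sum() == 0:
        logger.warning("no positive (FT) examples: recall/F1 undefined")
        out.update(recall=None, precision=None, f1=None)
    else:
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, pos_label=FT, average="binary", zero_division=0)
        out.update(recall=float(r), precision=float(p), f1=float(f1))
    if scores is None or len(np.unique(y_true)) < 2:
        if scores is not None:
            logger.warning("single-class test set: AUC undefined")
        out["auc"] = None
    else:
        out["auc"] = float(roc_auc_score(y_true == FT, scores))
    return out


def multiclass_metrics(y_true: np.ndarray, y_pred: np.ndarray
                       ) -> dict[str, float]:
    """Accuracy and macro recall/precision/F1 over the classes present in
    the test fold (absent classes are excluded with a logged note)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    present = np.unique(y_true)
    all_classes = np.unique(np.concatenate([y_true, y_pred]))
    if len(present) < len(all_classes):
        logger.info("classes absent from test fold excluded from macro "
                    "average: %s", sorted(set(all_classes) - set(present)))
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average="macro", zero_division=0)
    return {"accuracy": float(accuracy_score(y_true, y_pred)),
            "recall": float(r), "precision": float(p), "f1": float(f1)}


# ---------------------------------------------------------------------------
# nested CV

@dataclass
class FoldResult:
    fold_index: int
    test_participant: str
    params: dict
    task: str
    metrics: dict[str, float | None]
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray | None            # binary task only
    model: Pipeline = field(repr=False, default=None)


@dataclass
class NestedCVReport:
    family: str
    task: str
    window_length: float
    folds: list[FoldResult]
    summary: dict[str, tuple[float, float]]   # metric -> (mean, sd over folds)
    confusion: pd.DataFrame                   # row-normalized percent
    roc_points: list[dict] | None             # binary task only
    importances: pd.Series | None             # random forest only

    def summary_formatted(self) -> dict[str, str]:
        """"mean (SD)" to two decimals, as conventionally tabulated."""
        return {m: f"{mu:.2f} ({sd:.2f})"
                for m, (mu, sd) in self.summary.items()}

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "task": self.task,
            "window_length": self.window_length,
            "summary": {m: {"mean": mu, "sd": sd}
                        for m, (mu, sd) in self.summary.items()},
            "summary_formatted": self.summary_formatted(),
            "folds": [
                {"fold": f.fold_index, "test_participant": f.test_participant,
                 "params": {k: v for k, v in f.params.items()},
                 "metrics": f.metrics}
                for f in self.folds],
            "confusion_percent": {
                "classes": list(self.confusion.index),
                "rows": self.confusion.to_numpy().tolist()},
        }
        if self.roc_points is not None:
            d["roc"] = self.roc_points
        if self.importances is not None:
            d["importances_scaled"] = self.importances.to_dict()
        return d


def _targets(matrix: pd.DataFrame, task: str) -> np.ndarray:
    if task == BINARY:
        return matrix["category"].to_numpy()
    if task == MULTICLASS:
        return matrix["activity"].to_numpy()
    raise ValueError(f"unknown task {task!r}")


def _svm_score_sign(model: Pipeline) -> float:
    # decision_function is positive for classes_[1]
    return 1.0 if model.classes_[1] == FT else -1.0


def _fold_scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    clf = model.named_steps["clf"]
    if hasattr(clf, "predict_proba"):
        return model.predict_proba(X)[:, list(model.classes_).index(FT)]
    return model.decision_function(X) * _svm_score_sign(model)


def grid_search_inner(matrix: pd.DataFrame, fold: OuterFold, spec: ModelSpec,
                      task: str = BINARY, seed: int = 0) -> dict:
    """Select the grid point maximizing mean inner-validation F1.

    The selection score is the binary F1 (FT positive) for the binary task
    and the macro-F1 for the multiclass task; ties break toward the first
    grid point in the documented order.
    """
    X_all = matrix[list(FEATURE_NAMES)].to_numpy()
    y_all = _targets(matrix, task)
    pids = matrix["participant_id"].to_numpy()
    splits = []
    for held_out in range(len(fold.inner_groups)):
        val_p = set(fold.inner_groups[held_out])
        train_p = {p for g, grp in enumerate(fold.inner_groups)
                   for p in grp if g != held_out}
        tr = np.isin(pids, list(train_p))
        va = np.isin(pids, list(val_p))
        if len(np.unique(y_all[tr])) < 2:
            raise StratificationError(
                f"inner training split (validation group {held_out}, "
                f"participants {sorted(train_p)}) contains a single class")
        splits.append((tr, va))

    best_params, best_score = None, -np.inf
    for params in spec.grid:
        scores = []
        for tr, va in splits:
            model = make_estimator(spec.family, params, random_state=seed)
            model.fit(X_all[tr], y_all[tr])
            y_hat = model.predict(X_all[va])
            if task == BINARY:
                scores.append(binary_metrics(y_all[va], y_hat)["f1"] or 0.0)
            else:
                scores.append(multiclass_metrics(y_all[va], y_hat)["f1"])
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_params, best_score = params, mean_score
    return best_params


def pooled_confusion(folds: list[FoldResult],
                     class_order: list[str] | None = None) -> pd.DataFrame:
    """Pool all outer-fold test predictions; rows normalized to percent."""
    if not folds or all(len(f.y_true) == 0 for f in folds):
        raise ValueError("no predictions to pool")
    y_true = np.concatenate([f.y_true for f in folds])
    y_pred = np.concatenate([f.y_pred for f in folds])
    if class_order is None:
        class_order = sorted(np.unique(np.concatenate([y_true, y_pred])))
    cm = confusion_matrix(y_true, y_pred, labels=class_order).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        cm = np.where(row_sums > 0, 100.0 * cm / row_sums, 0.0)
    return pd.DataFrame(cm, index=class_order, columns=class_order)


def forest_importances(folds: list[FoldResult]) -> pd.Series:
    """Scaled impurity importances: mean over the fold forests ÷ max."""
    imps = []
    for f in folds:
        clf = f.model.named_steps["clf"]
        if not isinstance(clf, (RandomForestClassifier,)):
            raise UnsupportedFamilyError(
                "feature importances are reported for the random forest only")
        imps.append(clf.feature_importances_)
    mean_imp = np.mean(imps, axis=0)
    scaled = mean_imp / mean_imp.max()
    return pd.Series(scaled, index=list(FEATURE_NAMES)).sort_values(
        ascending=False)


def _aggregate(folds: list[FoldResult]) -> dict[str, tuple[float, float]]:
    summary = {}
    metric_names = folds[0].metrics.keys()
    for m in metric_names:
        vals = [f.metrics[m] for f in folds if f.metrics[m] is not None]
        if len(vals) < len(folds):
            logger.warning("metric %s undefined in %d fold(s); excluded "
                           "from the average", m, len(folds) - len(vals))
        summary[m] = (float(np.mean(vals)),
                      float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
    return summary


def run_nested_cv(matrix: pd.DataFrame, task: str, spec: ModelSpec,
                  plan: NestedCVPlan,
                  window_length: float = float("nan")) -> NestedCVReport:
    """Run the full nested protocol on a feature matrix.

    Per outer fold: grid-search on the inner triples, refit the winning
    combination on all nine training participants, evaluate on the held-out
    participant.  Leakage is asserted programmatically.
    """
    pids = matrix["participant_id"].to_numpy()
    plan_pids = {f.test_participant for f in plan.outer_folds}
    missing = plan_pids - set(pids)
    if missing:
        raise DesignError(f"matrix lacks windows for participants {missing}")
    X_all = matrix[list(FEATURE_NAMES)].to_numpy()
    y_all = _targets(matrix, task)

    folds: list[FoldResult] = []
    for i, fold in enumerate(plan.outer_folds):
        train_p = set(fold.train_participants)
        assert fold.test_participant not in train_p, "participant leakage"
        params = grid_search_inner(matrix[np.isin(pids, list(train_p))],
                                  fold, spec, task, seed=plan.seed + i)
        model = make_estimator(spec.family, params,
                               random_state=plan.seed + i)
        tr = np.isin(pids, list(train_p))
        te = pids == fold.test_participant
        model.fit(X_all[tr], y_all[tr])
        y_hat = model.predict(X_all[te])
        scores = _fold_scores(model, X_all[te]) if task == BINARY else None
        metrics = (binary_metrics(y_all[te], y_hat, scores)
                   if task == BINARY else multiclass_metrics(y_all[te], y_hat))
        folds.append(FoldResult(i, fold.test_participant, params, task,
                                metrics, y_all[te], y_hat, scores, model))
        logger.info("fold %d (test %s): %s", i, fold.test_participant,
                    {k: (round(v, 3) if v is not None else None)
                     for k, v in metrics.items()})

    roc_points = None
    if task == BINARY:
        roc_points = []
        for f in folds:
            if len(np.unique(f.y_true)) == 2:
                fpr, tpr, _ = roc_curve(f.y_true == FT, f.scores)
                roc_points.append({"fold": f.fold_index,
                                   "fpr": fpr.tolist(), "tpr": tpr.tolist()})
    importances = (forest_importances(folds)
                   if spec.family == "random_forest" else None)
    return NestedCVReport(spec.family, task, window_length, folds,
                          _aggregate(folds), pooled_confusion(folds),
                          roc_points, importances)


def window_sweep(segments, lengths, task: str, model_specs: list[ModelSpec],
                 sampling_rate: float, plan_seed: int = 0) -> pd.DataFrame:
    """Mean test accuracy for every (window length, model family) pair.

    Re-runs feature extraction and the full nested protocol per length.
    The best length per family is ``table.idxmax()``.
    """
    rows = {}
    for length in lengths:
        matrix = extract_features(segments, length, sampling_rate)
        plan = make_nested_plan(sorted(matrix["participant_id"].unique()),
                                plan_seed)
        rows[length] = {
            spec.family: run_nested_cv(matrix, task, spec, plan,
                                       length).summary["accuracy"][0]
            for spec in model_specs}
    table = pd.DataFrame(rows).T
    table.index.name = "window_length_s"
    return table
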