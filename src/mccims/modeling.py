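"""Dynamic fold selection, stratified cross-validation, final model
training, best-method selection and prediction.

The fold count adapts to the minority class: one fold per five minority
samples, capped at ten, and cross-validation is omitted entirely below ten
minority samples (every test fold then holds at least five samples per
class).  Per fold a random-forest classifier is trained and accuracy, F1,
sensitivity, specificity and trapezoidal ROC-AUC are computed from its
vote-fraction scores.  The final bundle freezes every pipeline parameter so
prediction can reconstruct identical features from new raw measurements.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from mccims.alignment import FeatureMatrix, GridSpec, probe_cluster
from mccims.errors import ValidationError
from mccims.io_formats import LabelTable, Measurement
from mccims.peak_detection import Peak

logger = logging.getLogger(__name__)

MAX_FOLDS = 10
SAMPLES_PER_FOLD = 5
MIN_MINORITY_FOR_CV = 10

__all__ = [
    "FoldPlan",
    "EvalReport",
    "ModelBundle",
    "choose_k",
    "stratified_folds",
    "crossvalidate",
    "resubstitution_report",
    "train_final",
    "select_best_method",
    "split_dataset",
    "predict",
    "save_bundle",
    "load_bundle",
]


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignments: dict[str, int]
    seed: int

    def test_ids(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignments.items() if f == fold)

    def train_ids(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignments.items() if f != fold)


def choose_k(class_counts: Mapping[str, int], user_k: int | None = None) -> int | None:
    """Dynamic fold count: ``min(floor(n_min / 5), 10)``.

    Returns None (cross-validation omitted) when the minority class has
    fewer than ten samples.  ``user_k`` overrides the rule but must be
    fillable by the minority class.
    """
    if len(class_counts) != 2:
        raise ValidationError("fold selection requires exactly two classes")
    n_min = min(class_counts.values())
    if user_k is not None:
        if user_k < 2:
            raise ValidationError("user-supplied k must be >= 2")
        if user_k > n_min:
            raise ValidationError(
                f"k={user_k} unfillable: minority class has only {n_min} samples"
            )
        return user_k
    if n_min < MIN_MINORITY_FOR_CV:
        return None
    return min(n_min // SAMPLES_PER_FOLD, MAX_FOLDS)


def stratified_folds(labels: LabelTable, k: int, seed: int) -> FoldPlan:
    """Class-stratified fold assignment (seeded shuffle + round robin).

    Within each class, fold sizes differ by at most one.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    counts = labels.class_counts()
    small = [c for c, n in counts.items() if n < k]
    if small:
        raise ValidationError(f"classes smaller than k={k}: {small}")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    for cls in sorted(counts):
        ids = sorted(s for s, lab in labels.entries.items() if lab == cls)
        order = rng.permutation(len(ids))
        for pos, idx in enumerate(order):
            assignments[ids[idx]] = pos % k
    return FoldPlan(k=k, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    fold_metrics: list[dict[str, float]]
    confusion: list[dict[str, int]]  # per-fold tp/fp/tn/fn w.r.t. positive class
    roc_points: list[list[tuple[float, float]]]  # per-fold (fpr, tpr)
    positive_class: str
    cv_omitted: bool = False

    def mean(self, metric: str) -> float:
        return float(np.mean([f[metric] for f in self.fold_metrics]))

    def std(self, metric: str) -> float:
        return float(np.std([f[metric] for f in self.fold_metrics]))

    def summary(self) -> dict[str, dict[str, float]]:
        metrics = self.fold_metrics[0].keys()
        return {m: {"mean": self.mean(m), "std": self.std(m)} for m in metrics}

    def to_dict(self) -> dict:
        return {
            "positive_class": self.positive_class,
            "cv_omitted": self.cv_omitted,
            "n_folds": len(self.fold_metrics),
            "fold_metrics": self.fold_metrics,
            "confusion": self.confusion,
            "summary": self.summary(),
        }


def _fold_metrics(y_true, y_score, y_pred, positive: str) -> tuple[dict, dict, list]:
    from sklearn.metrics import auc, roc_curve

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    if pos.all() or not pos.any():
        raise ValidationError(
            "a test fold contains a single class; ROC undefined — use "
            "stratified folds with k <= minority class size"
        )
    tp = int(np.sum((y_pred == positive) & pos))
    fn = int(np.sum((y_pred != positive) & pos))
    fp = int(np.sum((y_pred == positive) & ~pos))
    tn = int(np.sum((y_pred != positive) & ~pos))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * precision * sens / (precision + sens) if (precision + sens) else 0.0
    fpr, tpr, _ = roc_curve(pos.astype(int), y_score)
    metrics = {
        "accuracy": (tp + tn) / len(y_true),
        "f1": f1,
        "sensitivity": sens,
        "specificity": spec,
        "roc_auc": float(auc(fpr, tpr)),
    }
    confusion = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    return metrics, confusion, list(zip(fpr.tolist(), tpr.tolist()))


def _fit_forest(X, y, forest_params: Mapping, seed: int):
    from sklearn.ensemble import RandomForestClassifier

    params = {"n_estimators": 500, **dict(forest_params or {})}
    return RandomForestClassifier(random_state=seed, **params).fit(X, y)


def crossvalidate(
    fm: FeatureMatrix,
    labels: LabelTable,
    plan: FoldPlan,
    forest_params: Mapping | None = None,
    seed: int = 42,
    positive_class: str | None = None,
) -> EvalReport:
    """Train one forest per fold; score its held-out test split."""
    sub = labels.subset(fm.sample_ids)
    neg, pos = sub.require_binary()
    positive = positive_class or pos
    fold_metrics, confusion, rocs = [], [], []
    for fold in range(plan.k):
        train_ids = [s for s in fm.sample_ids if plan.assignments[s] != fold]
        test_ids = [s for s in fm.sample_ids if plan.assignments[s] == fold]
        tr = fm.select_samples(train_ids)
        te = fm.select_samples(test_ids)
        y_tr = [sub[s] for s in train_ids]
        y_te = [sub[s] for s in test_ids]
        forest = _fit_forest(tr.values, y_tr, forest_params, seed + fold)
        pos_idx = list(forest.classes_).index(positive)
        scores = forest.predict_proba(te.values)[:, pos_idx]
        preds = forest.predict(te.values)
        m, c, r = _fold_metrics(y_te, scores, preds, positive)
        fold_metrics.append(m)
        confusion.append(c)
        rocs.append(r)
    return EvalReport(fold_metrics, confusion, rocs, positive)


def resubstitution_report(
    fm: FeatureMatrix,
    labels: LabelTable,
    forest_params: Mapping | None = None,
    seed: int = 42,
    positive_class: str | None = None,
) -> EvalReport:
    """Training-set metrics when cross-validation is omitted (flagged)."""
    sub = labels.subset(fm.sample_ids)
    neg, pos = sub.require_binary()
    positive = positive_class or pos
    y = [sub[s] for s in fm.sample_ids]
    forest = _fit_forest(fm.values, y, forest_params, seed)
    pos_idx = list(forest.classes_).index(positive)
    scores = forest.predict_proba(fm.values)[:, pos_idx]
    preds = forest.predict(fm.values)
    m, c, r = _fold_metrics(y, scores, preds, positive)
    return EvalReport([m], [c], [r], positive, cv_omitted=True)


def select_best_method(reports: Mapping[str, EvalReport]) -> str:
    """Method with the highest mean ROC-AUC; ties by mean accuracy, then name."""
    if not reports:
        raise ValidationError("no reports to select from")
    return min(
        reports,
        key=lambda name: (
            -reports[name].mean("roc_auc"),
            -reports[name].mean("accuracy"),
            name,
        ),
    )


def split_dataset(
    labels: LabelTable, train_ratio: float, seed: int
) -> tuple[list[str], list[str]]:
    """Stratified train/validation split; per class floor(ratio*n) to train."""
    if not (0.0 < train_ratio < 1.0):
        raise ValidationError("train_ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, val = [], []
    for cls in sorted(set(labels.entries.values())):
        ids = sorted(s for s, lab in labels.entries.items() if lab == cls)
        n_train = int(np.floor(train_ratio * len(ids)))
        if n_train == 0:
            raise ValidationError(
                f"class {cls!r} would lose all training members at ratio {train_ratio}"
            )
        order = rng.permutation(len(ids))
        train.extend(ids[i] for i in sorted(order[:n_train]))
        val.extend(ids[i] for i in sorted(order[n_train:]))
    return sorted(train), sorted(val)


# ---------------------------------------------------------------------------
# final model bundle
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """Frozen pipeline parameters plus the trained models.

    Self-contained: prediction needs nothing beyond the bundle and new raw
    measurement files.  The training matrix over the selected features is
    stored so the (seeded, hence deterministic) forest and tree can be
    refit exactly when a bundle is re-loaded from disk.
    """

    preprocess_params: dict
    detection: dict  # {"method": ..., "params": {...}, optional "layer": [...]}
    alignment_params: dict  # {"method": ..., "grid": {...}, ...}
    peak_ids: list[str]
    coords: dict[str, tuple[float, float]]
    forest_params: dict
    tree_params: dict
    seed: int
    positive_class: str
    training_matrix: FeatureMatrix
    training_labels: LabelTable
    forest: object = field(default=None, repr=False)
    tree: object = field(default=None, repr=False)
    report: EvalReport | None = None

    @property
    def grid(self) -> GridSpec:
        return GridSpec.from_dict(self.alignment_params["grid"])


def train_final(
    fm_reduced: FeatureMatrix,
    labels: LabelTable,
    top_ids: Sequence[str],
    tree_params: Mapping | None = None,
    seed: int = 42,
    forest_params: Mapping | None = None,
    preprocess_params: Mapping | None = None,
    detection: Mapping | None = None,
    positive_class: str | None = None,
    report: EvalReport | None = None,
) -> ModelBundle:
    """Train the final forest and the interpretable decision tree.

    Both models use only the ``top_ids`` columns of the reduced feature
    matrix; the tree is depth-unlimited by default with
    ``min_samples_split``/``min_samples_leaf`` exposed for underfitting.
    """
    from sklearn.tree import DecisionTreeClassifier

    if not top_ids:
        raise ValidationError("top_ids must not be empty")
    missing = [p for p in top_ids if p not in fm_reduced.peak_ids]
    if missing:
        raise ValidationError(f"top ids not in feature matrix: {missing}")
    sub = labels.subset(fm_reduced.sample_ids)
    neg, pos = sub.require_binary()
    fm_top = fm_reduced.select_columns(list(top_ids))
    y = [sub[s] for s in fm_top.sample_ids]
    forest = _fit_forest(fm_top.values, y, forest_params, seed)
    t_params = {"min_samples_split": 2, "min_samples_leaf": 1, **dict(tree_params or {})}
    tree = DecisionTreeClassifier(random_state=seed, **t_params).fit(fm_top.values, y)
    return ModelBundle(
        preprocess_params=dict(preprocess_params or {}),
        detection=dict(detection or {}),
        alignment_params=dict(fm_reduced.alignment_params),
        peak_ids=list(top_ids),
        coords={p: fm_reduced.coords.get(p, (float("nan"),) * 2) for p in top_ids},
        forest_params={"n_estimators": 500, **dict(forest_params or {})},
        tree_params=t_params,
        seed=seed,
        positive_class=positive_class or pos,
        training_matrix=fm_top,
        training_labels=sub,
        forest=forest,
        tree=tree,
        report=report,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _features_from_measurement(bundle: ModelBundle, m: Measurement) -> np.ndarray:
    from mccims.peak_detection import detect_with_method
    from mccims.preprocess import apply_chain

    processed, noise = apply_chain(m, bundle.preprocess_params)
    peaks = detect_with_method(processed, noise, bundle.detection)
    if bundle.alignment_params.get("method") == "dbscan":
        from mccims.alignment import dbscan_align

        fm = dbscan_align(
            peaks,
            eps=float(bundle.alignment_params.get("eps", 0.01)),
            min_samples=int(bundle.alignment_params.get("min_samples", 2)),
            grid=bundle.grid,
            sample_ids=[m.sample_id],
        )
    else:
        fm = probe_cluster(peaks, grid=bundle.grid, sample_ids=[m.sample_id])
    vec = np.zeros(len(bundle.peak_ids))
    for j, pid in enumerate(bundle.peak_ids):
        if pid in fm.peak_ids:
            vec[j] = fm.values[0, fm.peak_ids.index(pid)]
    return vec


def predict(
    bundle: ModelBundle,
    inputs: Sequence[Measurement] | FeatureMatrix,
) -> dict[str, tuple[str, float]]:
    """Predict class labels for new raw measurements or a feature matrix.

    Raw measurements are replayed through the bundle's stored
    preprocessing, detection and alignment; feature-matrix input skips
    straight to column lookup (missing required columns fill with 0 and a
    warning).  Returns sample_id -> (predicted label, forest probability of
    that label).
    """
    if bundle.forest is None:
        raise ValidationError("bundle has no trained forest; load or train it first")
    if isinstance(inputs, FeatureMatrix):
        sample_ids = list(inputs.sample_ids)
        missing = [p for p in bundle.peak_ids if p not in inputs.peak_ids]
        if missing:
            warnings.warn(f"feature matrix missing required columns (filled 0): {missing}")
        X = np.zeros((len(sample_ids), len(bundle.peak_ids)))
        for j, pid in enumerate(bundle.peak_ids):
            if pid in inputs.peak_ids:
                X[:, j] = inputs.values[:, inputs.peak_ids.index(pid)]
    else:
        sample_ids = [m.sample_id for m in inputs]
        X = np.vstack([_features_from_measurement(bundle, m) for m in inputs])
    proba = bundle.forest.predict_proba(X)
    classes = list(bundle.forest.classes_)
    out: dict[str, tuple[str, float]] = {}
    for i, sid in enumerate(sample_ids):
        best = int(np.argmax(proba[i]))
        out[sid] = (classes[best], float(proba[i, best]))
    return out


# ---------------------------------------------------------------------------
# bundle persistence (text-only: parameters + training matrix; models are
# refit deterministically from the stored seed on load)
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, directory) -> None:
    from sklearn.tree import export_graphviz, export_text

    from mccims.io_formats import write_feature_matrix, write_labels

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    params = {
        "preprocess": bundle.preprocess_params,
        "detection": bundle.detection,
        "alignment": bundle.alignment_params,
        "peak_ids": bundle.peak_ids,
        "coords": {p: list(c) for p, c in bundle.coords.items()},
        "forest_params": bundle.forest_params,
        "tree_params": bundle.tree_params,
        "seed": bundle.seed,
        "positive_class": bundle.positive_class,
    }
    (d / "params.json").write_text(json.dumps(params, indent=2, sort_keys=True))
    write_feature_matrix(bundle.training_matrix, d / "features.csv")
    write_labels(bundle.training_labels, d / "training_labels.csv")
    if bundle.tree is not None:
        dot = export_graphviz(
            bundle.tree, feature_names=bundle.peak_ids,
            class_names=list(bundle.tree.classes_), filled=False,
        )
        (d / "tree.dot").write_text(dot)
        (d / "tree.txt").write_text(export_text(bundle.tree, feature_names=bundle.peak_ids))
    if bundle.report is not None:
        (d / "report.json").write_text(json.dumps(bundle.report.to_dict(), indent=2))
        with open(d / "roc_points.csv", "w", encoding="utf-8") as fh:
            fh.write("fold,fpr,tpr\n")
            for fold, points in enumerate(bundle.report.roc_points):
                for fpr, tpr in points:
                    fh.write(f"{fold},{fpr!r},{tpr!r}\n")


def load_bundle(directory) -> ModelBundle:
    """Reload a bundle; the forest and tree are refit from the stored seed."""
    from mccims.io_formats import read_feature_matrix, read_labels

    d = Path(directory)
    params = json.loads((d / "params.json").read_text())
    grid = GridSpec.from_dict(params["alignment"]["grid"])
    fm = read_feature_matrix(d / "features.csv", grid=grid)
    fm.alignment_params = params["alignment"]
    fm = fm.select_columns(params["peak_ids"])
    labels = read_labels(d / "training_labels.csv")
    return train_final(
        fm_reduced=fm,
        labels=labels,
        top_ids=params["peak_ids"],
        tree_params=params["tree_params"],
        seed=int(params["seed"]),
        forest_params=params["forest_params"],
        preprocess_params=params["preprocess"],
        detection=params["detection"],
        positive_class=params["positive_class"],
    )
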