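import numpy as np
import pytest

from mccims.alignment import FeatureMatrix
from mccims.errors import ValidationError
from mccims.io_formats import LabelTable, Measurement
from mccims.modeling import (
    choose_k,
    crossvalidate,
    load_bundle,
    predict,
    resubstitution_report,
    save_bundle,
    select_best_method,
    split_dataset,
    stratified_folds,
    train_final,
)


def fm_from(values, sample_ids=None, peak_ids=None, alignment_params=None):
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i:03d}" for i in range(values.shape[0])]
    peak_ids = peak_ids or [f"Peak_{j:04d}" for j in range(values.shape[1])]
    from mccims.alignment import build_grid

    return FeatureMatrix(
        sample_ids=sample_ids, peak_ids=peak_ids, values=values,
        alignment_params=alignment_params
        or {"method": "probe_clustering", "grid": build_grid().to_dict()},
    )


def balanced_labels(fm, split):
    return LabelTable({s: ("a" if i < split else "b") for i, s in enumerate(fm.sample_ids)})


def separable(n_per_class=10, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    values = rng.random((n, 4)) * 0.2
    values[:n_per_class, 0] += 0.8
    fm = fm_from(values)
    return fm, balanced_labels(fm, n_per_class)


# ---------------------------------------------------------------------------
# choose_k
# ---------------------------------------------------------------------------

def test_choose_k_worked_example():
    assert choose_k({"a": 15, "b": 20}) == 3


def test_choose_k_omitted_below_ten():
    assert choose_k({"a": 9, "b": 50}) is None


def test_choose_k_cap_at_ten():
    assert choose_k({"a": 200, "b": 300}) == 10


def test_choose_k_minimum_case():
    assert choose_k({"a": 10, "b": 10}) == 2


def test_choose_k_brute_force_table():
    # oracle: largest k <= 10 whose test folds keep >= 5 minority samples,
    # i.e. max{k : floor(n_min/k) >= 5}; omitted below 10
    for n_min in range(0, 201):
        counts = {"a": n_min, "b": n_min + 37}
        expected = None
        if n_min >= 10:
            expected = max(k for k in range(2, 11) if n_min // k >= 5)
        assert choose_k(counts) == expected


def test_choose_k_user_override():
    assert choose_k({"a": 31, "b": 93}, user_k=10) == 10
    with pytest.raises(ValidationError, match="unfillable"):
        choose_k({"a": 4, "b": 50}, user_k=5)
    with pytest.raises(ValidationError):
        choose_k({"a": 30, "b": 30}, user_k=1)


# ---------------------------------------------------------------------------
# stratified folds
# ---------------------------------------------------------------------------

def make_labels(n_a, n_b):
    entries = {f"a{i:03d}": "a" for i in range(n_a)}
    entries.update({f"b{i:03d}": "b" for i in range(n_b)})
    return LabelTable(entries)


def test_folds_15_20_have_five_per_class():
    labels = make_labels(15, 20)
    plan = stratified_folds(labels, 3, seed=0)
    for fold in range(3):
        test = plan.test_ids(fold)
        n_a = sum(labels[s] == "a" for s in test)
        n_b = sum(labels[s] == "b" for s in test)
        assert n_a == 5
        assert n_b >= 5


def test_folds_deterministic():
    labels = make_labels(12, 18)
    assert stratified_folds(labels, 3, 7) == stratified_folds(labels, 3, 7)
    assert stratified_folds(labels, 3, 7) != stratified_folds(labels, 3, 8)


def test_fold_sizes_differ_at_most_one_per_class():
    labels = make_labels(13, 29)
    plan = stratified_folds(labels, 4, 1)
    for cls, n_cls in (("a", 13), ("b", 29)):
        sizes = [sum(labels[s] == cls for s in plan.test_ids(f)) for f in range(4)]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == n_cls
        assert min(sizes) >= n_cls // 4


def test_folds_class_smaller_than_k_rejected():
    with pytest.raises(ValidationError, match="smaller than k"):
        stratified_folds(make_labels(2, 20), 3, 0)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_cv_perfectly_separable():
    fm, labels = separable(10)
    plan = stratified_folds(labels, 2, 0)
    report = crossvalidate(fm, labels, plan, {"n_estimators": 50}, seed=0)
    assert report.mean("roc_auc") == 1.0
    assert report.mean("accuracy") == 1.0
    assert report.positive_class == "b"


def test_cv_null_labels_auc_near_half():
    rng = np.random.default_rng(123)
    aucs = []
    for seed in range(10):
        values = np.random.default_rng(1000 + seed).random((100, 3))
        fm = fm_from(values)
        shuffled = rng.permutation([("a" if i < 50 else "b") for i in range(100)])
        labels = LabelTable(dict(zip(fm.sample_ids, shuffled)))
        plan = stratified_folds(labels, 5, seed)
        report = crossvalidate(fm, labels, plan, {"n_estimators": 30}, seed=seed)
        aucs.append(report.mean("roc_auc"))
    assert abs(np.mean(aucs) - 0.5) <= 0.1


def test_cv_metric_identities_from_confusion():
    fm, labels = separable(8, seed=3)
    plan = stratified_folds(labels, 2, 3)
    report = crossvalidate(fm, labels, plan, {"n_estimators": 50}, seed=3)
    for m, c in zip(report.fold_metrics, report.confusion):
        tp, fp, tn, fn = c["tp"], c["fp"], c["tn"], c["fn"]
        assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
        assert m["specificity"] == pytest.approx(tn / (tn + fp))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn)
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        assert m["f1"] == pytest.approx(f1)
        assert m["accuracy"] == pytest.approx((tp + tn) / (tp + tn + fp + fn))
        assert 0.0 <= m["roc_auc"] <= 1.0


def test_cv_single_class_fold_rejected():
    fm, labels = separable(4)
    # adversarial plan: fold 0 holds only class a
    assignments = {s: (0 if labels[s] == "a" else 1) for s in fm.sample_ids}
    from mccims.modeling import FoldPlan

    plan = FoldPlan(k=2, assignments=assignments, seed=0)
    with pytest.raises(ValidationError, match="single class"):
        crossvalidate(fm, labels, plan, {"n_estimators": 10}, seed=0)


def test_resubstitution_report_flagged():
    fm, labels = separable(5)
    report = resubstitution_report(fm, labels, {"n_estimators": 50}, seed=0)
    assert report.cv_omitted
    assert len(report.fold_metrics) == 1
    assert report.mean("accuracy") == 1.0


# ---------------------------------------------------------------------------
# best method / split
# ---------------------------------------------------------------------------

def fake_report(auc, acc):
    from mccims.modeling import EvalReport

    return EvalReport(
        fold_metrics=[{"accuracy": acc, "f1": acc, "sensitivity": acc,
                       "specificity": acc, "roc_auc": auc}],
        confusion=[{"tp": 1, "fp": 0, "tn": 1, "fn": 0}],
        roc_points=[[(0.0, 1.0)]],
        positive_class="b",
    )


def test_select_best_by_auc():
    reports = {"TOPHAT": fake_report(0.8, 0.9), "WATERSHED": fake_report(0.95, 0.8)}
    assert select_best_method(reports) == "WATERSHED"


def test_select_best_tie_by_accuracy_then_name():
    reports = {"TOPHAT": fake_report(0.9, 0.9), "WATERSHED": fake_report(0.9, 0.8)}
    assert select_best_method(reports) == "TOPHAT"
    reports = {"TOPHAT": fake_report(0.9, 0.9), "JIBB": fake_report(0.9, 0.9)}
    assert select_best_method(reports) == "JIBB"
    assert select_best_method({"X": fake_report(0.5, 0.5)}) == "X"


def test_split_candy_ratio():
    labels = make_labels(20, 22)
    train, val = split_dataset(labels, 0.8, seed=0)
    counts = lambda ids, c: sum(labels[s] == c for s in ids)
    assert (counts(train, "a"), counts(train, "b")) == (16, 17)
    assert (counts(val, "a"), counts(val, "b")) == (4, 5)
    assert sorted(train + val) == sorted(labels.entries)


def test_split_copd_ratio():
    labels = make_labels(93, 35)
    train, _ = split_dataset(labels, 0.9, seed=1)
    counts = lambda ids, c: sum(labels[s] == c for s in ids)
    assert (counts(train, "a"), counts(train, "b")) == (83, 31)


def test_split_deterministic_and_validated():
    labels = make_labels(10, 10)
    assert split_dataset(labels, 0.7, 5) == split_dataset(labels, 0.7, 5)
    with pytest.raises(ValidationError):
        split_dataset(labels, 1.5, 0)
    with pytest.raises(ValidationError, match="lose all training members"):
        split_dataset(make_labels(1, 50), 0.5, 0)


# ---------------------------------------------------------------------------
# final training + prediction + bundle round-trip
# ---------------------------------------------------------------------------

def test_tree_depth_one_for_single_separating_feature():
    fm, labels = separable(10)
    bundle = train_final(fm, labels, ["Peak_0000"], seed=0,
                         forest_params={"n_estimators": 50})
    assert bundle.tree.get_depth() == 1
    assert bundle.tree.tree_.feature[0] == 0


def test_tree_single_leaf_with_huge_min_samples_leaf():
    fm, labels = separable(10)
    bundle = train_final(fm, labels, list(fm.peak_ids), seed=0,
                         tree_params={"min_samples_leaf": 15},
                         forest_params={"n_estimators": 10})
    assert bundle.tree.get_depth() == 0


def test_train_final_validation():
    fm, labels = separable(5)
    with pytest.raises(ValidationError, match="not be empty"):
        train_final(fm, labels, [], seed=0)
    with pytest.raises(ValidationError, match="not in feature matrix"):
        train_final(fm, labels, ["Peak_9999"], seed=0)


def test_resubstitution_accuracy_at_least_cv_mean():
    fm, labels = separable(10, seed=5)
    plan = stratified_folds(labels, 2, 5)
    cv = crossvalidate(fm, labels, plan, {"n_estimators": 50}, seed=5)
    bundle = train_final(fm, labels, list(fm.peak_ids), seed=5,
                         forest_params={"n_estimators": 50})
    preds = predict(bundle, fm)
    acc = np.mean([preds[s][0] == labels[s] for s in fm.sample_ids])
    assert acc >= cv.mean("accuracy") - 1e-9


def test_predict_feature_matrix_missing_column_filled_zero():
    fm, labels = separable(10)
    bundle = train_final(fm, labels, list(fm.peak_ids), seed=0,
                         forest_params={"n_estimators": 20})
    partial = fm_from(fm.values[:, :2], sample_ids=fm.sample_ids,
                      peak_ids=fm.peak_ids[:2])
    with pytest.warns(UserWarning, match="filled 0"):
        preds = predict(bundle, partial)
    assert len(preds) == len(fm.sample_ids)


def test_predict_all_zero_measurement_majority_class():
    fm, labels = separable(10)
    # majority class via imbalance: drop some 'a' samples
    keep = fm.sample_ids[5:]
    fm2 = fm.select_samples(keep)
    labels2 = labels.subset(keep)
    bundle = train_final(fm2, labels2, list(fm2.peak_ids), seed=0,
                         forest_params={"n_estimators": 50},
                         preprocess_params={"chain": "default"},
                         detection={"method": "WATERSHED", "params": {}})
    zero = Measurement("z", np.arange(1.0, 21.0), np.linspace(0.02, 0.8, 40),
                       np.zeros((20, 40)))
    zero = Measurement("z", zero.rt_axis, zero.irm_axis,
                       np.full((20, 40), 1e-6))  # epsilon so normalization works
    preds = predict(bundle, [zero])
    assert preds["z"][0] == "b"  # majority class
    assert 0.0 <= preds["z"][1] <= 1.0


def test_bundle_roundtrip_identical_model(tmp_path):
    fm, labels = separable(10, seed=2)
    bundle = train_final(fm, labels, list(fm.peak_ids), seed=2,
                         forest_params={"n_estimators": 50},
                         detection={"method": "WATERSHED", "params": {}})
    save_bundle(bundle, tmp_path / "bundle")
    assert (tmp_path / "bundle" / "params.json").exists()
    assert (tmp_path / "bundle" / "tree.dot").exists()
    loaded = load_bundle(tmp_path / "bundle")
    assert loaded.peak_ids == bundle.peak_ids
    preds_a = predict(bundle, fm)
    preds_b = predict(loaded, fm)
    assert preds_a == preds_b
    from sklearn.tree import export_text

    assert export_text(loaded.tree, feature_names=bundle.peak_ids) == export_text(
        bundle.tree, feature_names=bundle.peak_ids
    )
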