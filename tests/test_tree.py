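"""From-scratch CART: oracles first, then behaviour and serialization.

Independent oracles used here:
- brute-force enumeration of every (feature, midpoint) split for the best
  first split;
- sklearn's DecisionTreeClassifier for full-tree predictions on continuous
  data (where tie-breaking cannot differ);
- O(n^2) concordant-pair counting for AUROC.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.tree import DecisionTreeClassifier

from pdsubtypes.tree import (CVGrid, OnsetTreeClassifier, cross_validate_grid,
                             evaluate, fit_tree, gini_feature_importance,
                             gini_impurity)


# ------------------------------------------------------------------ oracles

def brute_force_best_split(X, y, min_samples_leaf):
    """Enumerate every feature/midpoint; ties -> lowest feature, smallest
    threshold. Returns (feature, threshold, decrease) or None."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    parent = gini_impurity([np.sum(y == 0), np.sum(y == 1)])
    best = None
    for f in range(X.shape[1]):
        values = np.unique(X[:, f])
        for a, b in zip(values[:-1], values[1:]):
            t = (a + b) / 2.0
            left = X[:, f] <= t
            nl, nr = left.sum(), n - left.sum()
            if nl < min_samples_leaf or nr < min_samples_leaf:
                continue
            gl = gini_impurity([np.sum(y[left] == 0), np.sum(y[left] == 1)])
            gr = gini_impurity([np.sum(y[~left] == 0), np.sum(y[~left] == 1)])
            decrease = parent - (nl * gl + nr * gr) / n
            if decrease <= 1e-12:
                continue
            if best is None or decrease > best[2] + 1e-12:
                best = (f, t, decrease)
    return best


def pairwise_auroc(y, scores):
    """Concordant-pair AUROC with half-credit for ties."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = len(pos) * len(neg)
    credit = 0.0
    for p, q in itertools.product(pos, neg):
        credit += 1.0 if p > q else (0.5 if p == q else 0.0)
    return credit / total


# ------------------------------------------------------------ gini impurity

def test_gini_impurity_known_values():
    assert gini_impurity([10, 0]) == 0.0
    assert gini_impurity([5, 5]) == pytest.approx(0.5)
    assert gini_impurity([1, 3]) == pytest.approx(0.375)
    assert gini_impurity([20, 50]) == pytest.approx(0.40816, abs=1e-5)


def test_gini_impurity_rejects_bad_input():
    with pytest.raises(ValueError):
        gini_impurity([0, 0])
    with pytest.raises(ValueError):
        gini_impurity([-1, 2])


@given(st.integers(0, 50), st.integers(0, 50))
def test_gini_impurity_bounds_and_symmetry(a, b):
    if a + b == 0:
        return
    g = gini_impurity([a, b])
    assert 0.0 <= g <= 0.5
    assert g == pytest.approx(gini_impurity([b, a]))


# ------------------------------------------------------------- split search

@given(st.data())
def test_first_split_matches_brute_force(data):
    n = data.draw(st.integers(8, 30))
    n_features = data.draw(st.integers(1, 4))
    msl = data.draw(st.integers(1, 3))
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    X = rng.integers(0, 5, size=(n, n_features)).astype(float)
    y = rng.integers(0, 2, size=n)
    if len(np.unique(y)) < 2:
        return
    model = OnsetTreeClassifier(max_depth=1, min_samples_leaf=msl).fit(X, y)
    root = model.nodes_[0]
    expected = brute_force_best_split(X, y, msl)
    if expected is None:
        assert root.is_leaf
    else:
        assert not root.is_leaf
        assert root.split_feature == expected[0]
        assert root.threshold == pytest.approx(expected[1])
        assert root.impurity_decrease == pytest.approx(expected[2])


def test_tie_breaks_to_lowest_feature_index():
    # identical columns: both give the same best decrease; feature 0 must win
    X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
    y = np.array([0, 0, 1, 1])
    model = OnsetTreeClassifier(max_depth=1, min_samples_leaf=1).fit(X, y)
    assert model.nodes_[0].split_feature == 0


def test_tie_breaks_to_smallest_threshold_within_feature():
    # values 0,1,2,3 with labels 0,0,1,1 leave two equally good midpoints
    # when the middle pair is mixed; construct equal-decrease thresholds
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0, 1, 0, 1])
    # decreases: t=0.5 and t=2.5 both give 0.5 - (well, compute): all equal
    model = OnsetTreeClassifier(max_depth=1, min_samples_leaf=1).fit(X, y)
    root = model.nodes_[0]
    candidates = [(t, brute_force_best_split(X, y, 1))
                  for t in (0.5, 1.5, 2.5)]
    # whatever the maximum is, ours must equal the smallest threshold among
    # maxima; brute_force already applies that rule
    assert root.threshold == pytest.approx(candidates[0][1][1])


def test_pure_node_is_leaf():
    X = np.array([[0.0], [1.0], [2.0]])
    y = np.array([1, 1, 1])
    model = fit_tree(X, y, max_depth=5, min_samples_leaf=1)
    assert len(model.nodes_) == 1
    assert model.nodes_[0].is_leaf
    assert model.nodes_[0].leaf_label == 1


def test_max_depth_zero_gives_single_leaf():
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0, 0, 1, 1])
    model = fit_tree(X, y, max_depth=0, min_samples_leaf=1)
    assert len(model.nodes_) == 1


def test_min_samples_leaf_respected():
    rng = np.random.default_rng(5)
    X = rng.integers(0, 5, size=(40, 3)).astype(float)
    y = rng.integers(0, 2, size=40)
    model = fit_tree(X, y, max_depth=10, min_samples_leaf=7)
    for leaf in model.leaves_:
        assert sum(leaf.class_counts) >= 7


def test_no_split_without_strict_impurity_decrease():
    # alternating labels over a constant feature: no split possible at all
    X = np.zeros((10, 1))
    y = np.array([0, 1] * 5)
    model = fit_tree(X, y, max_depth=5, min_samples_leaf=1)
    assert len(model.nodes_) == 1


def test_leaf_majority_tie_labels_late_onset():
    X = np.zeros((4, 1))
    y = np.array([0, 0, 1, 1])
    model = fit_tree(X, y, max_depth=3, min_samples_leaf=1)
    assert model.nodes_[0].leaf_label == 1


def test_predictions_match_sklearn_on_continuous_data():
    """On continuous features with a unique optimum at every node the
    from-scratch tree and sklearn's CART agree on all predictions."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(200, 4))
    y = ((X[:, 0] + 0.5 * X[:, 1] + 0.2 * rng.normal(size=200)) > 0).astype(int)
    # depth 3: deeper trees can legitimately diverge because sklearn also
    # accepts zero-gain splits while this tree requires a strict decrease
    ours = fit_tree(X, y, max_depth=3, min_samples_leaf=10)
    theirs = DecisionTreeClassifier(max_depth=3, min_samples_leaf=10,
                                    criterion="gini", random_state=0).fit(X, y)
    X_new = rng.normal(size=(500, 4))
    agreement = (ours.predict(X_new) == theirs.predict(X_new)).mean()
    assert agreement == 1.0
    # training accuracy also matches
    assert (ours.predict(X) == theirs.predict(X)).mean() == 1.0


def test_training_accuracy_matches_sklearn_across_seeds():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(120, 3))
        y = rng.integers(0, 2, size=120)
        ours = fit_tree(X, y, max_depth=3, min_samples_leaf=5)
        theirs = DecisionTreeClassifier(max_depth=3, min_samples_leaf=5,
                                        random_state=0).fit(X, y)
        ours_acc = (ours.predict(X) == y).mean()
        theirs_acc = (theirs.predict(X) == y).mean()
        assert ours_acc == pytest.approx(theirs_acc)


# -------------------------------------------------------------- importances

def test_feature_importances_hand_computed_two_split_tree():
    """Root splits feature 0 (gain 2/9), its right child splits feature 1
    (weighted gain 2/9); importances are (0.5, 0.5)."""
    X = np.array([[0, 5], [0, 5], [0, 5], [1, 9], [1, 5], [1, 5]], dtype=float)
    y = np.array([0, 0, 0, 0, 1, 1])
    model = fit_tree(X, y, max_depth=2, min_samples_leaf=1)
    root = model.nodes_[0]
    assert root.split_feature == 0
    assert root.impurity_decrease == pytest.approx(2 / 9)
    np.testing.assert_allclose(model.feature_importances_, [0.5, 0.5])


def test_importances_zero_for_stump_without_splits():
    X = np.zeros((6, 2))
    y = np.array([0, 1, 0, 1, 0, 1])
    model = fit_tree(X, y, max_depth=3, min_samples_leaf=1)
    np.testing.assert_array_equal(model.feature_importances_, [0.0, 0.0])


def test_gini_feature_importance_named_and_sorted():
    frame = pd.DataFrame({"signal": [0.0, 0, 0, 1, 1, 1] * 5,
                          "noise": [0.0] * 30})
    y = np.array([0, 0, 0, 1, 1, 1] * 5)
    model = fit_tree(frame, y, max_depth=2, min_samples_leaf=1)
    series = gini_feature_importance(model)
    assert list(series.index) == ["signal", "noise"]
    assert series["signal"] == pytest.approx(1.0)


# --------------------------------------------------------------- inference

def test_apply_routes_rows_to_training_leaves():
    rng = np.random.default_rng(3)
    X = rng.integers(0, 5, size=(60, 3)).astype(float)
    y = rng.integers(0, 2, size=60)
    model = fit_tree(X, y, max_depth=4, min_samples_leaf=5)
    leaves = model.apply(X)
    for leaf in model.leaves_:
        routed = np.flatnonzero(leaves == leaf.node_id)
        np.testing.assert_array_equal(np.sort(routed),
                                      np.sort(model.leaf_row_indices_[leaf.node_id]))


def test_predict_proba_rows_sum_to_one():
    rng = np.random.default_rng(9)
    X = rng.integers(0, 5, size=(50, 2)).astype(float)
    y = rng.integers(0, 2, size=50)
    model = fit_tree(X, y, max_depth=3, min_samples_leaf=5)
    proba = model.predict_proba(X)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)
    np.testing.assert_array_equal(model.predict(X),
                                  np.array([model.nodes_[l].leaf_label
                                            for l in model.apply(X)]))


def test_decision_path_conditions_reproduce_leaf_membership():
    rng = np.random.default_rng(11)
    frame = pd.DataFrame(rng.integers(0, 5, size=(80, 4)).astype(float),
                         columns=["f0", "f1", "f2", "f3"])
    y = rng.integers(0, 2, size=80)
    model = fit_tree(frame, y, max_depth=4, min_samples_leaf=5)
    leaves = model.apply(frame)
    for leaf in model.leaves_:
        mask = np.ones(len(frame), dtype=bool)
        for name, op, t in model.decision_path_conditions(leaf.node_id):
            col = frame[name].to_numpy()
            mask &= (col <= t) if op == "<=" else (col > t)
        np.testing.assert_array_equal(mask, leaves == leaf.node_id)


def test_unique_patient_counts_ignore_duplicates():
    X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0]])
    y = np.array([0, 0, 0, 1, 1])
    ids = np.array(["A", "A", "B", "C", "C"])
    model = fit_tree(X, y, max_depth=1, min_samples_leaf=1, patient_ids=ids)
    root = model.nodes_[0]
    assert root.class_counts == (3, 2)
    assert root.unique_counts == (2, 1)


def test_fit_rejects_missing_values_and_nonbinary_labels():
    with pytest.raises(ValueError, match="missing"):
        fit_tree(np.array([[np.nan], [1.0]]), np.array([0, 1]))
    with pytest.raises(ValueError, match="binary"):
        fit_tree(np.array([[0.0], [1.0]]), np.array([0, 2]))


# ------------------------------------------------------------ serialization

def test_json_round_trip_preserves_predictions(tmp_path):
    rng = np.random.default_rng(21)
    frame = pd.DataFrame(rng.integers(0, 5, size=(70, 3)).astype(float),
                         columns=["a", "b", "c"])
    y = rng.integers(0, 2, size=70)
    model = fit_tree(frame, y, max_depth=4, min_samples_leaf=5)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = OnsetTreeClassifier.from_json(path)
    np.testing.assert_array_equal(back.predict(frame), model.predict(frame))
    np.testing.assert_allclose(back.feature_importances_,
                               model.feature_importances_)
    also = OnsetTreeClassifier.from_json(model.to_json())
    np.testing.assert_array_equal(also.predict(frame), model.predict(frame))


def test_sklearn_estimator_protocol():
    model = OnsetTreeClassifier(max_depth=3, min_samples_leaf=12)
    params = model.get_params()
    assert params == {"max_depth": 3, "min_samples_leaf": 12}
    model.set_params(max_depth=5)
    assert model.max_depth == 5
    from sklearn.base import clone
    clone(model)  # must not raise


# --------------------------------------------------------------- CV + eval

def make_cv_frame(n=60, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "onset_label": rng.integers(0, 2, size=n),
        "f0": rng.integers(0, 5, size=n).astype(float),
        "f1": rng.integers(0, 5, size=n).astype(float),
    })
    # guarantee both classes exist in every fold-complement
    frame.loc[:5, "onset_label"] = [0, 0, 0, 1, 1, 1]
    return frame


def test_cv_grid_rejects_small_min_samples_leaf():
    with pytest.raises(ValueError):
        CVGrid(min_samples_leaf=(5,))


def test_cross_validate_grid_returns_full_table():
    frame = make_cv_frame()
    grid = CVGrid(min_samples_leaf=(10, 12), max_depth=(2, 4), k=5)
    best, table = cross_validate_grid(frame, ["f0", "f1"], grid)
    assert len(table) == 4
    assert set(table.columns) == {"max_depth", "min_samples_leaf", "mean_accuracy"}
    assert (table["mean_accuracy"].between(0, 1)).all()
    top = table["mean_accuracy"].max()
    assert best["mean_accuracy"] == pytest.approx(top)
    tied = table[np.isclose(table["mean_accuracy"], top)]
    assert best["max_depth"] == tied["max_depth"].min()


def test_cross_validate_grid_is_deterministic():
    frame = make_cv_frame()
    grid = CVGrid(min_samples_leaf=(10,), max_depth=(2,), k=5)
    _, a = cross_validate_grid(frame, ["f0", "f1"], grid)
    _, b = cross_validate_grid(frame, ["f0", "f1"], grid)
    pd.testing.assert_frame_equal(a, b)


def test_cross_validate_rejects_k_above_patient_count():
    frame = make_cv_frame(n=8)
    with pytest.raises(ValueError, match="unique patients"):
        cross_validate_grid(frame, ["f0", "f1"], CVGrid(k=10))


def test_evaluate_metrics_on_known_predictions():
    # stump that routes by f0: build a separable problem
    X = pd.DataFrame({"f0": [0.0, 0, 0, 1, 1, 1, 1, 1]})
    y = np.array([0, 0, 0, 1, 1, 1, 1, 1])
    model = fit_tree(X, y, max_depth=1, min_samples_leaf=1)
    metrics = evaluate(model, X, y)
    assert metrics == {"accuracy": 1.0, "precision": 1.0, "recall": 1.0,
                       "auroc": 1.0}


def test_evaluate_auroc_matches_pairwise_oracle():
    rng = np.random.default_rng(17)
    X = pd.DataFrame(rng.integers(0, 5, size=(80, 3)).astype(float),
                     columns=["a", "b", "c"])
    y = rng.integers(0, 2, size=80)
    model = fit_tree(X, y, max_depth=3, min_samples_leaf=5)
    metrics = evaluate(model, X, y)
    scores = model.predict_proba(X)[:, 1]
    assert metrics["auroc"] == pytest.approx(pairwise_auroc(y, scores))


def test_evaluate_single_class_auroc_is_none():
    X = pd.DataFrame({"f0": [0.0, 1.0, 2.0]})
    y_train = np.array([0, 1, 1])
    model = fit_tree(X, y_train, max_depth=1, min_samples_leaf=1)
    metrics = evaluate(model, X, np.array([1, 1, 1]))
    assert metrics["auroc"] is None
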