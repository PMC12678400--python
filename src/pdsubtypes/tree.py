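"""From-scratch binary CART (Gini criterion) for early- vs late-onset labels.

The tree is the core of the subtyping method, so it is authored here rather
than delegated: leaves must expose their root-to-leaf condition paths, raw
and unique-patient class counts, and deterministic tie-breaking so that the
extracted subtype rules are reproducible. scikit-learn's tree appears in the
test suite only, as an independent oracle.

Split search at a node considers every feature and every midpoint between
consecutive distinct sorted values, and picks the split with the largest
decrease in count-weighted Gini impurity. Ties break to the lowest feature
index, then the smallest threshold. A split is accepted only if it strictly
decreases weighted impurity and leaves both children with at least
``min_samples_leaf`` rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score, precision_score, recall_score, roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .preprocess import LOPD, random_oversample

logger = logging.getLogger(__name__)

_EPS = 1e-12


def gini_impurity(class_counts) -> float:
    """Gini impurity ``1 - sum(p_c^2)`` of a two-class count vector.

    Ranges from 0 (pure node) to 0.5 (balanced binary node).
    """
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot compute impurity of an empty node")
    p = counts / total
    return float(1.0 - np.sum(p * p))


@dataclass
class TreeNode:
    """One node of a fitted tree; children are referenced by node id."""

    node_id: int
    depth: int
    class_counts: tuple[int, int]
    unique_counts: tuple[int, int]
    gini: float
    is_leaf: bool = True
    split_feature: int | None = None
    threshold: float | None = None
    left: int | None = None
    right: int | None = None
    leaf_label: int | None = None
    impurity_decrease: float = 0.0  # count-weighted, parent minus children

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "node_id", "depth", "class_counts", "unique_counts", "gini",
            "is_leaf", "split_feature", "threshold", "left", "right",
            "leaf_label", "impurity_decrease")}


class OnsetTreeClassifier(BaseEstimator, ClassifierMixin):
    """Binary CART over ordinal/numeric features, Gini split criterion.

    Parameters
    ----------
    max_depth : int
        Maximum root-to-leaf path length (root at depth 0).
    min_samples_leaf : int
        Minimum rows (including oversampling duplicates) in every leaf.

    Attributes
    ----------
    nodes_ : list of TreeNode
        Flat node table; node 0 is the root.
    feature_names_in_ : ndarray of str
        Column names when fitted on a DataFrame.
    feature_importances_ : ndarray
        Normalized total Gini-impurity reduction per feature; all-zero
        (and flagged via a log warning) if the tree has no splits.
    leaf_row_indices_ : dict of int -> ndarray
        Training row positions routed to each leaf.
    """

    def __init__(self, max_depth: int = 8, min_samples_leaf: int = 10):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf

    # ---------------------------------------------------------------- fit

    def fit(self, X, y, patient_ids=None) -> "OnsetTreeClassifier":
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(X.shape[1])], dtype=object)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("X must be a non-empty 2-D array")
        if len(X) != len(y):
            raise ValueError("X and y have different lengths")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute first")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("y must be binary 0/1")
        if patient_ids is None:
            patient_ids = np.arange(len(y))
        patient_ids = np.asarray(patient_ids)

        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        self.nodes_: list[TreeNode] = []
        self.leaf_row_indices_: dict[int, np.ndarray] = {}
        self._X, self._y, self._ids = X, y, patient_ids
        self._build(np.arange(len(y)), depth=0)
        del self._X, self._y, self._ids
        self.feature_importances_ = self._importances()
        return self

    def _counts(self, idx: np.ndarray) -> tuple[tuple[int, int], tuple[int, int]]:
        y = self._y[idx]
        counts = (int((y == 0).sum()), int((y == 1).sum()))
        ids = self._ids[idx]
        unique = (len(np.unique(ids[y == 0])), len(np.unique(ids[y == 1])))
        return counts, unique

    def _build(self, idx: np.ndarray, depth: int) -> int:
        counts, unique = self._counts(idx)
        node = TreeNode(node_id=len(self.nodes_), depth=depth,
                        class_counts=counts, unique_counts=unique,
                        gini=gini_impurity(counts))
        self.nodes_.append(node)
        node_id = node.node_id

        split = None
        if node.gini > 0 and depth < self.max_depth:
            split = self._best_split(idx, node.gini)
        if split is None:
            node.leaf_label = self._majority_label(counts)
            self.leaf_row_indices_[node_id] = idx
            return node_id

        feature, threshold, decrease = split
        node.is_leaf = False
        node.split_feature = int(feature)
        node.threshold = float(threshold)
        node.impurity_decrease = float(decrease)
        node.leaf_label = None
        mask = self._X[idx, feature] <= threshold
        node.left = self._build(idx[mask], depth + 1)
        node.right = self._build(idx[~mask], depth + 1)
        return node_id

    def _majority_label(self, counts: tuple[int, int]) -> int:
        if counts[1] == counts[0]:
            logger.info("leaf majority tie (%d, %d); labeling as late onset", *counts)
            return LOPD  # dataset-majority class breaks the tie
        return int(counts[1] > counts[0])

    def _best_split(self, idx: np.ndarray, parent_gini: float):
        """(feature, threshold, weighted impurity decrease) or None."""
        X, y = self._X[idx], self._y[idx]
        n = len(y)
        msl = self.min_samples_leaf
        if n < 2 * msl:
            return None
        best = None  # (decrease, feature, threshold)
        for f in range(X.shape[1]):
            v = X[:, f]
            order = np.argsort(v, kind="stable")
            vs, ys = v[order], y[order]
            # candidate split after position i (1-based left size)
            cum1 = np.cumsum(ys)
            sizes = np.arange(1, n)
            boundary = vs[1:] != vs[:-1]
            valid = boundary & (sizes >= msl) & (n - sizes >= msl)
            if not valid.any():
                continue
            left1 = cum1[:-1][valid].astype(float)
            nl = sizes[valid].astype(float)
            nr = n - nl
            right1 = cum1[-1] - left1
            gl = 1.0 - ((left1 / nl) ** 2 + ((nl - left1) / nl) ** 2)
            gr = 1.0 - ((right1 / nr) ** 2 + ((nr - right1) / nr) ** 2)
            decrease = parent_gini - (nl * gl + nr * gr) / n
            pos = np.flatnonzero(valid)
            k = int(np.argmax(decrease))
            # within a feature, argmax takes the first (= smallest threshold) max
            dmax = decrease[k]
            if dmax <= _EPS:
                continue
            i = pos[k]
            threshold = (vs[i] + vs[i + 1]) / 2.0
            if best is None or dmax > best[0] + _EPS:
                best = (dmax, f, threshold)
            # equal decrease on a later feature never replaces an earlier one
        if best is None:
            return None
        return best[1], best[2], best[0]

    # ---------------------------------------------------------- inference

    def _route(self, X: np.ndarray) -> np.ndarray:
        """Leaf node id for every row."""
        out = np.empty(len(X), dtype=int)
        for i, row in enumerate(X):
            node = self.nodes_[0]
            while not node.is_leaf:
                nxt = node.left if row[node.split_feature] <= node.threshold else node.right
                node = self.nodes_[nxt]
            out[i] = node.node_id
        return out

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names_in_)].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def apply(self, X) -> np.ndarray:
        check_is_fitted(self, "nodes_")
        return self._route(self._as_array(X))

    def predict(self, X) -> np.ndarray:
        leaves = self.apply(X)
        return np.array([self.nodes_[l].leaf_label for l in leaves], dtype=int)

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities from the leaf's training class fractions."""
        leaves = self.apply(X)
        proba = np.empty((len(leaves), 2))
        for i, l in enumerate(leaves):
            c0, c1 = self.nodes_[l].class_counts
            total = c0 + c1
            proba[i] = (c0 / total, c1 / total)
        return proba

    # --------------------------------------------------------- accessors

    @property
    def leaves_(self) -> list[TreeNode]:
        return [n for n in self.nodes_ if n.is_leaf]

    def decision_path_conditions(self, leaf_id: int) -> list[tuple[str, str, float]]:
        """Raw (feature, operator, threshold) conditions from root to a leaf."""
        target = self.nodes_[leaf_id]
        path: list[tuple[str, str, float]] = []
        node = self.nodes_[0]
        while not node.is_leaf:
            name = str(self.feature_names_in_[node.split_feature])
            left = self.nodes_[node.left]
            # does the target sit in the left subtree?
            if self._subtree_contains(node.left, leaf_id):
                path.append((name, "<=", node.threshold))
                node = left
            else:
                path.append((name, ">", node.threshold))
                node = self.nodes_[node.right]
        if node.node_id != leaf_id:
            raise ValueError(f"node {leaf_id} is not a leaf of this tree")
        return path

    def _subtree_contains(self, root_id: int, target_id: int) -> bool:
        stack = [root_id]
        while stack:
            nid = stack.pop()
            if nid == target_id:
                return True
            node = self.nodes_[nid]
            if not node.is_leaf:
                stack.extend((node.left, node.right))
        return False

    def _importances(self) -> np.ndarray:
        total_rows = sum(self.nodes_[0].class_counts)
        scores = np.zeros(self.n_features_in_)
        for node in self.nodes_:
            if not node.is_leaf:
                weight = sum(node.class_counts) / total_rows
                scores[node.split_feature] += weight * node.impurity_decrease
        if scores.sum() <= 0:
            logger.warning("tree has no splits; importances are all zero")
            return scores
        return scores / scores.sum()

    # ------------------------------------------------------ serialization

    def to_json(self, path: str | Path | None = None) -> str:
        check_is_fitted(self, "nodes_")
        payload = {
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "feature_names": list(map(str, self.feature_names_in_)),
            "nodes": [n.to_dict() for n in self.nodes_],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "OnsetTreeClassifier":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        model = cls(max_depth=payload["max_depth"],
                    min_samples_leaf=payload["min_samples_leaf"])
        model.feature_names_in_ = np.asarray(payload["feature_names"], dtype=object)
        model.n_features_in_ = len(model.feature_names_in_)
        model.classes_ = np.array([0, 1])
        model.nodes_ = []
        for spec in payload["nodes"]:
            spec = dict(spec)
            spec["class_counts"] = tuple(spec["class_counts"])
            spec["unique_counts"] = tuple(spec["unique_counts"])
            model.nodes_.append(TreeNode(**spec))
        model.leaf_row_indices_ = {}
        model.feature_importances_ = model._importances()
        return model


def fit_tree(X, y, max_depth: int = 8, min_samples_leaf: int = 10,
             patient_ids=None) -> OnsetTreeClassifier:
    """Thin functional wrapper over :class:`OnsetTreeClassifier`."""
    return OnsetTreeClassifier(max_depth, min_samples_leaf).fit(
        X, y, patient_ids=patient_ids)


@dataclass
class CVGrid:
    """Hyperparameter grid for 10-fold cross-validated model selection."""

    min_samples_leaf: tuple[int, ...] = (10, 12, 14, 16, 18, 20)
    max_depth: tuple[int, ...] = (4, 8, 12, 16, 20)
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m < 10 for m in self.min_samples_leaf):
            raise ValueError("min_samples_leaf candidates must be >= 10 so that "
                             "every candidate subtype stays analyzable")


def cross_validate_grid(frame: pd.DataFrame, features: list[str],
                        grid: CVGrid | None = None,
                        label_col: str = "onset_label",
                        oversample_before_cv: bool = False,
                        ) -> tuple[dict, pd.DataFrame]:
    """Select (max_depth, min_samples_leaf) by k-fold grid search.

    Folds partition *unique patients* (seeded). By default oversampling is
    applied to each fold's training portion only, so validation folds never
    contain oversampling duplicates; ``oversample_before_cv=True``
    reproduces the alternative reading in which the whole table is
    oversampled first and duplicates may leak into validation folds.

    Returns the best cell (ties to smaller depth, then larger
    min_samples_leaf) and a per-cell table of mean validation accuracy.
    """
    grid = grid or CVGrid()
    work = random_oversample(frame, seed=grid.seed, label_col=label_col) \
        if oversample_before_cv else frame
    unique_ids = np.sort(frame["patient_id"].unique())
    if grid.k > len(unique_ids):
        raise ValueError(f"k={grid.k} exceeds the {len(unique_ids)} unique patients")
    rng = np.random.default_rng(grid.seed)
    folds = np.array_split(rng.permutation(unique_ids), grid.k)

    records = []
    for depth in grid.max_depth:
        for msl in grid.min_samples_leaf:
            accs = []
            for fold_ids in folds:
                in_fold = work["patient_id"].isin(fold_ids)
                train_part = work[~in_fold]
                valid_part = work[in_fold]
                if not oversample_before_cv:
                    train_part = random_oversample(train_part, seed=grid.seed,
                                                   label_col=label_col)
                model = OnsetTreeClassifier(depth, msl).fit(
                    train_part[features], train_part[label_col],
                    patient_ids=train_part["patient_id"].to_numpy())
                pred = model.predict(valid_part[features])
                accs.append(accuracy_score(valid_part[label_col], pred))
            records.append({"max_depth": depth, "min_samples_leaf": msl,
                            "mean_accuracy": float(np.mean(accs))})
    table = pd.DataFrame.from_records(records)
    best_row = table.sort_values(
        ["mean_accuracy", "max_depth", "min_samples_leaf"],
        ascending=[False, True, False]).iloc[0]
    best = {"max_depth": int(best_row["max_depth"]),
            "min_samples_leaf": int(best_row["min_samples_leaf"]),
            "mean_accuracy": float(best_row["mean_accuracy"])}
    return best, table


def evaluate(model: OnsetTreeClassifier, X_test, y_test) -> dict:
    """Held-out accuracy, precision/recall for the late-onset class, AUROC.

    AUROC ranks patients by the leaf's late-onset training fraction
    (midrank tie convention). With a single-class test set the AUROC is
    undefined and reported as None.
    """
    y_test = np.asarray(y_test, dtype=int)
    pred = model.predict(X_test)
    scores = model.predict_proba(X_test)[:, 1]
    out = {
        "accuracy": float(accuracy_score(y_test, pred)),
        "precision": float(precision_score(y_test, pred, pos_label=LOPD,
                                           zero_division=0)),
        "recall": float(recall_score(y_test, pred, pos_label=LOPD,
                                     zero_division=0)),
    }
    out["auroc"] = float(roc_auc_score(y_test, scores)) \
        if len(np.unique(y_test)) == 2 else None
    return out


def gini_feature_importance(model: OnsetTreeClassifier) -> pd.Series:
    """Named, normalized Gini importance vector of a fitted tree."""
    check_is_fitted(model, "feature_importances_")
    return pd.Series(model.feature_importances_,
                     index=list(model.feature_names_in_)).sort_values(ascending=False)
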