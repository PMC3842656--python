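"""CART classification of choroidal imaging types Z1/Z2/Z3.

The three imaging types — shadow layouts under retinal lesions (Z1), global
brightness reduction (Z2) and uniform scar tissue (Z3) — are separated by a
classification tree over the 20 texture features.  The tree is grown by
exhaustive axis-aligned threshold search maximizing the Gini impurity
decrease, with no minimum node size, and pruned by cost-complexity
(weakest-link) pruning with the pruning level selected by the one-standard-
error rule on stratified cross-validation: the smallest tree whose CV
misclassification cost is within one standard error of the minimum.

Everything is deterministic: split ties break towards the lowest feature
index, then the lowest threshold; candidate thresholds are midpoints between
consecutive distinct sorted feature values; CV fold assignment is seeded.

The module also provides one-vs-rest SPC/TPR/ACC evaluation, per-feature ROC
curves, exhaustive feature-subset search, and a statsmodels-style
``ChoroidTypeModel`` / ``ChoroidTypeResults`` pair wrapping the tree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES, N_FEATURES

__all__ = [
    "CLASS_LABELS",
    "CARTree",
    "PruningReport",
    "EvalReport",
    "ROCCurve",
    "SubsetSearchResult",
    "train_cart",
    "prune_1se",
    "evaluate",
    "subset_search",
    "plan_tree_count",
    "per_feature_roc",
    "ChoroidTypeModel",
    "ChoroidTypeResults",
]

CLASS_LABELS: tuple[str, ...] = ("Z1", "Z2", "Z3")


# ---------------------------------------------------------------------------
# tree representation and growth
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    counts: np.ndarray            # class histogram of the node's samples
    feature: int = -1             # split feature (global column index), -1 = leaf
    threshold: float = np.nan     # split: x[feature] <= threshold goes left
    left: int = -1
    right: int = -1

    @property
    def is_leaf(self) -> bool:
        return self.left < 0

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def prediction(self) -> int:
        # tie on counts breaks to the lowest class index
        return int(np.argmax(self.counts))

    @property
    def resub_errors(self) -> int:
        return self.n - int(self.counts.max())


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.dot(p, p))


def _best_split(x_col: np.ndarray, y_enc: np.ndarray, n_classes: int
                ) -> tuple[float, float] | None:
    """Best (threshold, weighted child impurity) for one feature, or None.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; the returned impurity is (n_l*G_l + n_r*G_r)/n.  Among equal
    impurities the lowest threshold wins.
    """
    order = np.argsort(x_col, kind="stable")
    xs, ys = x_col[order], y_enc[order]
    n = xs.size
    boundaries = np.flatnonzero(np.diff(xs) > 0) + 1  # split positions
    if boundaries.size == 0:
        return None
    onehot = np.zeros((n, n_classes), dtype=np.float64)
    onehot[np.arange(n), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)
    left = cum[boundaries - 1]                       # counts with x <= midpoint
    right = cum[-1][None, :] - left
    n_l = left.sum(axis=1)
    n_r = n - n_l
    g_l = 1.0 - np.sum((left / n_l[:, None]) ** 2, axis=1)
    g_r = 1.0 - np.sum((right / n_r[:, None]) ** 2, axis=1)
    weighted = (n_l * g_l + n_r * g_r) / n
    # lowest threshold among ties; the tolerance absorbs float noise between
    # mathematically equal scores reached by different summation orders
    best = int(np.flatnonzero(weighted <= weighted.min() + 1e-12)[0])
    thr = 0.5 * (xs[boundaries[best] - 1] + xs[boundaries[best]])
    return float(thr), float(weighted[best])


class CARTree:
    """A binary classification tree grown by exhaustive Gini search.

    Parameters
    ----------
    classes : sequence of labels defining the class index order.
    feature_indices : global column indices the tree may split on (the
        feature-subset mask); thresholds are stored against global indices.
    """

    def __init__(self, classes: tuple[str, ...],
                 feature_indices: np.ndarray,
                 n_features_total: int):
        self.classes_ = tuple(classes)
        self.feature_indices = np.asarray(feature_indices, dtype=np.intp)
        self.n_features_total = int(n_features_total)
        self.nodes: list[_Node] = []

    # -- growth -----------------------------------------------------------

    def _grow(self, X: np.ndarray, y_enc: np.ndarray) -> int:
        counts = np.bincount(y_enc, minlength=len(self.classes_)).astype(np.float64)
        node_id = len(self.nodes)
        node = _Node(counts=counts)
        self.nodes.append(node)
        if _gini(counts) == 0.0:
            return node_id
        parent_imp = _gini(counts)
        best: tuple[float, float, int] | None = None  # (impurity, threshold, feature)
        for f in self.feature_indices:                # ascending = tie-break order
            found = _best_split(X[:, f], y_enc, len(self.classes_))
            if found is None:
                continue
            thr, imp = found
            if best is None or imp < best[0] - 1e-12:
                best = (imp, thr, int(f))
        if best is None or best[0] >= parent_imp - 1e-12:
            return node_id
        imp, thr, f = best
        go_left = X[:, f] <= thr
        node.feature = f
        node.threshold = thr
        node.left = self._grow(X[go_left], y_enc[go_left])
        node.right = self._grow(X[~go_left], y_enc[~go_left])
        return node_id

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CARTree":
        X = np.asarray(X, dtype=np.float64)
        y_enc = _encode(y, self.classes_)
        self.nodes = []
        self._grow(X, y_enc)
        return self

    # -- prediction -------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        out = np.empty(X.shape[0], dtype=object)
        for i, row in enumerate(X):
            node = self.nodes[0]
            while not node.is_leaf:
                node = self.nodes[node.left if row[node.feature] <= node.threshold
                                  else node.right]
            out[i] = self.classes_[node.prediction]
        return out

    # -- structure queries ------------------------------------------------

    def _reachable(self) -> list[int]:
        """Node ids reachable from the root (pruning can orphan subtrees)."""
        if not self.nodes:
            return []
        out, stack = [], [0]
        while stack:
            i = stack.pop()
            out.append(i)
            nd = self.nodes[i]
            if not nd.is_leaf:
                stack += [nd.left, nd.right]
        return out

    def n_leaves(self) -> int:
        return sum(1 for i in self._reachable() if self.nodes[i].is_leaf)

    def depth(self) -> int:
        def d(i: int) -> int:
            nd = self.nodes[i]
            return 0 if nd.is_leaf else 1 + max(d(nd.left), d(nd.right))
        return d(0) if self.nodes else 0

    def features_used(self) -> list[int]:
        return sorted({self.nodes[i].feature for i in self._reachable()
                       if not self.nodes[i].is_leaf})

    # -- cost-complexity pruning ------------------------------------------

    def _collapse(self, node_id: int) -> None:
        nd = self.nodes[node_id]
        nd.feature, nd.threshold, nd.left, nd.right = -1, np.nan, -1, -1

    def _subtree_stats(self, node_id: int) -> tuple[float, int]:
        """(sum of leaf resubstitution errors, number of leaves) under node_id."""
        nd = self.nodes[node_id]
        if nd.is_leaf:
            return float(nd.resub_errors), 1
        e_l, l_l = self._subtree_stats(nd.left)
        e_r, l_r = self._subtree_stats(nd.right)
        return e_l + e_r, l_l + l_r

    def copy(self) -> "CARTree":
        new = CARTree(self.classes_, self.feature_indices, self.n_features_total)
        new.nodes = [_Node(counts=nd.counts.copy(), feature=nd.feature,
                           threshold=nd.threshold, left=nd.left, right=nd.right)
                     for nd in self.nodes]
        return new

    def pruning_path(self) -> tuple[list[float], list["CARTree"]]:
        """Weakest-link pruning sequence.

        Returns (alphas, trees): alphas[0] = 0 with the unpruned tree, then
        strictly increasing complexity parameters, ending at the root leaf.
        """
        n_total = self.nodes[0].n if self.nodes else 0
        current = self.copy()
        alphas = [0.0]
        trees = [current.copy()]
        while not current.nodes[0].is_leaf:
            gs: dict[int, float] = {}

            def visit(i: int) -> None:
                nd = current.nodes[i]
                if nd.is_leaf:
                    return
                sub_err, n_leaves = current._subtree_stats(i)
                gs[i] = (nd.resub_errors - sub_err) / (n_leaves - 1) / n_total
                visit(nd.left)
                visit(nd.right)

            visit(0)
            g_min = min(gs.values())
            for i, g in gs.items():
                if g <= g_min + 1e-12 and not current.nodes[i].is_leaf:
                    current._collapse(i)
            alphas.append(max(g_min, alphas[-1]))
            trees.append(current.copy())
        return alphas, trees

    @staticmethod
    def _prune_to_alpha(alphas: list[float], trees: list["CARTree"],
                        alpha: float) -> "CARTree":
        """Smallest tree in the sequence whose alpha threshold is <= alpha."""
        k = 0
        for i, a in enumerate(alphas):
            if a <= alpha + 1e-12:
                k = i
        return trees[k]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes_),
            "feature_indices": self.feature_indices.tolist(),
            "n_features_total": self.n_features_total,
            "nodes": [
                {"counts": nd.counts.tolist(), "feature": int(nd.feature),
                 "threshold": None if math.isnan(nd.threshold) else float(nd.threshold),
                 "left": int(nd.left), "right": int(nd.right)}
                for nd in self.nodes
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CARTree":
        tree = cls(tuple(data["classes"]), np.asarray(data["feature_indices"]),
                   int(data["n_features_total"]))
        tree.nodes = [
            _Node(counts=np.asarray(d["counts"], dtype=np.float64),
                  feature=int(d["feature"]),
                  threshold=np.nan if d["threshold"] is None else float(d["threshold"]),
                  left=int(d["left"]), right=int(d["right"]))
            for d in data["nodes"]
        ]
        return tree


def _encode(y, classes: tuple[str, ...]) -> np.ndarray:
    y = np.asarray(y)
    lut = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lut[v] for v in y], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in classes {classes}") from None


def train_cart(X: np.ndarray, y: np.ndarray,
               subset_mask: np.ndarray | None = None,
               classes: tuple[str, ...] | None = None) -> CARTree:
    """Grow an unrestricted CART on (X, y) over the masked feature subset.

    A single-class training set yields a degenerate single-leaf tree; an
    empty feature subset is an error.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if classes is None:
        classes = tuple(sorted(np.unique(y)))
    if subset_mask is None:
        feature_indices = np.arange(X.shape[1])
    else:
        subset_mask = np.asarray(subset_mask, dtype=bool)
        feature_indices = np.flatnonzero(subset_mask)
        if feature_indices.size == 0:
            raise ValueError("feature subset mask selects no features")
    return CARTree(classes, feature_indices, X.shape[1]).fit(X, y)


# ---------------------------------------------------------------------------
# pruning with the 1-SE rule
# ---------------------------------------------------------------------------

@dataclass
class PruningReport:
    """Cross-validated cost per pruning level and the 1-SE selection."""

    alphas: list[float]
    n_leaves: list[int]
    cv_cost: np.ndarray
    cv_se: np.ndarray
    resub_cost: np.ndarray
    best_level: int
    threshold: float            # min CV cost + 1 SE

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "level": np.arange(len(self.alphas)),
            "alpha": self.alphas,
            "n_leaves": self.n_leaves,
            "cv_cost": self.cv_cost,
            "cv_se": self.cv_se,
            "resub_cost": self.resub_cost,
        })


def prune_1se(model: CARTree, X: np.ndarray, y: np.ndarray,
              k_folds: int = 10, seed: int = 0
              ) -> tuple[CARTree, PruningReport]:
    """Cost-complexity pruning with level selection by the 1-SE rule.

    The pruning sequence of ``model`` defines the candidate levels (level 0 =
    unpruned).  Each level's misclassification cost is estimated by
    stratified k-fold cross-validation: per fold, a tree grown on the
    training part is pruned at the geometric-mean alpha of the level and
    scored on the held-out part.  The selected level is the smallest tree
    (largest level) whose CV cost is at most min(CV cost) + one binomial
    standard error of the minimum.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n = y.size
    alphas, trees = model.pruning_path()
    n_levels = len(alphas)
    # geometric-mean alphas between consecutive levels index the CV trees
    betas = [math.sqrt(alphas[k] * alphas[k + 1]) if k + 1 < n_levels else np.inf
             for k in range(n_levels)]

    _, class_counts = np.unique(y, return_counts=True)
    max_folds = int(class_counts.min())
    if k_folds > max_folds:
        warnings.warn(f"reducing CV folds from {k_folds} to {max_folds} "
                      "(smallest class size)", stacklevel=2)
        k_folds = max(2, max_folds)
    errors = np.zeros(n_levels)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        fold_tree = train_cart(X[train_idx], y[train_idx],
                               subset_mask=_indices_to_mask(model.feature_indices,
                                                            model.n_features_total),
                               classes=model.classes_)
        f_alphas, f_trees = fold_tree.pruning_path()
        for k, beta in enumerate(betas):
            sub = CARTree._prune_to_alpha(f_alphas, f_trees, beta)
            errors[k] += np.sum(sub.predict(X[test_idx]) != y[test_idx])
    cv_cost = errors / n
    cv_se = np.sqrt(cv_cost * (1.0 - cv_cost) / n)
    resub = np.array([np.mean(t.predict(X) != y) for t in trees])
    k_min = int(np.flatnonzero(cv_cost == cv_cost.min())[-1])
    threshold = float(cv_cost[k_min] + cv_se[k_min])
    best = int(np.flatnonzero(cv_cost <= threshold + 1e-12)[-1])
    report = PruningReport(alphas=alphas, n_leaves=[t.n_leaves() for t in trees],
                           cv_cost=cv_cost, cv_se=cv_se, resub_cost=resub,
                           best_level=best, threshold=threshold)
    return trees[best], report


def _indices_to_mask(indices: np.ndarray, n_total: int) -> np.ndarray:
    mask = np.zeros(n_total, dtype=bool)
    mask[indices] = True
    return mask


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """One-vs-rest confusion statistics per class.

    SPC = TN/(FP+TN), TPR = TP/(TP+FN), ACC = (TP+TN)/(TP+TN+FP+FN).
    """

    classes: tuple[str, ...]
    confusion: np.ndarray                  # rows = true, cols = predicted
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = self.confusion.sum()
        for i, c in enumerate(self.classes):
            tp = self.confusion[i, i]
            fn = self.confusion[i].sum() - tp
            fp = self.confusion[:, i].sum() - tp
            tn = total - tp - fn - fp
            self.per_class[c] = {
                "TP": float(tp), "TN": float(tn), "FP": float(fp), "FN": float(fn),
                "TPR": tp / (tp + fn) if tp + fn else 0.0,
                "SPC": tn / (fp + tn) if fp + tn else 0.0,
                "ACC": (tp + tn) / total if total else 0.0,
            }

    @property
    def overall_accuracy(self) -> float:
        total = self.confusion.sum()
        return float(np.trace(self.confusion) / total) if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_class).T[["TP", "TN", "FP", "FN",
                                               "TPR", "SPC", "ACC"]]


def evaluate(model: CARTree, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """Predict every row and compute the per-class one-vs-rest report."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("evaluation set is empty")
    _encode(y, model.classes_)   # validates labels
    pred = model.predict(X)
    k = len(model.classes_)
    lut = {c: i for i, c in enumerate(model.classes_)}
    confusion = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y, pred):
        confusion[lut[t], lut[p]] += 1
    return EvalReport(classes=model.classes_, confusion=confusion)


# ---------------------------------------------------------------------------
# per-feature ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    feature: int
    class_label: str
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    orientation: str       # ">=" or "<=": direction that predicts positive


def _roc_one_orientation(values: np.ndarray, positive: np.ndarray,
                         orientation: str) -> tuple[np.ndarray, np.ndarray, float]:
    thresholds = np.unique(values)
    mids = (thresholds[:-1] + thresholds[1:]) / 2.0
    cuts = np.concatenate(([-np.inf], mids, [np.inf]))
    n_pos = positive.sum()
    n_neg = positive.size - n_pos
    pts = []
    for t in cuts:
        pred = values >= t if orientation == ">=" else values <= t
        tp = np.sum(pred & positive)
        fp = np.sum(pred & ~positive)
        pts.append((fp / n_neg, tp / n_pos))
    pts = sorted(set(pts))
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def per_feature_roc(X: np.ndarray, y: np.ndarray,
                    classes: tuple[str, ...] | None = None,
                    feature_names: tuple[str, ...] | None = None
                    ) -> dict[tuple[int, str], ROCCurve]:
    """One-vs-rest ROC of every single feature used as a threshold classifier.

    Both decision orientations are swept; the better-AUC one is reported,
    since feature polarity depends on the class.  A constant feature yields
    the degenerate diagonal (AUC 0.5) with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y)
    if classes is None:
        classes = tuple(sorted(np.unique(y)))
    curves: dict[tuple[int, str], ROCCurve] = {}
    for c in classes:
        positive = y == c
        if positive.all() or not positive.any():
            raise ValueError(f"class {c!r} needs at least one positive and one negative")
        for f in range(X.shape[1]):
            values = X[:, f]
            if np.all(values == values[0]):
                warnings.warn(f"feature {f} is constant: degenerate ROC", stacklevel=2)
                curves[(f, c)] = ROCCurve(f, c, np.array([0.0, 1.0]),
                                          np.array([0.0, 1.0]), 0.5, ">=")
                continue
            best = None
            for orientation in (">=", "<="):
                fpr, tpr, auc = _roc_one_orientation(values, positive, orientation)
                if best is None or auc > best.auc:
                    best = ROCCurve(f, c, fpr, tpr, auc, orientation)
            curves[(f, c)] = best
    return curves


# ---------------------------------------------------------------------------
# feature-subset search
# ---------------------------------------------------------------------------

def plan_tree_count(n_features: int) -> dict[str, int]:
    """Planned tree counts for an exhaustive search over ``n_features`` features.

    Every bitmask over the feature pool is a subset (2^k of them, including
    the degenerate empty one), each trained as a full and as a pruned tree.
    """
    if n_features > N_FEATURES:
        raise ValueError(f"feature pool cannot exceed {N_FEATURES} features")
    n_subsets = 2 ** n_features
    return {"subsets": n_subsets, "full_trees": n_subsets,
            "pruned_trees": n_subsets, "total_trees": 2 * n_subsets}


class _MajorityTree:
    """Degenerate classifier for the empty feature subset: the training prior."""

    def __init__(self, y: np.ndarray, classes: tuple[str, ...]):
        self.classes_ = classes
        counts = np.bincount(_encode(y, classes), minlength=len(classes))
        self._label = classes[int(np.argmax(counts))]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return np.array([self._label] * X.shape[0], dtype=object)

    def n_leaves(self) -> int:
        return 1


@dataclass
class SubsetSearchResult:
    """Outcome of the feature-subset enumeration.

    ``table`` has one row per subset with per-class ACC for the full and the
    pruned tree on the test split.  ``top3`` reproduces the best-3-per-class
    table layout (binary feature-membership rows plus the ACC row);
    ``feature_frequencies`` gives, for the top-ranked subsets, how often each
    feature occurs.
    """

    feature_pool: list[int]
    table: pd.DataFrame
    classes: tuple[str, ...]
    n_trees_trained: int

    def top3(self, class_label: str, kind: str = "pruned") -> pd.DataFrame:
        col = f"acc_{kind}_{class_label}"
        best = self.table.sort_values([col, "subset"],
                                      ascending=[False, True]).head(3)
        rows = {}
        for rank, (_, row) in enumerate(best.iterrows(), start=1):
            member = [1 if f in row["features"] else 0 for f in range(N_FEATURES)]
            rows[rank] = member + [row[col]]
        index = [FEATURE_NAMES[f] for f in range(N_FEATURES)] + ["ACC"]
        return pd.DataFrame(rows, index=index)

    def feature_frequencies(self, kind: str = "pruned", top: int = 1000) -> pd.Series:
        ranked = self.table.sort_values([f"acc_{kind}_overall", "subset"],
                                        ascending=[False, True]).head(top)
        counts = np.zeros(N_FEATURES)
        for feats in ranked["features"]:
            for f in feats:
                counts[f] += 1
        return pd.Series(counts / max(len(ranked), 1), index=list(FEATURE_NAMES))


def subset_search(X: np.ndarray, y: np.ndarray, split: np.ndarray,
                  feature_pool: list[int] | None = None,
                  masks: list[int] | None = None,
                  k_folds: int = 10, seed: int = 0) -> SubsetSearchResult:
    """Train a full and a pruned tree for every feature subset and tabulate.

    Subsets come either from exhaustive enumeration of ``feature_pool``
    (all 2^k bitmasks; the empty mask is scored as the training-prior
    majority classifier) or from an explicit ``masks`` bitmask list over the
    pool.  Trees are trained on the learning split and evaluated on the test
    split.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    split = np.asarray(split)
    if feature_pool is None:
        feature_pool = list(range(N_FEATURES))
    if len(feature_pool) > N_FEATURES:
        raise ValueError(f"feature pool cannot exceed {N_FEATURES} features")
    learn = split == "learning"
    test = split == "test"
    if not learn.any() or not test.any():
        raise ValueError("need non-empty learning and test splits")
    classes = tuple(sorted(np.unique(y)))
    if masks is None:
        masks = list(range(2 ** len(feature_pool)))
    rows = []
    n_trees = 0
    for bits in masks:
        feats = tuple(feature_pool[j] for j in range(len(feature_pool))
                      if bits >> j & 1)
        if feats:
            mask = np.zeros(X.shape[1], dtype=bool)
            mask[list(feats)] = True
            full = train_cart(X[learn], y[learn], subset_mask=mask, classes=classes)
            pruned, _ = prune_1se(full, X[learn], y[learn],
                                  k_folds=k_folds, seed=seed)
        else:
            full = _MajorityTree(y[learn], classes)
            pruned = full
        n_trees += 2
        row: dict = {"subset": bits, "features": feats, "n_features": len(feats)}
        for kind, model in (("full", full), ("pruned", pruned)):
            rep = _evaluate_any(model, X[test], y[test], classes)
            row[f"acc_{kind}_overall"] = rep.overall_accuracy
            for c in classes:
                row[f"acc_{kind}_{c}"] = rep.per_class[c]["ACC"]
            row[f"n_leaves_{kind}"] = model.n_leaves()
        rows.append(row)
    return SubsetSearchResult(feature_pool=list(feature_pool),
                              table=pd.DataFrame(rows), classes=classes,
                              n_trees_trained=n_trees)


def _evaluate_any(model, X, y, classes) -> EvalReport:
    pred = model.predict(X)
    lut = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    confusion = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y, pred):
        confusion[lut[t], lut[p]] += 1
    return EvalReport(classes=classes, confusion=confusion)


# ---------------------------------------------------------------------------
# statsmodels-style model / results wrappers
# ---------------------------------------------------------------------------

class ChoroidTypeModel:
    """Choroidal-imaging-type classifier built from a feature table.

    Wraps the CART machinery in a model object: construct from arrays or a
    DataFrame with ``w1..w20`` columns and a label column, then ``fit()`` to
    obtain a :class:`ChoroidTypeResults`.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 feature_names: tuple[str, ...] | None = None,
                 subset_mask: np.ndarray | None = None):
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y)
        self.feature_names = (tuple(feature_names) if feature_names is not None
                              else tuple(f"x{i}" for i in range(self.X.shape[1])))
        self.subset_mask = subset_mask
        self.classes_ = tuple(sorted(np.unique(self.y)))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       feature_cols: tuple[str, ...] = FEATURE_NAMES,
                       subset_mask: np.ndarray | None = None) -> "ChoroidTypeModel":
        return cls(df[list(feature_cols)].to_numpy(), df[label_col].to_numpy(),
                   feature_names=feature_cols, subset_mask=subset_mask)

    def fit(self, prune: bool = True, k_folds: int = 10, seed: int = 0
            ) -> "ChoroidTypeResults":
        tree = train_cart(self.X, self.y, subset_mask=self.subset_mask,
                          classes=self.classes_)
        report = None
        if prune:
            tree, report = prune_1se(tree, self.X, self.y,
                                     k_folds=k_folds, seed=seed)
        return ChoroidTypeResults(self, tree, report)


class ChoroidTypeResults:
    """Fitted tree with its pruning diagnostics and evaluation helpers."""

    def __init__(self, model: ChoroidTypeModel, tree: CARTree,
                 pruning: PruningReport | None):
        self.model = model
        self.tree = tree
        self.pruning = pruning

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.tree.predict(X)

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> EvalReport:
        return evaluate(self.tree, X, y)

    def summary(self, X_eval: np.ndarray | None = None,
                y_eval: np.ndarray | None = None) -> str:
        lines = ["Choroidal imaging-type classification tree",
                 "=" * 46,
                 f"classes:        {', '.join(self.tree.classes_)}",
                 f"n training:     {self.model.y.size}",
                 f"leaves / depth: {self.tree.n_leaves()} / {self.tree.depth()}",
                 "features used:  " + (", ".join(
                     self.model.feature_names[f] for f in self.tree.features_used())
                     or "(none: majority leaf)")]
        if self.pruning is not None:
            lines += [f"pruning level:  {self.pruning.best_level} "
                      f"(CV cost {self.pruning.cv_cost[self.pruning.best_level]:.3f}"
                      f" <= min+1SE {self.pruning.threshold:.3f})"]
        rep = (self.evaluate(X_eval, y_eval) if X_eval is not None
               else self.evaluate(self.model.X, self.model.y))
        tag = "held-out" if X_eval is not None else "training"
        lines += ["", f"per-class metrics ({tag}):",
                  rep.to_frame().round(3).to_string()]
        return "\n".join(lines)
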