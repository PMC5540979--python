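"""From-scratch AdaBoost over depth-limited decision trees.

The ensemble follows the classic discrete AdaBoost recipe for binary
labels ``y in {-1, +1}``: sample weights start uniform, each round
trains a weight-aware tree, the weighted misclassification rate ``e_m``
sets the learner weight ``alpha_m = 0.5 ln((1 - e_m) / e_m)``, weights
of misclassified samples are boosted and renormalized, and the final
decision is ``sign(sum lr * alpha_m * D_m(x))``.

Sample weights enter the trees through the split criterion (weighted
Gini impurity), not through resampling, so training is fully
deterministic; ties in the split search are broken toward the smallest
threshold, then the lowest feature index.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "DecisionTreeWeakLearner",
    "AdaBoostBinaryClassifier",
    "train_weak_learner",
    "adaboost_fit",
    "adaboost_score",
    "adaboost_predict",
    "make_baseline",
    "save_model",
    "load_model",
]

_EPS_ERROR = 1e-10  # clamp for a perfect round's error rate
_MIN_GAIN = 1e-12


def _weighted_gini_split(values: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Best threshold for one feature under weighted Gini; None if no split.

    Returns ``(score, threshold)`` where ``score`` is the summed
    child-weighted impurity (lower is better).  Candidate thresholds
    are midpoints between consecutive distinct sorted values; the
    smallest optimal threshold wins.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    wy = w[order]
    is_pos = (y[order] == 1).astype(float)

    cut = np.nonzero(v[:-1] < v[1:])[0]  # split after these positions
    if cut.size == 0:
        return None

    cw = np.cumsum(wy)
    cw_pos = np.cumsum(wy * is_pos)
    W = cw[-1]
    W_pos = cw_pos[-1]

    wl = cw[cut]
    wl_pos = cw_pos[cut]
    wl_neg = wl - wl_pos
    wr = W - wl
    wr_pos = W_pos - wl_pos
    wr_neg = wr - wr_pos

    # child_weight * gini = child_weight - (pos^2 + neg^2) / child_weight
    with np.errstate(invalid="ignore", divide="ignore"):
        score = (
            wl
            - np.where(wl > 0, (wl_pos**2 + wl_neg**2) / wl, 0.0)
            + wr
            - np.where(wr > 0, (wr_pos**2 + wr_neg**2) / wr, 0.0)
        )
    best = int(np.argmin(score))  # first occurrence = smallest threshold
    threshold = 0.5 * (v[cut[best]] + v[cut[best] + 1])
    return float(score[best]), float(threshold)


def _leaf_label(y: np.ndarray, w: np.ndarray) -> int:
    """Sign of the weighted class majority; exact ties predict +1."""
    return 1 if float(np.sum(w * y)) >= 0 else -1


def _build_tree(X, y, w, depth, max_depth):
    label = _leaf_label(y, w)
    if depth >= max_depth or y.shape[0] < 2 or np.all(y == y[0]):
        return {"leaf": label}

    W = w.sum()
    w_pos = w[y == 1].sum()
    parent = W - (w_pos**2 + (W - w_pos) ** 2) / W if W > 0 else 0.0

    best_score, best_feature, best_threshold = None, None, None
    for f in range(X.shape[1]):  # ascending index breaks cross-feature ties
        res = _weighted_gini_split(X[:, f], y, w)
        if res is None:
            continue
        score, threshold = res
        if best_score is None or score < best_score:
            best_score, best_feature, best_threshold = score, f, threshold

    # zero-gain splits are allowed (as in CART): a split that does not
    # reduce impurity at this level can still enable a useful one below
    if best_score is None or parent <= _MIN_GAIN:
        return {"leaf": label}

    mask = X[:, best_feature] <= best_threshold
    return {
        "feature": best_feature,
        "threshold": best_threshold,
        "left": _build_tree(X[mask], y[mask], w[mask], depth + 1, max_depth),
        "right": _build_tree(X[~mask], y[~mask], w[~mask], depth + 1, max_depth),
    }


def _tree_predict(node, X, out, idx):
    if "leaf" in node:
        out[idx] = node["leaf"]
        return
    mask = X[idx, node["feature"]] <= node["threshold"]
    _tree_predict(node["left"], X, out, idx[mask])
    _tree_predict(node["right"], X, out, idx[~mask])


def _tree_depth(node) -> int:
    if "leaf" in node:
        return 0
    return 1 + max(_tree_depth(node["left"]), _tree_depth(node["right"]))


class DecisionTreeWeakLearner:
    """Axis-aligned binary decision tree grown under sample weights.

    Greedy recursive partitioning minimizing weighted Gini impurity;
    every leaf predicts a label in ``{-1, +1}``.
    """

    def __init__(self, max_depth: int = 1) -> None:
        if max_depth < 0:
            raise ValueError("max_depth must be non-negative")
        self.max_depth = max_depth
        self.root_ = None
        self.n_features_ = None

    def fit(self, X, y, sample_weight=None) -> "DecisionTreeWeakLearner":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isin(y, (-1, 1))):
            raise ValueError("labels must be in {-1, +1}")
        if sample_weight is None:
            sample_weight = np.full(y.shape[0], 1.0 / y.shape[0])
        w = np.asarray(sample_weight, dtype=float)
        if np.any(w < 0):
            raise ValueError("sample weights must be non-negative")
        if len(np.unique(y)) < 2:
            warnings.warn("single class in y; depth-0 learner", stacklevel=2)
        self.root_ = _build_tree(X, y, w, 0, self.max_depth)
        self.n_features_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if self.root_ is None:
            raise RuntimeError("tree is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"X has {X.shape[1]} features, tree was grown on {self.n_features_}"
            )
        out = np.empty(X.shape[0], dtype=int)
        _tree_predict(self.root_, X, out, np.arange(X.shape[0]))
        return out

    @property
    def depth(self) -> int:
        return _tree_depth(self.root_)


def train_weak_learner(X, y, w, max_depth: int) -> DecisionTreeWeakLearner:
    """Fit a weight-aware depth-limited tree (functional wrapper)."""
    return DecisionTreeWeakLearner(max_depth=max_depth).fit(X, y, sample_weight=w)


class AdaBoostBinaryClassifier(ClassifierMixin, BaseEstimator):
    """Discrete AdaBoost with depth-limited decision trees as base learners.

    Parameters
    ----------
    n_estimators : int, default 500
        Boosting rounds ``M`` (an early stop may retain fewer).
    learning_rate : float, default 1.0
        Shrinkage ``lr`` applied when accumulating the ensemble score
        ``f_m(x) = f_{m-1}(x) + lr * alpha_m * D_m(x)``; the sample
        reweighting itself uses the unshrunk ``alpha_m``.
    max_depth : int, default 9
        Depth limit of every base tree.
    random_state : int or None
        Kept for the estimator contract; training is deterministic.

    Attributes
    ----------
    estimators_ : list of fitted trees (the retained rounds).
    alphas_ : ndarray of learner weights, all positive.
    estimator_errors_ : ndarray of the weighted error ``e_m`` per round.
    classes_ : the two class labels; ``classes_[1]`` maps to +1.

    Degenerate rounds: ``e_m = 0`` clamps to 1e-10, retains the
    (perfect) learner and stops; ``e_m >= 0.5`` discards the learner
    and stops with a warning.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        learning_rate: float = 1.0,
        max_depth: int = 9,
        random_state: int | None = None,
    ) -> None:
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y, track_weights: bool = False):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.shape[0] > 2:
            raise ValueError("binary classification only")
        if self.classes_.shape[0] == 1:
            # degenerate but trainable: a single depth-0 perfect learner
            self.classes_ = np.array([self.classes_[0], self.classes_[0]])
        yy = np.where(y == self.classes_[1], 1, -1)

        N = X.shape[0]
        w = np.full(N, 1.0 / N)
        self.estimators_: list[DecisionTreeWeakLearner] = []
        alphas: list[float] = []
        errors: list[float] = []
        self.weight_history_ = [] if track_weights else None

        for _ in range(self.n_estimators):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tree = train_weak_learner(X, yy, w, self.max_depth)
            pred = tree.predict(X)
            e = float(np.sum(w[pred != yy]))
            if e >= 0.5:
                warnings.warn(
                    f"weak learner error {e:.3f} >= 0.5; discarding and stopping",
                    stacklevel=2,
                )
                break
            stop = e == 0.0
            e_clamped = max(e, _EPS_ERROR)
            alpha = 0.5 * np.log((1.0 - e_clamped) / e_clamped)
            self.estimators_.append(tree)
            alphas.append(alpha)
            errors.append(e)
            w = w * np.exp(-alpha * yy * pred)
            w /= w.sum()
            if track_weights:
                self.weight_history_.append(w.copy())
            if stop:
                break

        if not self.estimators_:
            raise RuntimeError("no weak learner achieved error below 0.5")
        self.alphas_ = np.asarray(alphas)
        self.estimator_errors_ = np.asarray(errors)
        self.n_iter_ = len(self.estimators_)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Continuous margin ``f_M(x) = sum lr * alpha_m * D_m(x)``."""
        check_is_fitted(self, "alphas_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        score = np.zeros(X.shape[0])
        for alpha, tree in zip(self.alphas_, self.estimators_):
            score += self.learning_rate * alpha * tree.predict(X)
        return score

    def predict(self, X) -> np.ndarray:
        """Sign decision; a margin of exactly 0 predicts ``classes_[1]`` (+1)."""
        score = self.decision_function(X)
        return self.classes_[(score >= 0).astype(int)]

    def staged_training_error(self, X, y) -> np.ndarray:
        """Training error of the partial ensemble after each round."""
        check_is_fitted(self, "alphas_")
        X = check_array(X)
        yy = np.where(np.asarray(y) == self.classes_[1], 1, -1)
        score = np.zeros(X.shape[0])
        errs = np.empty(self.n_iter_)
        for m, (alpha, tree) in enumerate(zip(self.alphas_, self.estimators_)):
            score += self.learning_rate * alpha * tree.predict(X)
            pred = np.where(score >= 0, 1, -1)
            errs[m] = float(np.mean(pred != yy))
        return errs


# -- functional wrappers ----------------------------------------------------

def adaboost_fit(
    X, y, M: int = 500, lr: float = 1.0, max_depth: int = 9, seed: int | None = None
) -> AdaBoostBinaryClassifier:
    return AdaBoostBinaryClassifier(
        n_estimators=M, learning_rate=lr, max_depth=max_depth, random_state=seed
    ).fit(X, y)


def adaboost_score(model: AdaBoostBinaryClassifier, X) -> np.ndarray:
    return model.decision_function(X)


def adaboost_predict(model: AdaBoostBinaryClassifier, X) -> np.ndarray:
    return model.predict(X)


# -- baseline comparators ---------------------------------------------------

class _NBAdapter(ClassifierMixin, BaseEstimator):
    """Gaussian naive Bayes with a log-odds decision_function."""

    def __init__(self, var_smoothing: float = 1e-9) -> None:
        self.var_smoothing = var_smoothing

    def fit(self, X, y):
        self.nb_ = GaussianNB(var_smoothing=self.var_smoothing).fit(X, y)
        self.classes_ = self.nb_.classes_
        return self

    def decision_function(self, X):
        logp = self.nb_.predict_log_proba(X)
        return logp[:, 1] - logp[:, 0]

    def predict(self, X):
        return self.nb_.predict(X)


class _DTAdapter(ClassifierMixin, BaseEstimator):
    """Unweighted tree baseline reusing the boosting weak learner."""

    def __init__(self, max_depth: int = 9) -> None:
        self.max_depth = max_depth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        yy = np.where(y == self.classes_[-1], 1, -1)
        w = np.full(y.shape[0], 1.0 / y.shape[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.tree_ = train_weak_learner(X, yy, w, self.max_depth)
        return self

    def decision_function(self, X):
        return self.tree_.predict(X).astype(float)

    def predict(self, X):
        pred = self.tree_.predict(X)
        return np.where(pred == 1, self.classes_[-1], self.classes_[0])


def make_baseline(name: str, param_grid: dict | None = None, **hyperparams):
    """Baseline classifier adapters with a uniform fit/decision_function API.

    ``name`` is one of ``svm_rbf``, ``naive_bayes_gaussian``, ``dt`` or
    ``adaboost``.  If ``param_grid`` is given the estimator is wrapped
    in a grid search (5-fold) over it.
    """
    if name == "svm_rbf":
        est = SVC(kernel="rbf", **hyperparams)
    elif name == "naive_bayes_gaussian":
        est = _NBAdapter(**hyperparams)
    elif name == "dt":
        est = _DTAdapter(**hyperparams)
    elif name == "adaboost":
        est = AdaBoostBinaryClassifier(**hyperparams)
    else:
        raise ValueError(f"unknown baseline {name!r}")
    if param_grid:
        from sklearn.model_selection import GridSearchCV

        est = GridSearchCV(est, param_grid, cv=5)
    return est


# -- persistence ------------------------------------------------------------

_PERSIST_VERSION = 1


def save_model(model: AdaBoostBinaryClassifier, path: str | Path) -> Path:
    """Serialize a fitted ensemble to a versioned JSON document."""
    check_is_fitted(model, "alphas_")
    doc = {
        "format_version": _PERSIST_VERSION,
        "learning_rate": model.learning_rate,
        "max_depth": model.max_depth,
        "n_estimators": model.n_estimators,
        "random_state": model.random_state,
        "classes": np.asarray(model.classes_).tolist(),
        "alphas": model.alphas_.tolist(),
        "estimator_errors": model.estimator_errors_.tolist(),
        "n_features_in": model.n_features_in_,
        "trees": [t.root_ for t in model.estimators_],
        "tree_max_depths": [t.max_depth for t in model.estimators_],
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_model(path: str | Path) -> AdaBoostBinaryClassifier:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _PERSIST_VERSION:
        raise ValueError(f"unsupported model format {doc.get('format_version')!r}")
    model = AdaBoostBinaryClassifier(
        n_estimators=doc["n_estimators"],
        learning_rate=doc["learning_rate"],
        max_depth=doc["max_depth"],
        random_state=doc["random_state"],
    )
    model.classes_ = np.asarray(doc["classes"])
    model.alphas_ = np.asarray(doc["alphas"])
    model.estimator_errors_ = np.asarray(doc["estimator_errors"])
    model.n_features_in_ = doc["n_features_in"]
    model.n_iter_ = len(doc["trees"])
    model.estimators_ = []
    for root, md in zip(doc["trees"], doc["tree_max_depths"]):
        tree = DecisionTreeWeakLearner(max_depth=md)
        tree.root_ = root
        tree.n_features_ = doc["n_features_in"]
        model.estimators_.append(tree)
    return model
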