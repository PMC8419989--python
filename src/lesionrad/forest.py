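"""Random forest with balanced bootstrap and balanced class weights.

Class imbalance is neutralised two ways: each tree is grown on a bootstrap
sample containing an equal number of draws per class (the minority-class
count, drawn with replacement from every class), and tree split criteria use
inverse-class-frequency weights.  With label-independent features this makes
the mean predicted positive-class score ~0.5 regardless of the training
prior.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier


class BalancedRandomForestClassifier(BaseEstimator, ClassifierMixin):
    def __init__(self, n_estimators: int = 500, max_depth=None,
                 max_features="sqrt", random_state=None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        # float32 + check_input=False skips per-tree revalidation, which would
        # otherwise dominate the cost of growing many small trees
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        rng = np.random.default_rng(self.random_state)
        class_idx = [np.flatnonzero(y_enc == c) for c in range(len(self.classes_))]
        n_min = min(len(ix) for ix in class_idx)
        self.estimators_ = []
        n_classes = len(self.classes_)
        for _ in range(self.n_estimators):
            # per tree: undersample every class to the minority count without
            # replacement, then bootstrap within class.  Doing both steps keeps
            # the *distinct*-subject count symmetric across classes; a plain
            # with-replacement draw would give the majority class more distinct
            # points per tree and bias pure leaves toward it.
            parts = []
            for ix in class_idx:
                base = ix if len(ix) == n_min else rng.choice(ix, size=n_min, replace=False)
                parts.append(rng.choice(base, size=n_min, replace=True))
            idx = np.concatenate(parts)
            yb = y_enc[idx]
            # inverse-class-frequency ("balanced") weights, computed directly;
            # under the balanced bootstrap the per-tree counts are equal, so
            # the weights are uniform, but the general formula is kept for
            # subclasses that change the resampling
            counts = np.bincount(yb, minlength=n_classes)
            sw = (len(yb) / (n_classes * counts))[yb].astype(np.float64)
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                max_features=self.max_features,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(X[idx], yb, sample_weight=sw, check_input=False)
            self.estimators_.append(tree)
        return self

    def predict_proba(self, X):
        X = np.ascontiguousarray(X, dtype=np.float32)
        n_classes = len(self.classes_)
        proba = np.zeros((X.shape[0], n_classes))
        for tree in self.estimators_:
            # balanced bootstrap guarantees every class in every tree, so the
            # per-tree class order always matches self.classes_
            values = np.asarray(tree.tree_.predict(X)).reshape(X.shape[0], -1)[:, :n_classes]
            proba += values / values.sum(axis=1, keepdims=True)
        return proba / len(self.estimators_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
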