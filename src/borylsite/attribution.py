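"""Additive per-feature attributions for tree-ensemble predictions.

Implements the path-dependent TreeSHAP algorithm for scikit-learn decision
trees and random forests: exact Shapley values of the tree's conditional
expectation game, computed in polynomial time by tracking the proportion of
feature subsets flowing down each path.  For a forest, attributions and the
base value are averaged over trees, which preserves the local-accuracy
identity

    base_value + sum(contributions) == predicted probability of label 1

to numerical precision.  Only tree ensembles are supported (the
attribution game is defined by tree traversal); other learners raise
:class:`UnsupportedModelError`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .classify import FittedModel
from .errors import UnsupportedModelError


def _tree_arrays(tree):
    """Extract node arrays and per-node P(label=1) from an sklearn tree."""
    t = tree.tree_
    value = t.value[:, 0, :]
    classes = list(getattr(tree, "classes_", [0, 1]))
    if 1 in classes:
        pos = classes.index(1)
        totals = value.sum(axis=1)
        safe = np.where(totals > 0, totals, 1.0)
        prob1 = np.where(totals > 0, value[:, pos] / safe, 0.0)
    else:  # degenerate single-class tree: P(label=1) is identically 0
        prob1 = np.zeros(value.shape[0])
    return (
        t.children_left,
        t.children_right,
        t.feature,
        t.threshold,
        t.weighted_n_node_samples,
        prob1,
    )


def _tree_expected_value(tree) -> float:
    left, right, feature, threshold, cover, value = _tree_arrays(tree)
    # cover-weighted mean over leaves == recursive expectation with no
    # features conditioned on
    leaves = left == -1
    return float(np.sum(cover[leaves] * value[leaves]) / cover[0])


def _tree_shap(tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Path-dependent TreeSHAP for one fitted sklearn tree."""
    left, right, feature, threshold, cover, value = _tree_arrays(tree)
    phi = np.zeros(n_features)

    def extend(d, z, o, w, pz, po, pi):
        d = d + [pi]
        z = z + [pz]
        o = o + [po]
        u = len(w)  # index of new element
        w = w + [1.0 if u == 0 else 0.0]
        for i in range(u - 1, -1, -1):
            w[i + 1] += po * w[i] * (i + 1) / (u + 1)
            w[i] = pz * w[i] * (u - i) / (u + 1)
        return d, z, o, w

    def unwound_sum(z, o, w, i):
        u = len(w) - 1
        total = 0.0
        if o[i] != 0:
            n = w[u]
            for j in range(u - 1, -1, -1):
                tmp = n * (u + 1) / ((j + 1) * o[i])
                total += tmp
                n = w[j] - tmp * z[i] * (u - j) / (u + 1)
        else:
            for j in range(u - 1, -1, -1):
                total += w[j] * (u + 1) / (z[i] * (u - j))
        return total

    def unwind(d, z, o, w, i):
        u = len(w) - 1
        d, z, o, w = list(d), list(z), list(o), list(w)
        n = w[u]
        if o[i] != 0:
            for j in range(u - 1, -1, -1):
                tmp = n * (u + 1) / ((j + 1) * o[i])
                n = w[j] - tmp * z[i] * (u - j) / (u + 1)
                w[j] = tmp
        else:
            for j in range(u - 1, -1, -1):
                w[j] = w[j] * (u + 1) / (z[i] * (u - j))
        for j in range(i, u):
            d[j], z[j], o[j] = d[j + 1], z[j + 1], o[j + 1]
        return d[:-1], z[:-1], o[:-1], w[:-1]

    def recurse(node, d, z, o, w, pz, po, pi):
        d, z, o, w = extend(d, z, o, w, pz, po, pi)
        if left[node] == -1:
            for i in range(1, len(d)):
                s = unwound_sum(z, o, w, i)
                phi[d[i]] += s * (o[i] - z[i]) * value[node]
            return
        f = feature[node]
        hot, cold = (
            (left[node], right[node])
            if x[f] <= threshold[node]
            else (right[node], left[node])
        )
        iz, io = 1.0, 1.0
        k = next((j for j in range(1, len(d)) if d[j] == f), None)
        if k is not None:
            iz, io = z[k], o[k]
            d, z, o, w = unwind(d, z, o, w, k)
        recurse(hot, d, z, o, w, iz * cover[hot] / cover[node], io, f)
        recurse(cold, d, z, o, w, iz * cover[cold] / cover[node], 0.0, f)

    recurse(0, [], [], [], [], 1.0, 1.0, -1)
    return phi


def shap_attributions(model, row) -> tuple[pd.Series, float]:
    """Per-feature additive contributions and base value for one site row.

    ``model`` is a :class:`~borylsite.classify.FittedModel` wrapping a tree
    ensemble (or a bare sklearn forest/tree); ``row`` is a Series or 1-D
    array in the model's column order.  Contributions sum with the base
    value to the model's predicted probability of borylation.
    """
    columns = None
    if isinstance(model, FittedModel):
        columns = model.columns
        estimator = model.estimator
    else:
        estimator = model
    if isinstance(estimator, RandomForestClassifier):
        trees = list(estimator.estimators_)
    elif isinstance(estimator, DecisionTreeClassifier):
        trees = [estimator]
    else:
        raise UnsupportedModelError(
            f"SHAP attributions support tree ensembles only, got {type(estimator).__name__}"
        )
    if isinstance(row, pd.Series):
        if columns is None:
            columns = list(row.index)
        x = row.loc[columns].to_numpy(dtype=float) if set(columns) <= set(row.index) \
            else row.to_numpy(dtype=float)
    else:
        x = np.asarray(row, dtype=float)
    n_features = trees[0].tree_.n_features
    phi = np.zeros(n_features)
    base = 0.0
    for tree in trees:
        phi += _tree_shap(tree, x, n_features)
        base += _tree_expected_value(tree)
    phi /= len(trees)
    base /= len(trees)
    index = columns if columns is not None and len(columns) == n_features else range(n_features)
    return pd.Series(phi, index=index, name="contribution"), float(base)
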