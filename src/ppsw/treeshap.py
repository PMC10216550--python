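"""Exact Shapley-value attribution for sklearn tree ensembles (Tree SHAP).

Implements the path-dependent Tree SHAP algorithm: for each sample the tree
is traversed once while maintaining the set of unique features on the path
together with the proportion of all feature subsets ("path weights") that
flow down each branch, which yields the exact Shapley values of the
cover-weighted conditional-expectation game in O(leaves * depth^2) instead
of exponential time.  Attributions satisfy local accuracy by construction:
for every sample and output, ``base_value + sum(phi) == model output``.

Supported models: ``DecisionTreeClassifier`` / ``DecisionTreeRegressor``
and their random-forest / extra-trees ensembles.  Classifier attributions
are in probability space (per class); forest attributions are the average
of per-tree attributions, matching the averaged ``predict_proba``.

The per-sample kernel is numba-compiled with an explicit work stack (one
frame per path node, carrying a private copy of the path arrays, exactly
mirroring the recursive formulation).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["tree_shap_values", "expected_value"]


@njit(cache=True)
def _extend(fi, zf, of, pw, unique_depth, pz, po, pi):
    fi[unique_depth] = pi
    zf[unique_depth] = pz
    of[unique_depth] = po
    pw[unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pw[i + 1] += po * pw[i] * (i + 1.0) / (unique_depth + 1.0)
        pw[i] = pz * pw[i] * (unique_depth - i) / (unique_depth + 1.0)


@njit(cache=True)
def _unwind(fi, zf, of, pw, unique_depth, path_index):
    one_fraction = of[path_index]
    zero_fraction = zf[path_index]
    next_one_portion = pw[unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = pw[i]
            pw[i] = next_one_portion * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
            next_one_portion = tmp - pw[i] * zero_fraction * (unique_depth - i) / (
                unique_depth + 1.0
            )
        else:
            pw[i] = pw[i] * (unique_depth + 1.0) / (zero_fraction * (unique_depth - i))
    for i in range(path_index, unique_depth):
        fi[i] = fi[i + 1]
        zf[i] = zf[i + 1]
        of[i] = of[i + 1]


@njit(cache=True)
def _unwound_path_sum(zf, of, pw, unique_depth, path_index):
    one_fraction = of[path_index]
    zero_fraction = zf[path_index]
    next_one_portion = pw[unique_depth]
    total = 0.0
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = next_one_portion * (unique_depth + 1.0) / ((i + 1.0) * one_fraction)
            total += tmp
            next_one_portion = pw[i] - tmp * zero_fraction * (unique_depth - i) / (
                unique_depth + 1.0
            )
        elif zero_fraction != 0.0:
            total += (pw[i] / zero_fraction) / ((unique_depth - i) / (unique_depth + 1.0))
    return total


@njit(cache=True)
def _tree_shap_sample(
    children_left,
    children_right,
    feature,
    threshold,
    cover,
    values,  # (n_nodes, n_outputs) leaf values
    x,
    phi,  # (n_features, n_outputs), accumulated in place
):
    max_depth = 0
    # conservative path bound: tree depth + 2; compute depth iteratively
    n_nodes = children_left.shape[0]
    depth = np.zeros(n_nodes, dtype=np.int64)
    for node in range(n_nodes):
        if children_left[node] >= 0:
            depth[children_left[node]] = depth[node] + 1
            depth[children_right[node]] = depth[node] + 1
            if depth[node] + 1 > max_depth:
                max_depth = depth[node] + 1
    plen = max_depth + 2

    stack_cap = 2 * (max_depth + 1) + 2
    st_node = np.empty(stack_cap, dtype=np.int64)
    st_depth = np.empty(stack_cap, dtype=np.int64)
    st_pz = np.empty(stack_cap)
    st_po = np.empty(stack_cap)
    st_pi = np.empty(stack_cap, dtype=np.int64)
    st_fi = np.empty((stack_cap, plen), dtype=np.int64)
    st_zf = np.empty((stack_cap, plen))
    st_of = np.empty((stack_cap, plen))
    st_pw = np.empty((stack_cap, plen))

    fi = np.empty(plen, dtype=np.int64)
    zf = np.empty(plen)
    of = np.empty(plen)
    pw = np.empty(plen)

    top = 0
    st_node[0] = 0
    st_depth[0] = 0
    st_pz[0] = 1.0
    st_po[0] = 1.0
    st_pi[0] = -1
    top = 1

    n_outputs = values.shape[1]
    while top > 0:
        top -= 1
        node = st_node[top]
        unique_depth = st_depth[top]
        pz = st_pz[top]
        po = st_po[top]
        pi = st_pi[top]
        for i in range(unique_depth):
            fi[i] = st_fi[top, i]
            zf[i] = st_zf[top, i]
            of[i] = st_of[top, i]
            pw[i] = st_pw[top, i]

        _extend(fi, zf, of, pw, unique_depth, pz, po, pi)

        if children_left[node] < 0:  # leaf
            for i in range(1, unique_depth + 1):
                w = _unwound_path_sum(zf, of, pw, unique_depth, i)
                scale = w * (of[i] - zf[i])
                f = fi[i]
                for k in range(n_outputs):
                    phi[f, k] += scale * values[node, k]
        else:
            hot = children_left[node]
            cold = children_right[node]
            if x[feature[node]] > threshold[node]:
                hot, cold = cold, hot
            incoming_zero = 1.0
            incoming_one = 1.0
            path_index = 0
            for i in range(1, unique_depth + 1):
                if fi[i] == feature[node]:
                    path_index = i
                    break
            if path_index > 0:
                incoming_zero = zf[path_index]
                incoming_one = of[path_index]
                _unwind(fi, zf, of, pw, unique_depth, path_index)
                unique_depth -= 1

            hot_zero = cover[hot] / cover[node]
            cold_zero = cover[cold] / cover[node]

            # push cold then hot (order immaterial)
            for child, child_zero, child_one in (
                (cold, cold_zero * incoming_zero, 0.0),
                (hot, hot_zero * incoming_zero, incoming_one),
            ):
                st_node[top] = child
                st_depth[top] = unique_depth + 1
                st_pz[top] = child_zero
                st_po[top] = child_one
                st_pi[top] = feature[node]
                for i in range(unique_depth + 1):
                    st_fi[top, i] = fi[i]
                    st_zf[top, i] = zf[i]
                    st_of[top, i] = of[i]
                    st_pw[top, i] = pw[i]
                top += 1


@njit(cache=True)
def _tree_shap_batch(children_left, children_right, feature, threshold, cover, values, X):
    n_samples = X.shape[0]
    n_features = X.shape[1]
    n_outputs = values.shape[1]
    phi = np.zeros((n_samples, n_features, n_outputs))
    for s in range(n_samples):
        _tree_shap_sample(
            children_left, children_right, feature, threshold, cover, values, X[s], phi[s]
        )
    return phi


def _tree_arrays(tree, normalize_proba: bool):
    """Flat arrays of one fitted sklearn tree, leaf values per output."""
    t = tree.tree_
    values = t.value.copy()  # (n_nodes, n_outputs_sk, n_classes or 1)
    if normalize_proba:
        # classifier: per-node class-count (or fraction) vectors -> probabilities
        sums = values.sum(axis=2, keepdims=True)
        sums[sums == 0] = 1.0
        values = values / sums
        values = values[:, 0, :]
    else:
        values = values[:, :, 0] if values.shape[2] == 1 else values[:, 0, :]
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
        np.ascontiguousarray(values, dtype=np.float64),
    )


def _is_classifier(model) -> bool:
    return hasattr(model, "predict_proba")


def _component_trees(model):
    if hasattr(model, "estimators_"):
        ests = np.asarray(model.estimators_).ravel().tolist()
        if not all(hasattr(e, "tree_") for e in ests):
            raise TypeError(f"{type(model).__name__} is not a supported tree ensemble")
        if _is_classifier(model) and not all(_is_classifier(e) for e in ests):
            raise TypeError(
                f"{type(model).__name__} aggregates raw scores, not probabilities; "
                "probability-space attributions are only defined for "
                "probability-averaging ensembles (random forest / extra trees)"
            )
        return ests
    if hasattr(model, "tree_"):
        return [model]
    raise TypeError(f"{type(model).__name__} has no tree structure")


def expected_value(model) -> np.ndarray:
    """Cover-weighted expectation of the model output (the SHAP base value)."""
    trees = _component_trees(model)
    proba = _is_classifier(model)
    acc = None
    for est in trees:
        _, _, _, _, cover, values = _tree_arrays(est, proba)
        t = est.tree_
        leaves = t.children_left < 0
        ev = (values[leaves] * (cover[leaves] / cover[0])[:, None]).sum(axis=0)
        acc = ev if acc is None else acc + ev
    return acc / len(trees)


def tree_shap_values(model, X: np.ndarray) -> np.ndarray:
    """Exact Tree SHAP attributions, shape (n_samples, n_features, n_outputs).

    For classifiers the outputs are class probabilities; for a forest the
    attributions (and base values) average over member trees, so
    ``expected_value(model) + phi.sum(axis=1)`` equals ``predict_proba(X)``
    up to floating round-off.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    trees = _component_trees(model)
    proba = _is_classifier(model)
    phi = None
    for est in trees:
        arrays = _tree_arrays(est, proba)
        contrib = _tree_shap_batch(*arrays, X)
        phi = contrib if phi is None else phi + contrib
    return phi / len(trees)
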